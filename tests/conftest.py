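import numpy as np
import pandas as pd
import pytest

import radiotox
from radiotox.risk import DosagePanel, RiskModel, RiskVariant
from radiotox.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def packaged_model() -> RiskModel:
    return radiotox.packaged_risk_model()


@pytest.fixture()
def tiny_model() -> RiskModel:
    """Three non-palindromic variants with hand-pickable weights."""
    return RiskModel(
        [
            RiskVariant("v1", "1", 100, "G", "T", 1.2, eaf=0.3),
            RiskVariant("v2", "2", 200, "A", "C", 1.5, eaf=0.5),
            RiskVariant("v3", "3", 300, "C", "T", 0.8, eaf=0.7),
        ],
        source_label="tiny",
    )


def make_panel(model: RiskModel, dosage: np.ndarray, orient: str = "risk") -> DosagePanel:
    """Panel whose dosage counts the risk allele (orient='risk') or the other."""
    if orient == "risk":
        a = [v.other_allele for v in model]
        b = [v.risk_allele for v in model]
    else:
        a = [v.risk_allele for v in model]
        b = [v.other_allele for v in model]
        dosage = 2.0 - dosage
    meta = pd.DataFrame(
        {
            "variant_id": model.variant_ids,
            "chrom": [v.chrom for v in model],
            "pos": [v.pos for v in model],
            "allele_a": a,
            "allele_b": b,
        }
    )
    return DosagePanel(
        sample_ids=[f"S{i}" for i in range(dosage.shape[0])], variants=meta, dosage=dosage
    )


@pytest.fixture(scope="session")
def prostate_cohort(packaged_model):
    """One deterministic null prostate cohort reused by read-only tests."""
    cfg = SimulationConfig(n_patients=300, site="prostate", master_seed=42)
    return simulate_cohort(cfg, model=packaged_model)
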