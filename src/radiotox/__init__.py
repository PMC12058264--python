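"""radiotox: polygenic risk scores and radiotherapy-toxicity association testing.

The package covers the full analysis chain for asking whether genetic
predisposition to rheumatoid arthritis (a 101-variant polygenic risk score)
associates with acute or late radiotherapy toxicity: harmonizing genotype
dosages to a risk-variant model and scoring them, collapsing longitudinal
CTCAE grades into standardized total average toxicity (STAT), and running
the per-site univariable/multivariable linear-model battery with Bonferroni
multiplicity control — plus a synthetic-cohort generator so every stage is
testable without patient data.
"""

from importlib import resources

__version__ = "0.1.0"

from .association import (
    DoseSpec,
    bed_convert,
    bonferroni_threshold,
    dichotomize_at_percentile,
    fit_ols,
    run_battery,
)
from .risk import (
    DosagePanel,
    RiskModel,
    RiskVariant,
    ScoreSet,
    compare_by_diagnosis,
    compute_scores,
    harmonize_dosages,
    load_risk_model,
)
from .simulate import SimulationConfig, generate_cohort, simulate_cohort
from .toxicity import SITE_ENDPOINTS, Windows, compute_stat, stat_table, summarize_endpoints


def packaged_risk_model() -> RiskModel:
    """The packaged 101-variant synthetic RA risk model.

    A deterministic stand-in for the 101-locus rheumatoid-arthritis GWAS hit
    list used for scoring: same size and schema, synthetic positions, allele
    pairs, odds ratios and frequencies (the real table is redistributed
    under its own terms, so a generated fixture ships instead).
    """
    path = resources.files("radiotox.data") / "ra_101_synthetic.tsv"
    return load_risk_model(str(path), source_label="ra_101_synthetic")
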