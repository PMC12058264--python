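"""Synthetic radiotherapy cohorts for end-to-end pipeline testing.

Real radiogenomics cohorts of this kind are not publicly deposited, so the
generator produces self-contained stand-ins with known ground truth: a risk
model of ~101 independent biallelic SNPs, Hardy-Weinberg genotype dosages
with optional imputation noise, per-site clinical covariates with plausible
marginals, and longitudinal CTCAE grades produced by thresholding a latent
toxicity variable.  The latent noise is a Gaussian plus a centred Gamma,
giving the right-skewed overall-toxicity (STAT) distributions seen in
observational toxicity data, and an optional planted effect couples the
standardized weighted risk score to the latent scale so recovery of a known
coefficient can be tested.

Every draw is a pure function of its seed; per-component seeds are derived
deterministically from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .risk import DosagePanel, RiskModel, RiskVariant, compute_scores
from .toxicity import SITE_ENDPOINTS

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: visit schedule in days from the end of radiotherapy (fixed, so window
#: maxima are exactly predictable in tests)
BASELINE_DAY = -7
ACUTE_DAYS = (14, 45, 80)
LATE_DAYS = (180, 365, 540, 720)

#: latent-scale covariate effects (per sd for continuous, per unit for binary)
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "prostate": {"age": 0.10, "diabetes": 0.15, "bed": 0.20, "hormone_therapy": 0.10},
    "lung": {"age": 0.10, "smoker": 0.20, "bed": 0.20, "copd": 0.15, "v20_lungs": 0.10},
    "breast": {"age": 0.10, "smoker": 0.15, "bmi": 0.10, "boost": 0.15, "breast_volume": 0.10},
}

#: latent thresholds for CTCAE grades 1..4
DEFAULT_GRADE_THRESHOLDS = (0.8, 1.8, 2.8, 3.8)


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic cohort."""

    n_patients: int = 500
    n_variants: int = 101
    site: str = "prostate"
    effect_gamma: float = 0.0  # latent effect per standardized wPRS unit
    covariate_effects: dict[str, float] | None = None
    grade_thresholds: tuple[float, ...] = DEFAULT_GRADE_THRESHOLDS
    imputation_noise_sd: float = 0.05
    covariate_missingness: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.site not in SITE_ENDPOINTS:
            raise ValueError(f"unknown site {self.site!r}")
        t = tuple(self.grade_thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("grade thresholds must be strictly increasing")
        if self.imputation_noise_sd < 0:
            raise ValueError("imputation_noise_sd must be >= 0")

    def component_seeds(self) -> dict[str, int]:
        """Deterministic per-component child seeds below 2**31."""
        ss = np.random.SeedSequence(self.master_seed)
        names = ("risk_model", "genotypes", "covariates", "toxicity")
        states = ss.generate_state(len(names)) % (2**31)
        return dict(zip(names, (int(s) for s in states)))


def draw_risk_model(
    n_variants: int, seed: int, ambiguous_fraction: float = 0.0
) -> RiskModel:
    """A synthetic risk-variant table emulating a GWAS hit list.

    Effect-allele frequencies are Uniform(0.05, 0.95) and log odds ratios
    Normal(0, 0.1); allele pairs avoid palindromic (A/T, C/G) combinations
    except for a requested ``ambiguous_fraction``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.05, 0.95, size=n_variants)
    odds = np.exp(rng.normal(0.0, 0.1, size=n_variants))
    chrom = rng.integers(1, 23, size=n_variants)
    pos = rng.integers(10_000, 50_000_000, size=n_variants)
    ambiguous = rng.random(n_variants) < ambiguous_fraction
    bases = np.array(list("ACGT"))
    variants = []
    for i in range(n_variants):
        risk = rng.choice(bases)
        if ambiguous[i]:
            other = _COMPLEMENT[risk]
        else:
            choices = [b for b in bases if b != risk and b != _COMPLEMENT[risk]]
            other = rng.choice(choices)
        variants.append(
            RiskVariant(
                variant_id=f"rs{i + 1:06d}",
                chrom=str(chrom[i]),
                pos=int(pos[i]),
                risk_allele=str(risk),
                other_allele=str(other),
                odds_ratio=float(odds[i]),
                eaf=float(eaf[i]),
            )
        )
    return RiskModel(variants, source_label=f"synthetic(seed={seed})")


def draw_genotypes(
    model: RiskModel, n_patients: int, imputation_noise_sd: float = 0.0, seed: int = 0
) -> DosagePanel:
    """Hardy-Weinberg genotypes with optional imputation-like dosage noise.

    Hard genotypes are Binomial(2, eaf) independently per variant (no LD);
    dosage adds Normal(0, noise_sd) and clamps to [0, 2].  ``allele_b`` is
    the model's risk allele, so the panel is born risk-allele oriented.
    """
    rng = np.random.default_rng(seed)
    eaf = np.array([v.eaf if v.eaf is not None else 0.5 for v in model])
    geno = rng.binomial(2, eaf, size=(n_patients, len(model))).astype(float)
    if imputation_noise_sd > 0:
        geno = geno + rng.normal(0.0, imputation_noise_sd, size=geno.shape)
        np.clip(geno, 0.0, 2.0, out=geno)
    sample_ids = [f"P{i + 1:05d}" for i in range(n_patients)]
    meta = pd.DataFrame(
        {
            "variant_id": model.variant_ids,
            "chrom": [v.chrom for v in model],
            "pos": [v.pos for v in model],
            "allele_a": [v.other_allele for v in model],
            "allele_b": [v.risk_allele for v in model],
        }
    )
    return DosagePanel(sample_ids=sample_ids, variants=meta, dosage=geno)


_REGIMENS = {
    # (total dose Gy, n fractions), sampling probability
    "prostate": ([(74.0, 37), (60.0, 20), (78.0, 39)], [0.5, 0.3, 0.2]),
    "lung": ([(60.0, 30), (55.0, 20), (66.0, 33)], [0.5, 0.3, 0.2]),
    "breast": ([(40.05, 15), (50.0, 25)], [0.6, 0.4]),
}


def draw_covariates(
    site: str, n_patients: int, seed: int = 0, missingness: float = 0.0
) -> pd.DataFrame:
    """Per-site clinical covariates with plausible marginals.

    Prescriptions are drawn from a small set of standard fractionation
    regimens and stored as ``total_dose``/``n_fractions`` columns (the
    association design derives BED from them).  ``missingness`` masks that
    fraction of covariate cells at random (doses stay complete).
    """
    if site not in _REGIMENS:
        raise ValueError(f"unknown site {site!r}")
    rng = np.random.default_rng(seed)
    n = n_patients
    idx = pd.Index([f"P{i + 1:05d}" for i in range(n)], name="patient_id")
    regimens, probs = _REGIMENS[site]
    reg_idx = rng.choice(len(regimens), size=n, p=probs)
    total_dose = np.array([regimens[i][0] for i in reg_idx])
    n_fractions = np.array([regimens[i][1] for i in reg_idx])

    if site == "prostate":
        df = pd.DataFrame(
            {
                "age": rng.normal(70, 8, n).round(1),
                "diabetes": rng.binomial(1, 0.20, n),
                "prior_surgery": rng.binomial(1, 0.15, n),
                "hormone_therapy": rng.binomial(1, 0.50, n),
            },
            index=idx,
        )
    elif site == "lung":
        df = pd.DataFrame(
            {
                "sex": rng.binomial(1, 0.35, n),
                "age": rng.normal(68, 8, n).round(1),
                "smoker": rng.binomial(1, 0.70, n),
                "technique": rng.choice(
                    ["3d_conformal", "imrt", "arc", "tomotherapy", "sbrt"],
                    size=n,
                    p=[0.35, 0.30, 0.20, 0.05, 0.10],
                ),
                "fev1": np.clip(rng.normal(2.0, 0.6, n), 0.5, None).round(2),
                "v20_lungs": np.clip(rng.normal(25, 7, n), 0, 60).round(1),
                "v35_esophagus": np.clip(rng.normal(30, 12, n), 0, 80).round(1),
                "copd": rng.binomial(1, 0.30, n),
            },
            index=idx,
        )
    else:  # breast
        df = pd.DataFrame(
            {
                "age": rng.normal(58, 8, n).round(1),
                "smoker": rng.binomial(1, 0.25, n),
                "cardiovascular_disease": rng.binomial(1, 0.15, n),
                "bmi": np.clip(rng.normal(27, 5, n), 15, None).round(1),
                "breast_volume": np.clip(rng.normal(800, 300, n), 100, None).round(0),
                "diabetes": rng.binomial(1, 0.10, n),
                "postop_infection": rng.binomial(1, 0.08, n),
                "boost": rng.binomial(1, 0.50, n),
            },
            index=idx,
        )
    if missingness > 0:
        mask = rng.random(df.shape) < missingness
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    df["total_dose"] = total_dose
    df["n_fractions"] = n_fractions
    return df


def _latent_covariate_term(covariates: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    """Linear predictor over named covariates; continuous ones enter per-sd."""
    term = np.zeros(len(covariates))
    for name, beta in effects.items():
        if name == "bed":
            from .association import bed_column

            col = bed_column(covariates["total_dose"], covariates["n_fractions"])
            col = pd.Series(col, index=covariates.index)
        else:
            col = covariates[name]
        col = col.astype(float)
        vals = col.to_numpy()
        uniq = np.unique(vals[~np.isnan(vals)])
        if uniq.size > 2:  # continuous: standardize so beta is per sd
            sd = np.nanstd(vals, ddof=1)
            vals = (vals - np.nanmean(vals)) / (sd if sd > 0 else 1.0)
        term = term + beta * np.nan_to_num(vals, nan=0.0)
    return term


def _skewed_noise(rng: np.random.Generator, size) -> np.ndarray:
    """Gaussian plus centred Gamma(2, 0.5): right-skewed, mean ~0."""
    return rng.normal(0.0, 1.0, size) + rng.gamma(2.0, 0.5, size) - 1.0


def draw_toxicity(
    prs_std: np.ndarray,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
    timings: tuple[str, ...] = ("acute", "late"),
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Longitudinal CTCAE records from a thresholded latent toxicity variable.

    Per patient, endpoint and visit the latent value is the covariate linear
    term plus ``effect_gamma * prs_std`` plus skewed noise; the grade counts
    how many of the (increasing) thresholds lie below it, capped at 4.
    Baseline visits (day -7) are drawn with the planted effect set to zero.
    Returns the long-format record table and per-patient means of the
    realized post-treatment latent values per window (the ground truth used
    by effect-recovery checks).
    """
    rng = np.random.default_rng(seed)
    effects = config.covariate_effects
    if effects is None:
        effects = DEFAULT_COVARIATE_EFFECTS[config.site]
    cov_term = _latent_covariate_term(covariates, effects)
    prs_std = np.asarray(prs_std, dtype=float)
    n = len(cov_term)
    if len(prs_std) != n:
        raise ValueError("prs_std and covariates disagree on cohort size")
    thresholds = np.asarray(config.grade_thresholds)

    site_eps = SITE_ENDPOINTS[config.site]
    endpoints = sorted(set(site_eps["acute"]) | set(site_eps["late"]))
    days: list[int] = [BASELINE_DAY]
    if "acute" in timings:
        days += list(ACUTE_DAYS)
    if "late" in timings:
        days += list(LATE_DAYS)

    patient_ids = np.asarray(covariates.index)
    frames = []
    latent_sums = {"acute": np.zeros(n), "late": np.zeros(n)}
    latent_counts = {"acute": 0, "late": 0}
    for ep in endpoints:
        for day in days:
            gamma = 0.0 if day <= 0 else config.effect_gamma
            latent = cov_term + gamma * prs_std + _skewed_noise(rng, n)
            grade = np.searchsorted(thresholds, latent, side="left")  # thresholds strictly below
            grade = np.minimum(grade, 4)
            if day > 0:
                window = "acute" if day <= 90 else "late"
                latent_sums[window] += latent
                latent_counts[window] += 1
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_ids,
                        "endpoint": ep,
                        "day": day,
                        "grade": grade.astype(int),
                    }
                )
            )
    records = pd.concat(frames, ignore_index=True)
    latent_means = {
        w: latent_sums[w] / latent_counts[w] if latent_counts[w] else np.full(n, np.nan)
        for w in ("acute", "late")
    }
    return records, latent_means


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: every input the pipeline consumes, plus truth."""

    config: SimulationConfig
    model: RiskModel
    panel: DosagePanel
    covariates: pd.DataFrame
    toxicity: pd.DataFrame
    truth: dict


def simulate_cohort(
    config: SimulationConfig,
    model: RiskModel | None = None,
    timings: tuple[str, ...] = ("acute", "late"),
) -> CohortBundle:
    """Draw a full cohort under ``config``.

    A ``model`` may be supplied (e.g. the packaged synthetic risk model) to
    hold the locus set fixed across replicate cohorts; otherwise one is
    drawn from the config's seed.  The planted effect acts on the wPRS
    z-scored within the cohort.
    """
    seeds = config.component_seeds()
    if model is None:
        model = draw_risk_model(config.n_variants, seeds["risk_model"])
    panel = draw_genotypes(model, config.n_patients, config.imputation_noise_sd, seeds["genotypes"])
    covariates = draw_covariates(
        config.site, config.n_patients, seeds["covariates"], config.covariate_missingness
    )
    scores = compute_scores(panel, model).scores
    wprs = scores["wprs"].to_numpy()
    prs_std = (wprs - wprs.mean()) / wprs.std(ddof=1)
    toxicity, latent_means = draw_toxicity(prs_std, covariates, config, seeds["toxicity"], timings)
    truth = {
        "master_seed": config.master_seed,
        "component_seeds": seeds,
        "effect_gamma": config.effect_gamma,
        "site": config.site,
        "prs": scores["prs"].tolist(),
        "wprs": wprs.tolist(),
        "prs_std": prs_std.tolist(),
        "latent_stat_acute": latent_means["acute"].tolist(),
        "latent_stat_late": latent_means["late"].tolist(),
        "patient_id": list(covariates.index),
    }
    return CohortBundle(config, model, panel, covariates, toxicity, truth)


def write_vcf(panel: DosagePanel, path) -> None:
    """Serialize a dosage panel as a minimal VCF with a DS FORMAT field.

    REF is ``allele_a`` and ALT ``allele_b``; DS counts ALT copies, matching
    the panel's dosage orientation.  GT hard calls are emitted alongside DS
    (dosage rounded) so GT-only readers still work.
    """
    meta = panel.variants
    order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].astype(str).to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n'
        )
        for c in sorted(meta["chrom"].astype(str).unique(), key=lambda x: (len(x), x)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in order:
            row = meta.iloc[j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["variant_id"]),
                str(row["allele_a"]),
                str(row["allele_b"]),
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            for d in panel.dosage[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(d))]}:{d:.3f}")
            fh.write("\t".join(fields) + "\n")


def write_dosage_tsv(panel: DosagePanel, path, sidecar_path) -> None:
    """Dosage TSV (sample_id + one column per variant) with an allele sidecar."""
    df = pd.DataFrame(
        panel.dosage,
        index=pd.Index(panel.sample_ids, name="sample_id"),
        columns=panel.variants["variant_id"],
    )
    df.to_csv(path, sep="\t")
    panel.variants.to_csv(sidecar_path, sep="\t", index=False)


def generate_cohort(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write a complete cohort bundle to ``outdir`` and return the file map.

    Files: risk_model.tsv, genotypes.vcf, dosages.tsv (+ sidecar
    dosages_variants.tsv), covariates.tsv, toxicity.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_cohort(config)
    paths = {
        "risk_model": outdir / "risk_model.tsv",
        "genotypes_vcf": outdir / "genotypes.vcf",
        "dosages": outdir / "dosages.tsv",
        "dosages_variants": outdir / "dosages_variants.tsv",
        "covariates": outdir / "covariates.tsv",
        "toxicity": outdir / "toxicity.tsv",
        "truth": outdir / "truth.json",
    }
    bundle.model.to_tsv(paths["risk_model"])
    write_vcf(bundle.panel, paths["genotypes_vcf"])
    write_dosage_tsv(bundle.panel, paths["dosages"], paths["dosages_variants"])
    bundle.covariates.to_csv(paths["covariates"], sep="\t")
    bundle.toxicity.to_csv(paths["toxicity"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1)
    return paths
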