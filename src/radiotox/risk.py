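"""Risk-variant models, dosage harmonization, and polygenic risk scores.

The rheumatoid-arthritis risk model is a table of biallelic SNPs, each with a
risk allele and a per-allele odds ratio from an external GWAS.  A patient's
polygenic risk score (PRS) is the sum of their risk-allele dosages over the
loci of the model; the weighted score (wPRS) weights each dosage by the
locus's odds ratio.  Genotype files orient dosages to an arbitrary allele, so
before scoring, every variant is harmonized: the dosage is re-expressed as a
count of the model's risk allele, resolving swapped alleles and strand flips
and flagging palindromic (A/T, C/G) variants whose orientation is
undecidable from allele labels alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization statuses, in the order they are tried
STATUS_DIRECT = "direct"
STATUS_SWAPPED = "swapped"
STATUS_STRAND_FLIPPED = "strand_flipped"
STATUS_STRAND_FLIPPED_SWAPPED = "strand_flipped_swapped"
STATUS_AMBIGUOUS_KEPT = "ambiguous_kept"
STATUS_AMBIGUOUS_DROPPED = "ambiguous_dropped"
STATUS_UNMATCHED_DROPPED = "unmatched_dropped"

#: dosages may stray outside [0, 2] by this much (float serialization noise)
DOSAGE_CLAMP_TOL = 1e-6


class RiskModelError(ValueError):
    """Raised for malformed risk-model tables."""


@dataclass(frozen=True)
class RiskVariant:
    """One risk locus: a biallelic SNP with an effect (risk) allele.

    ``odds_ratio`` is the per-risk-allele odds ratio; ``eaf`` the effect
    (risk) allele frequency, used to impute missing dosages as 2*eaf.
    """

    variant_id: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_ALLELES:
            raise RiskModelError(
                f"variant {self.variant_id}: malformed risk allele {self.risk_allele!r}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise RiskModelError(
                f"variant {self.variant_id}: malformed other allele {self.other_allele!r}"
            )
        if self.risk_allele == self.other_allele:
            raise RiskModelError(
                f"variant {self.variant_id}: risk and other allele are both {self.risk_allele}"
            )
        if not self.odds_ratio > 0:
            raise RiskModelError(
                f"variant {self.variant_id}: odds ratio must be positive, got {self.odds_ratio}"
            )
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise RiskModelError(
                f"variant {self.variant_id}: eaf must lie in (0,1), got {self.eaf}"
            )

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G SNPs (alleles are their own reverse complement)."""
        return _COMPLEMENT[self.risk_allele] == self.other_allele


@dataclass
class RiskModel:
    """Ordered collection of risk variants with unique ids."""

    variants: list[RiskVariant]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.variants:
            raise RiskModelError("risk model is empty")
        seen: set[str] = set()
        for v in self.variants:
            if v.variant_id in seen:
                raise RiskModelError(f"duplicate variant_id {v.variant_id!r} in risk model")
            seen.add(v.variant_id)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "risk_allele": [v.risk_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "odds_ratio": [v.odds_ratio for v in self.variants],
                "eaf": [v.eaf for v in self.variants],
            }
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        if df["eaf"].isna().all():
            df = df.drop(columns=["eaf"])
        df.to_csv(path, sep="\t", index=False)


@dataclass
class DosagePanel:
    """Sample-by-variant dosage matrix with allele metadata.

    ``dosage`` has one row per sample and one column per variant; each value
    counts copies (0..2, real-valued for imputed genotypes) of ``allele_b``
    for that variant.  Missing dosages are NaN.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: variant_id, chrom, pos, allele_a, allele_b
    dosage: np.ndarray  # shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n_s, n_v = self.dosage.shape
        if n_s != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample_ids")
        if n_v != len(self.variants):
            raise ValueError("dosage columns do not match variant metadata")
        d = self.dosage
        finite = d[~np.isnan(d)]
        if finite.size:
            low, high = float(finite.min()), float(finite.max())
            if low < -DOSAGE_CLAMP_TOL or high > 2 + DOSAGE_CLAMP_TOL:
                raise ValueError(
                    f"dosages outside [0,2] beyond tolerance (min {low}, max {high}); "
                    "input file is likely corrupt"
                )
        np.clip(d, 0.0, 2.0, out=d)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class ScoreSet:
    """Per-sample PRS/wPRS with usage diagnostics."""

    scores: pd.DataFrame  # index sample_id; columns prs, wprs, n_dosages_imputed
    n_variants_used: int
    weight_scheme: str = "or"

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.insert(2, "n_variants_used", self.n_variants_used)
        out.to_csv(path, sep="\t", index=True, index_label="sample_id")


REQUIRED_MODEL_COLUMNS = ("variant_id", "chrom", "pos", "risk_allele", "other_allele", "odds_ratio")


def load_risk_model(path, source_label: str | None = None) -> RiskModel:
    """Load a risk-variant table (TSV) into a :class:`RiskModel`.

    The table must carry columns ``variant_id, chrom, pos, risk_allele,
    other_allele, odds_ratio`` and may carry ``eaf``.  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_id": str})
    missing = [c for c in REQUIRED_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise RiskModelError(f"risk model table {path} lacks required columns: {missing}")
    has_eaf = "eaf" in df.columns
    variants = [
        RiskVariant(
            variant_id=row.variant_id,
            chrom=str(row.chrom),
            pos=int(row.pos),
            risk_allele=str(row.risk_allele).upper(),
            other_allele=str(row.other_allele).upper(),
            odds_ratio=float(row.odds_ratio),
            eaf=float(row.eaf) if has_eaf and pd.notna(row.eaf) else None,
        )
        for row in df.itertuples(index=False)
    ]
    model = RiskModel(variants, source_label=source_label or str(path))
    logger.info("loaded risk model with %d variants from %s", len(model), path)
    return model


def _match_panel_variant(model_v: RiskVariant, panel: DosagePanel, by_id: dict, by_pos: dict):
    """Index of the panel column for a model variant, or None.

    Matches by variant_id first, chrom:pos as fallback; a duplicated key in
    the panel (stored as None) is treated as unmatched.
    """
    if model_v.variant_id in by_id:
        return by_id[model_v.variant_id]
    return by_pos.get((model_v.chrom, model_v.pos))


def harmonize_dosages(
    panel: DosagePanel, model: RiskModel, drop_ambiguous: bool = False
) -> tuple[DosagePanel, pd.DataFrame]:
    """Orient panel dosages so every retained column counts the model's risk allele.

    For each model variant the matching panel column (by ``variant_id``, falling
    back to ``chrom:pos``; duplicated keys are dropped as unmatched) is
    classified against the model alleles:

    - ``direct``: panel counts the risk allele already;
    - ``swapped``: panel counts the other allele, dosage becomes ``2 - d``;
    - ``strand_flipped`` / ``strand_flipped_swapped``: same two cases after
      reverse-complementing the panel alleles;
    - ``ambiguous_kept`` / ``ambiguous_dropped``: palindromic model variants,
      matched by exact label (imputed panels are assumed reference-strand)
      unless ``drop_ambiguous`` is set;
    - ``unmatched_dropped``: no panel column, or irreconcilable alleles.

    Returns the harmonized panel (columns in model order, dropped variants
    removed) and a per-variant report DataFrame with columns ``variant_id``,
    ``status``, ``n_missing``.  Anomalies never raise; they become statuses.
    """
    by_id: dict[str, int] = {}
    by_pos: dict[tuple[str, int], int] = {}
    meta = panel.variants
    for j, row in enumerate(meta.itertuples(index=False)):
        vid = str(row.variant_id)
        by_id[vid] = None if vid in by_id else j  # collision -> unmatched
        key = (str(row.chrom), int(row.pos))
        by_pos[key] = None if key in by_pos else j

    statuses: list[str] = []
    cols: list[np.ndarray] = []
    kept_variant_rows: list[dict] = []
    n_missing: list[int] = []

    for v in model:
        j = _match_panel_variant(v, panel, by_id, by_pos)
        if j is None:
            statuses.append(STATUS_UNMATCHED_DROPPED)
            n_missing.append(0)
            continue
        a = str(meta.iloc[j]["allele_a"]).upper()
        b = str(meta.iloc[j]["allele_b"]).upper()
        d = panel.dosage[:, j]
        status, flip = _classify(v, a, b, drop_ambiguous)
        statuses.append(status)
        if status in (STATUS_UNMATCHED_DROPPED, STATUS_AMBIGUOUS_DROPPED):
            n_missing.append(0)
            continue
        new_d = 2.0 - d if flip else d.copy()
        cols.append(new_d)
        n_missing.append(int(np.isnan(new_d).sum()))
        kept_variant_rows.append(
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "allele_a": v.other_allele,
                "allele_b": v.risk_allele,
            }
        )

    report = pd.DataFrame(
        {
            "variant_id": model.variant_ids,
            "status": statuses,
            "n_missing": [
                m if s not in (STATUS_UNMATCHED_DROPPED, STATUS_AMBIGUOUS_DROPPED) else 0
                for s, m in zip(statuses, n_missing)
            ],
        }
    )
    for s in report.loc[
        report["status"].isin([STATUS_UNMATCHED_DROPPED, STATUS_AMBIGUOUS_DROPPED]), "variant_id"
    ]:
        logger.warning("variant %s dropped during harmonization", s)

    dosage = (
        np.column_stack(cols) if cols else np.empty((panel.n_samples, 0))
    )
    out = DosagePanel(
        sample_ids=list(panel.sample_ids),
        variants=pd.DataFrame(
            kept_variant_rows, columns=["variant_id", "chrom", "pos", "allele_a", "allele_b"]
        ),
        dosage=dosage,
    )
    return out, report


def _classify(v: RiskVariant, a: str, b: str, drop_ambiguous: bool) -> tuple[str, bool]:
    """Map panel alleles (a, b; dosage counts b) onto a status and a flip flag."""
    if v.is_palindromic:
        if drop_ambiguous:
            return STATUS_AMBIGUOUS_DROPPED, False
        # exact-label match: reference-strand assumption
        if (a, b) == (v.other_allele, v.risk_allele):
            return STATUS_AMBIGUOUS_KEPT, False
        if (a, b) == (v.risk_allele, v.other_allele):
            return STATUS_AMBIGUOUS_KEPT, True
        return STATUS_UNMATCHED_DROPPED, False
    if (a, b) == (v.other_allele, v.risk_allele):
        return STATUS_DIRECT, False
    if (a, b) == (v.risk_allele, v.other_allele):
        return STATUS_SWAPPED, True
    ra, rb = _COMPLEMENT.get(a), _COMPLEMENT.get(b)
    if (ra, rb) == (v.other_allele, v.risk_allele):
        return STATUS_STRAND_FLIPPED, False
    if (ra, rb) == (v.risk_allele, v.other_allele):
        return STATUS_STRAND_FLIPPED_SWAPPED, True
    return STATUS_UNMATCHED_DROPPED, False


def compute_scores(
    panel: DosagePanel, model: RiskModel, weight_scheme: str = "or"
) -> ScoreSet:
    """Sum risk-allele dosages into PRS and odds-ratio-weighted wPRS.

    ``panel`` must already be harmonized (every column counts the risk allele
    of the like-named model variant).  Weights are the per-variant odds ratio
    (``weight_scheme="or"``) or its natural log (``"log_or"``).  Missing
    dosages are imputed as ``2*eaf`` when the model carries an allele
    frequency, else as the cohort mean dosage at that variant, and counted
    per sample in ``n_dosages_imputed``.
    """
    if weight_scheme not in ("or", "log_or"):
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    if panel.n_variants == 0:
        raise ValueError("no variants retained after harmonization; cannot score")
    by_id = {v.variant_id: v for v in model}
    weights = np.empty(panel.n_variants)
    fill = np.empty(panel.n_variants)
    d = panel.dosage
    for j, vid in enumerate(panel.variants["variant_id"]):
        v = by_id.get(vid)
        if v is None:
            raise ValueError(f"panel variant {vid!r} not present in the risk model")
        weights[j] = v.odds_ratio if weight_scheme == "or" else np.log(v.odds_ratio)
        if v.eaf is not None:
            fill[j] = 2.0 * v.eaf
        else:
            col = d[:, j]
            m = np.nanmean(col)
            fill[j] = m if np.isfinite(m) else 0.0

    missing = np.isnan(d)
    filled = np.where(missing, fill[np.newaxis, :], d)
    prs = filled.sum(axis=1)
    wprs = filled @ weights
    scores = pd.DataFrame(
        {
            "prs": prs,
            "wprs": wprs,
            "n_dosages_imputed": missing.sum(axis=1).astype(int),
        },
        index=pd.Index(panel.sample_ids, name="sample_id"),
    )
    return ScoreSet(scores=scores, n_variants_used=panel.n_variants, weight_scheme=weight_scheme)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str


def compare_by_diagnosis(
    values: np.ndarray | pd.Series, diagnosis: np.ndarray | pd.Series
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparing scores between diagnosed and undiagnosed.

    Exact enumeration when both groups have at most 8 observations and no
    ties; otherwise the normal approximation with tie and continuity
    correction.  Reports the smaller of the two group statistics.
    """
    values = np.asarray(values, dtype=float)
    diagnosis = np.asarray(diagnosis, dtype=bool)
    x = values[diagnosis]
    y = values[~diagnosis]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both diagnosis groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    return MannWhitneyResult(u=u, p=float(res.pvalue), n1=len(x), n2=len(y), method=method)
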