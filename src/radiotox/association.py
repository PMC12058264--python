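"""Association battery: OLS fits of toxicity on polygenic risk, per site.

The battery mirrors a radiogenomics association analysis: STAT-acute and
STAT-late are regressed on the PRS and wPRS, each as a continuous predictor
and dichotomized above the cohort's 90th percentile, in univariable and
covariate-adjusted multivariable linear models; individual toxicity
endpoints are tested in multivariable models only, with a Bonferroni
correction over the site-and-timing endpoint family.  Prescription doses
enter multivariable models as biologically effective dose (BED) with
alpha/beta = 10 Gy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# covariate specification


@dataclass(frozen=True)
class Covariate:
    name: str
    kind: str  # continuous | binary | categorical

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass(frozen=True)
class CovariateSpec:
    """Preselected adjustment variables for one treatment site."""

    site: str
    covariates: tuple[Covariate, ...]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.covariates]


SITE_COVARIATES: dict[str, CovariateSpec] = {
    "prostate": CovariateSpec(
        "prostate",
        (
            Covariate("age", "continuous"),
            Covariate("diabetes", "binary"),
            Covariate("prior_surgery", "binary"),
            Covariate("hormone_therapy", "binary"),
            Covariate("bed", "continuous"),
        ),
    ),
    "lung": CovariateSpec(
        "lung",
        (
            Covariate("sex", "binary"),
            Covariate("age", "continuous"),
            Covariate("smoker", "binary"),
            Covariate("technique", "categorical"),
            Covariate("fev1", "continuous"),
            Covariate("v20_lungs", "continuous"),
            Covariate("v35_esophagus", "continuous"),
            Covariate("bed", "continuous"),
            Covariate("copd", "binary"),
        ),
    ),
    "breast": CovariateSpec(
        "breast",
        (
            Covariate("age", "continuous"),
            Covariate("smoker", "binary"),
            Covariate("cardiovascular_disease", "binary"),
            Covariate("bmi", "continuous"),
            Covariate("breast_volume", "continuous"),
            Covariate("diabetes", "binary"),
            Covariate("postop_infection", "binary"),
            Covariate("boost", "binary"),
        ),
    ),
}


# ---------------------------------------------------------------------------
# primitives


@dataclass(frozen=True)
class DoseSpec:
    """A fractionated prescription: total dose in Gy over n equal fractions."""

    total_dose: float
    n_fractions: int
    alpha_beta: float = 10.0

    def __post_init__(self) -> None:
        if not self.total_dose > 0:
            raise ValueError("total_dose must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if not self.alpha_beta > 0:
            raise ValueError("alpha_beta must be positive")


def bed_convert(dose: DoseSpec) -> float:
    """Biologically effective dose: BED = D * (1 + d/(alpha/beta)), d = D/n."""
    d = dose.total_dose / dose.n_fractions
    return dose.total_dose * (1.0 + d / dose.alpha_beta)


def bed_column(total_dose, n_fractions, alpha_beta: float = 10.0) -> np.ndarray:
    """Vectorized BED over prescription columns."""
    total_dose = np.asarray(total_dose, dtype=float)
    n_fractions = np.asarray(n_fractions, dtype=float)
    return total_dose * (1.0 + (total_dose / n_fractions) / alpha_beta)


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Family-wise threshold alpha/m, returned unrounded and at 3-decimal display."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    exact = alpha / m
    return exact, round(exact, 3)


def dichotomize_at_percentile(scores, q: float = 90.0) -> pd.Series:
    """Flag scores strictly above the linearly interpolated q-th percentile.

    Missing scores yield missing flags; at least 10 non-missing values are
    required for the quantile to be meaningful.
    """
    if not 0 < q < 100:
        raise ValueError(f"percentile must lie in (0,100), got {q}")
    s = pd.Series(scores, dtype=float)
    vals = s.dropna()
    if len(vals) < 10:
        raise ValueError(f"need >= 10 non-missing scores to dichotomize, got {len(vals)}")
    threshold = np.percentile(vals.to_numpy(), q)  # type-7 linear interpolation
    flags = s > threshold
    return flags.where(s.notna()).astype("boolean" if s.isna().any() else bool)


class RankDeficientDesignError(ValueError):
    """Raised when the design matrix is not full column rank."""


def fit_ols(y, design: pd.DataFrame) -> pd.DataFrame:
    """Exact least-squares fit with t-based inference per term.

    ``design`` holds the named model terms (no intercept column; one is
    added).  Rows with any missing value in y or the design are dropped
    first (complete case).  Returns one row per term (including the
    intercept) with ``beta, se, t, p, ci_low, ci_high`` and ``.attrs["n"]``
    set to the complete-case sample size; p and CI use the t distribution
    with n - k degrees of freedom.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=design.index, name="y")
    df = pd.concat([y, design], axis=1).dropna()
    n = len(df)
    X = sm.add_constant(df[design.columns].astype(float), has_constant="add")
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"need more observations ({n}) than model terms ({k})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        bad = _collinear_terms(X)
        raise RankDeficientDesignError(f"design is rank deficient; collinear terms: {bad}")
    fit = sm.OLS(df["y"], X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    out.attrs["n"] = n
    out.attrs["df_resid"] = int(fit.df_resid)
    return out


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    """Name the columns whose removal restores full rank."""
    cols = list(X.columns)
    bad = []
    arr = X.to_numpy()
    base_rank = np.linalg.matrix_rank(arr)
    for j, c in enumerate(cols):
        sub = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(sub) == base_rank:
            bad.append(c)
    return bad


# ---------------------------------------------------------------------------
# design-matrix assembly


def build_covariate_design(covariates: pd.DataFrame, spec: CovariateSpec) -> pd.DataFrame:
    """Numeric design columns for a site's preselected adjustment variables.

    Continuous and binary covariates pass through as floats; categorical
    covariates are reference-coded with the most frequent level as
    reference.  A ``bed`` covariate absent from the table is derived from
    ``total_dose`` and ``n_fractions`` prescription columns.
    """
    cols: dict[str, pd.Series] = {}
    for cov in spec.covariates:
        if cov.name == "bed" and "bed" not in covariates.columns:
            if not {"total_dose", "n_fractions"} <= set(covariates.columns):
                raise KeyError("covariate table lacks bed and total_dose/n_fractions")
            cols["bed"] = pd.Series(
                bed_column(covariates["total_dose"], covariates["n_fractions"]),
                index=covariates.index,
            )
            continue
        if cov.name not in covariates.columns:
            raise KeyError(f"covariate table lacks required column {cov.name!r}")
        col = covariates[cov.name]
        if cov.kind == "categorical":
            reference = col.mode(dropna=True).iloc[0]
            dummies = pd.get_dummies(col, prefix=cov.name, dtype=float)
            dummies.loc[col.isna(), :] = np.nan
            dummies = dummies.drop(columns=f"{cov.name}_{reference}")
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            cols[cov.name] = col.astype(float)
    return pd.DataFrame(cols, index=covariates.index)


# ---------------------------------------------------------------------------
# the battery


RESULT_COLUMNS = [
    "site",
    "outcome",
    "timing",
    "predictor",
    "transform",
    "model",
    "n",
    "beta",
    "ci_low",
    "ci_high",
    "p",
    "family_size",
    "alpha_adjusted",
    "significant",
]


def run_battery(
    scores: pd.DataFrame,
    stat: pd.DataFrame,
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    site: str,
    endpoints: dict[str, list[str]] | None = None,
    covariate_spec: CovariateSpec | None = None,
    alpha: float = 0.05,
    percentile: float = 90.0,
    use_delta_outcomes: bool | str = "auto",
) -> pd.DataFrame:
    """Run the full site association battery and return one row per test.

    Emits, joined on patient id with complete-case n per row:

    - STAT-acute and STAT-late x {prs, wprs} x {continuous, p90} x
      {univariable, multivariable}, each evaluated at ``alpha`` (family size 1);
    - every individual endpoint of the site's acute and late families x
      {prs, wprs} x {continuous, p90}, multivariable only, with
      ``alpha_adjusted = alpha / family_size`` over that site-timing family.

    Individual-endpoint outcomes use the baseline-adjusted delta when
    ``use_delta_outcomes`` engages it (same rule as STAT), else the raw
    window maximum.
    """
    from .toxicity import SITE_ENDPOINTS

    endpoints = endpoints or SITE_ENDPOINTS[site]
    spec = covariate_spec or SITE_COVARIATES[site]

    tables = [scores, stat, covariates]
    idx = scores.index
    for t in tables[1:]:
        idx = idx.intersection(t.index)
    n_union = max(len(t) for t in tables)
    if len(idx) < 0.5 * n_union:
        raise ValueError(
            f"join on patient_id keeps {len(idx)} of {n_union} patients; "
            "likely a key mismatch between input tables"
        )
    scores = scores.loc[idx]
    stat = stat.loc[idx]
    covariates = covariates.loc[idx]
    logger.info("battery join: %d patients at site %s", len(idx), site)

    cov_design = build_covariate_design(covariates, spec)

    predictors: dict[tuple[str, str], pd.Series] = {}
    for name in ("prs", "wprs"):
        cont = scores[name].astype(float)
        predictors[(name, "continuous")] = cont
        predictors[(name, "p90")] = dichotomize_at_percentile(cont, percentile).astype(float)

    rows: list[dict] = []

    def _fit_row(outcome_name, timing, y, pred_key, model, family_size):
        pred = predictors[pred_key]
        design = pred.rename("score").to_frame()
        if model == "multivariable":
            design = pd.concat([design, cov_design], axis=1)
        res = fit_ols(y, design)
        est = res.loc["score"]
        a_adj = alpha / family_size
        rows.append(
            {
                "site": site,
                "outcome": outcome_name,
                "timing": timing,
                "predictor": pred_key[0],
                "transform": pred_key[1],
                "model": model,
                "n": res.attrs["n"],
                "beta": est["beta"],
                "ci_low": est["ci_low"],
                "ci_high": est["ci_high"],
                "p": est["p"],
                "family_size": family_size,
                "alpha_adjusted": a_adj,
                "significant": bool(est["p"] < a_adj),
            }
        )

    # STAT outcomes: all four predictor forms, uni- and multivariable, alpha unadjusted
    for timing in ("acute", "late"):
        y = stat[f"stat_{timing}"]
        for pred_key in predictors:
            for model in ("univariable", "multivariable"):
                _fit_row(f"stat_{timing}", timing, y, pred_key, model, family_size=1)

    # individual endpoints: multivariable only, Bonferroni over the family
    for timing in ("acute", "late"):
        family = endpoints[timing]
        m = len(family)
        for ep in family:
            y = _endpoint_outcome(summaries, ep, timing, use_delta_outcomes).reindex(idx)
            if y.notna().sum() < 3:
                logger.warning("endpoint %s (%s) has <3 observations; skipped", ep, timing)
                continue
            for pred_key in predictors:
                _fit_row(ep, timing, y, pred_key, "multivariable", family_size=m)

    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _endpoint_outcome(summaries, endpoint, timing, use_delta) -> pd.Series:
    sub = summaries[summaries["endpoint"] == endpoint].set_index("patient_id")
    max_col, delta_col = f"{timing}_max", f"{timing}_delta"
    if sub.empty:
        return pd.Series(dtype=float)
    if use_delta in (True, "on"):
        engage = True
    elif use_delta in (False, "off"):
        engage = False
    else:
        have = sub[sub[max_col].notna()]
        engage = bool(len(have)) and have["baseline_grade"].notna().mean() >= 0.8
    return (sub[delta_col] if engage else sub[max_col]).astype(float)
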