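"""CTCAE grade summarisation and standardized total average toxicity (STAT).

Longitudinal toxicity records carry one CTCAE grade (0-4) per patient,
endpoint and visit day.  Day 0 anchors the end of radiotherapy: records at
day <= 0 are baseline, the acute window is days 1-90 (within three months)
and the late window days 91-730 (three months to two years).  Per patient
and endpoint we take the maximum grade in each window; where a baseline is
available a delta measure floors the window maximum minus baseline at zero,
so only increases are attributed to radiotherapy.

STAT pools endpoints into one per-patient overall-toxicity measure: each
endpoint's chosen value is z-standardized across the cohort (sample sd,
n-1) and a patient's STAT is the mean of their available z-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GRADES = frozenset(range(5))

#: per-site endpoint families; family size sets the Bonferroni denominator
SITE_ENDPOINTS: dict[str, dict[str, list[str]]] = {
    "prostate": {
        "acute": [
            "urinary_frequency",
            "nocturia",
            "urinary_urgency",
            "hematuria",
            "urinary_incontinence",
            "decreased_stream",
            "dysuria",
            "gi_incontinence",
            "diarrhea",
            "gi_urgency",
            "tenesmus",
            "gi_pain",
            "rectal_bleeding",
            "constipation",
        ],
        "late": ["proctitis", "rectal_bleeding", "hematuria", "urinary_frequency", "urinary_retention"],
    },
    "lung": {
        "acute": ["cough", "dyspnea", "pneumonitis", "dysphagia", "esophagitis"],
        "late": ["cough", "dyspnea", "pneumonitis", "dysphagia", "esophagitis"],
    },
    "breast": {
        "acute": ["erythema", "ulceration"],
        "late": [
            "telangiectasia",
            "telangiectasia_tumor_bed",
            "edema",
            "induration",
            "induration_tumor_bed",
            "pigmentation",
            "atrophy",
        ],
    },
}


@dataclass(frozen=True)
class Windows:
    """Time windows in days relative to the last radiotherapy fraction."""

    baseline_max_day: int = 0
    acute: tuple[int, int] = (1, 90)
    late: tuple[int, int] = (91, 730)

    def __post_init__(self) -> None:
        if not (self.baseline_max_day < self.acute[0] <= self.acute[1] < self.late[0] <= self.late[1]):
            raise ValueError(f"windows must be ordered and disjoint: {self}")


def load_toxicity_records(path) -> pd.DataFrame:
    """Read a long-format toxicity TSV (patient_id, endpoint, day, grade)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "endpoint": str})
    required = {"patient_id", "endpoint", "day", "grade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"toxicity table {path} lacks columns: {sorted(missing)}")
    return df


def summarize_endpoints(
    records: pd.DataFrame, windows: Windows = Windows(), vocabulary: list[str] | None = None
) -> pd.DataFrame:
    """Collapse longitudinal grades into per patient-endpoint window summaries.

    Returns one row per observed patient x endpoint with columns
    ``baseline_grade`` (latest record at day <= 0), ``acute_max``,
    ``late_max`` and the floored deltas ``acute_delta``, ``late_delta``.
    Windows with no record yield NaN, never 0.  Deltas without a baseline
    fall back to the raw window maximum.
    """
    if records.empty:
        raise ValueError("no toxicity records supplied")
    bad = ~records["grade"].isin(VALID_GRADES)
    if bad.any():
        row = records[bad].iloc[0]
        raise ValueError(
            f"grade {row['grade']!r} outside 0-4 for patient {row['patient_id']} "
            f"endpoint {row['endpoint']} day {row['day']}"
        )
    if vocabulary is not None:
        unknown = set(records["endpoint"]) - set(vocabulary)
        if unknown:
            raise ValueError(f"endpoints outside the configured vocabulary: {sorted(unknown)}")

    df = records.copy()
    keys = ["patient_id", "endpoint"]

    base = df[df["day"] <= windows.baseline_max_day]
    # latest baseline record wins
    base = base.sort_values("day").groupby(keys, sort=False)["grade"].last()
    acute = df[df["day"].between(*windows.acute)].groupby(keys, sort=False)["grade"].max()
    late = df[df["day"].between(*windows.late)].groupby(keys, sort=False)["grade"].max()

    out = pd.concat(
        {"baseline_grade": base, "acute_max": acute, "late_max": late}, axis=1
    ).reset_index()
    for timing in ("acute", "late"):
        mx = out[f"{timing}_max"]
        delta = mx - out["baseline_grade"].fillna(0)
        out[f"{timing}_delta"] = np.maximum(delta, 0).where(mx.notna())
    return out


def compute_stat(
    summaries: pd.DataFrame,
    endpoint_set: list[str],
    timing: str,
    use_delta: str | bool = "auto",
    baseline_coverage_min: float = 0.8,
) -> pd.DataFrame:
    """Pool endpoint grades into per-patient STAT scores.

    For every endpoint in ``endpoint_set`` the chosen value (the
    baseline-adjusted delta where engaged, else the raw window maximum) is
    z-standardized across patients with non-missing values; a patient's STAT
    is the mean of their available z-values.  ``use_delta="auto"`` engages
    deltas per endpoint only when at least ``baseline_coverage_min`` of
    patients with a window value also have a baseline.  Endpoints with zero
    variance carry no ranking information and are dropped with a logged
    reason; patients with no available endpoint get NaN.

    Returns a DataFrame indexed by patient with columns ``stat`` and
    ``n_endpoints``; dropped endpoints are recorded in ``.attrs["dropped"]``.
    """
    if timing not in ("acute", "late"):
        raise ValueError(f"timing must be 'acute' or 'late', got {timing!r}")
    if not endpoint_set:
        raise ValueError("endpoint_set is empty")
    if use_delta not in ("auto", True, False, "on", "off"):
        raise ValueError(f"use_delta must be auto/on/off, got {use_delta!r}")
    patients = summaries["patient_id"].unique()
    if len(patients) < 2:
        raise ValueError("STAT needs at least 2 patients")

    max_col, delta_col = f"{timing}_max", f"{timing}_delta"
    zcols: dict[str, pd.Series] = {}
    dropped: list[tuple[str, str]] = []
    for ep in endpoint_set:
        sub = summaries[summaries["endpoint"] == ep].set_index("patient_id")
        if sub.empty:
            dropped.append((ep, "no data"))
            continue
        have = sub[sub[max_col].notna()]
        if use_delta in (True, "on"):
            engage = True
        elif use_delta in (False, "off"):
            engage = False
        else:
            cov = have["baseline_grade"].notna().mean() if len(have) else 0.0
            engage = cov >= baseline_coverage_min
            if not engage and len(have):
                logger.warning(
                    "endpoint %s: baseline coverage %.0f%% < %.0f%%; using raw %s maxima",
                    ep, 100 * cov, 100 * baseline_coverage_min, timing,
                )
        vals = have[delta_col] if engage else have[max_col]
        vals = vals.dropna()
        if len(vals) < 2:
            dropped.append((ep, "fewer than 2 patients with data"))
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            dropped.append((ep, "zero variance"))
            logger.info("endpoint %s dropped from STAT-%s: zero variance", ep, timing)
            continue
        zcols[ep] = (vals - vals.mean()) / sd

    if not zcols:
        raise ValueError(f"no usable endpoints for STAT-{timing}; dropped: {dropped}")
    z = pd.DataFrame(zcols).reindex(patients)
    out = pd.DataFrame(
        {"stat": z.mean(axis=1, skipna=True), "n_endpoints": z.notna().sum(axis=1)},
    )
    out.index.name = "patient_id"
    out.attrs["dropped"] = dropped
    out.attrs["timing"] = timing
    return out


def stat_table(
    summaries: pd.DataFrame,
    site: str,
    use_delta: str | bool = "auto",
    endpoints: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: STAT-acute and STAT-late side by side for a site."""
    eps = endpoints or SITE_ENDPOINTS[site]
    acute = compute_stat(summaries, eps["acute"], "acute", use_delta=use_delta)
    late = compute_stat(summaries, eps["late"], "late", use_delta=use_delta)
    out = pd.DataFrame(
        {
            "stat_acute": acute["stat"],
            "n_endpoints_acute": acute["n_endpoints"],
            "stat_late": late["stat"],
            "n_endpoints_late": late["n_endpoints"],
        }
    )
    out.attrs["dropped_acute"] = acute.attrs["dropped"]
    out.attrs["dropped_late"] = late.attrs["dropped"]
    return out
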