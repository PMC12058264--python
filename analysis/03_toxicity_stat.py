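#!/usr/bin/env python
"""Summarize CTCAE records and compute STAT-acute / STAT-late per cohort.

Collapses each simulated cohort's longitudinal grades into window maxima and
baseline-adjusted deltas, pools them into STAT scores, reports the skewness
of the STAT distributions (expected right-sided: a small tail of patients
with severe toxicity), and draws histograms to results/figures/.
"""

import pandas as pd
from pathlib import Path
from scipy.stats import skew

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from radiotox.toxicity import load_toxicity_records, stat_table, summarize_endpoints

ROOT = Path(__file__).resolve().parent.parent / "results"
figdir = ROOT / "figures"
figdir.mkdir(parents=True, exist_ok=True)

for site in ("prostate", "lung", "breast"):
    d = ROOT / "cohorts" / site
    records = load_toxicity_records(d / "toxicity.tsv")
    summaries = summarize_endpoints(records)
    summaries.to_csv(d / "endpoint_summaries.tsv", sep="\t", index=False)
    table = stat_table(summaries, site)
    table.to_csv(d / "stat.tsv", sep="\t")
    sk_a = skew(table["stat_acute"].dropna())
    sk_l = skew(table["stat_late"].dropna())
    print(f"{site}: STAT-acute skew {sk_a:+.2f}, STAT-late skew {sk_l:+.2f}")

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, col in zip(axes, ("stat_acute", "stat_late")):
        ax.hist(table[col].dropna(), bins=40, color="steelblue")
        ax.set_xlabel(col)
        ax.set_ylabel("patients")
    fig.suptitle(f"{site}: STAT distributions")
    fig.tight_layout()
    fig.savefig(figdir / f"stat_hist_{site}.png", dpi=120)
    plt.close(fig)
print("histograms in", figdir)
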