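#!/usr/bin/env python
"""Score each simulated cohort and compare PRS by rheumatoid-arthritis diagnosis.

Loads each cohort bundle written by 01_simulate_cohorts.py, harmonizes the
dosage panel to the risk model, computes PRS/wPRS, then draws a documented-RA
flag at a realistic ~2% prevalence independent of the score — emulating the
observed condition that patients with a documented diagnosis showed no
shift in the score distribution — and runs the Mann-Whitney U contrast of
PRS by diagnosis.  Writes scores.tsv and harmonization.tsv per site and a
summary table results/prs_by_diagnosis.tsv.
"""

import numpy as np
import pandas as pd
from pathlib import Path

from radiotox.io import read_dosage_tsv
from radiotox.risk import compare_by_diagnosis, compute_scores, harmonize_dosages, load_risk_model

ROOT = Path(__file__).resolve().parent.parent / "results"
rows = []
for site in ("prostate", "lung", "breast"):
    d = ROOT / "cohorts" / site
    model = load_risk_model(d / "risk_model.tsv")
    panel = read_dosage_tsv(d / "dosages.tsv")
    harmonized, report = harmonize_dosages(panel, model)
    scores = compute_scores(harmonized, model)
    scores.to_tsv(d / "scores.tsv")
    report.to_csv(d / "harmonization.tsv", sep="\t", index=False)

    import zlib

    n = len(scores.scores)
    rng = np.random.default_rng(zlib.crc32(site.encode()))
    # documented RA diagnosis at ~2% prevalence, independent of the score
    diagnosed = rng.random(n) < 0.02
    mw = compare_by_diagnosis(scores.scores["prs"], diagnosed)
    rows.append(
        {"site": site, "n": n, "n_diagnosed": int(diagnosed.sum()),
         "mannwhitney_u": mw.u, "p": mw.p}
    )
    print(f"{site}: {diagnosed.sum()}/{n} diagnosed, Mann-Whitney p={mw.p:.3f}")

pd.DataFrame(rows).to_csv(ROOT / "prs_by_diagnosis.tsv", sep="\t", index=False)
print("wrote", ROOT / "prs_by_diagnosis.tsv")
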