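# Methods

## Polygenic risk score

The score is the additive dosage sum over a fixed set of biallelic risk
loci: PRS(s) = Σ_v d_sv, with the weighted variant wPRS(s) = Σ_v w_v·d_sv.
The default weight is the per-allele odds ratio itself (w_v = OR_v),
reproducing the convention the analysis this package implements was run
under; `weight_scheme="log_or"` switches to the ln(OR) weighting that is
more common elsewhere.  Since both weightings are strictly monotone
transforms of the same dosage information their z-scores are highly
correlated, and nothing downstream depends on the choice beyond the scale
of the coefficient.

No shrinkage, LD-pruning or P+T selection is applied: the model is a fixed
published locus list, not a genome-wide score, and the package deliberately
stops at the additive dosage sum.

### Harmonization

Genotype files orient each variant's dosage to an arbitrary allele.  For
every model locus the panel's allele pair is classified against the model's
(risk, other) pair in four steps — exact match, allele swap, strand flip
(reverse complement), flip + swap — and the dosage is re-expressed as a
risk-allele count (d or 2 − d).  Decisions and edge rules:

- **Palindromic (A/T, C/G) loci** cannot be strand-resolved from labels.
  Default behaviour keeps them under exact-label matching, on the assumption
  that a single imputation pipeline produced reference-strand calls;
  `drop_ambiguous=True` excludes them.  With allele frequencies available a
  frequency-based resolution would be possible; it is deliberately not
  attempted (silent, frequency-dependent flips are a worse failure mode
  than an explicit drop).
- **Matching key** is `variant_id` first with a `chrom:pos` fallback;
  duplicated keys in the panel are treated as unmatched.  All anomalies
  become report statuses, never exceptions: applying a fixed score to an
  arbitrary file must degrade gracefully and auditable, so the report
  carries exactly one status per model locus.
- **Missing dosages** are imputed as 2·EAF when the model records an
  effect-allele frequency, else as the cohort mean dosage at the locus, and
  counted per sample.  This keeps every sample's score on the same scale
  (dropping loci per-sample would not); the count lets users filter
  heavily-imputed samples.
- Dosages outside [0, 2] by ≤ 1e-6 are clamped (float serialization noise);
  larger excursions raise, since they indicate a corrupt file.

### Diagnosis contrast

`compare_by_diagnosis` is the two-sided Mann–Whitney U comparing scores
between patients with and without a documented RA diagnosis.  With both
groups ≤ 8 and no ties the exact null enumeration is used; otherwise the
normal approximation with tie and continuity correction (both via
`scipy.stats.mannwhitneyu`).  The reported U is the smaller group statistic.

## Toxicity windows and STAT

Day 0 anchors the **end** of radiotherapy; records at day ≤ 0 are baseline
(latest wins), acute is days 1–90 and late 91–730.  The windows partition
days 1–730, so no record is double-counted.  An empty window yields a
missing value, never grade 0 — absence of follow-up is not absence of
toxicity.  The delta measure max(window max − baseline, 0) attributes only
*increases* to radiotherapy; without a baseline the raw window maximum is
used.

STAT z-standardizes each endpoint's chosen value across patients with
non-missing values (sample sd, n − 1, declared so tests are exact) and
averages the available z-values per patient.  Consequences worth knowing:

- with complete data the cohort STAT mean is 0 to numerical precision, and
  STAT is invariant to per-endpoint affine transforms of the grades;
- zero-variance endpoints carry no ranking information and are dropped with
  a logged reason rather than contributing 0/0;
- patients missing some endpoints average over the rest (their STAT has
  higher variance; n_endpoints is reported so users can filter);
- the standardization population is the analysis cohort itself, per site —
  STAT values are therefore comparable within a cohort, not across cohorts.

`use_delta="auto"` engages the delta per endpoint only when ≥ 80% of
patients with a window value also have a baseline; below that the raw
maxima are used with a warning, since a delta computed for a small baseline
subset would silently change the estimand mid-endpoint.

## Association battery

All fits are ordinary least squares (statsmodels) with exact t-based
inference (p and 95% CI on n − k df) after complete-case row deletion;
rank-deficient designs raise with the collinear terms named.  The 90th
percentile dichotomization uses the linear-interpolation (type-7) quantile
and flags values *strictly* above the threshold, so a cohort of identical
scores flags nobody.  Categorical covariates are reference-coded with the
most frequent level as reference — an arbitrary but deterministic rule.
Prescription dose enters as BED = D(1 + d/(α/β)) with α/β = 10 Gy.

The STAT analyses are evaluated at α = .05 unadjusted; the Bonferroni
correction α/m applies to the individual-endpoint families per site and
timing (m = 14/5 for prostate acute/late, 5/5 lung, 2/7 breast).
Thresholds are compared at full precision; the 3-decimal rounding (.004,
.01, .007) is display-only, avoiding threshold artifacts for p-values near
the boundary.

## Synthetic cohorts

The generator emulates the study conditions the pipeline is meant for:
site-sized cohorts (defaults n = 500 for calibration work; the analysis
scripts use 1494/483/1820), a 101-locus model with EAF ~ U(0.05, 0.95) and
ln OR ~ N(0, 0.1), Hardy–Weinberg genotypes (Binomial(2, EAF)) with
optional N(0, 0.05) imputation noise, and per-site covariates with
plausible clinical marginals drawn from small sets of standard
fractionation regimens.

Toxicity grades come from a latent-variable threshold model: per patient,
endpoint and visit, L = covariate term + γ·z(wPRS) + ε, with
ε = N(0, 1) + (Gamma(2, 0.5) − 1) — a right-skewed, mean-zero mixture
chosen as the simplest two-parameter mechanism that reproduces the
right-sided skew of observed overall-toxicity distributions.  The grade is
the count of thresholds (default 0.8, 1.8, 2.8, 3.8) below L, giving a
majority of grade 0–1 records and < 5% grade ≥ 3 under the null.  Baseline
visits (day −7) are drawn with γ = 0; visits are fixed at days 14/45/80
(acute) and 180/365/540/720 (late) so window maxima are exactly predictable
in tests.  There is no LD, population structure, relatedness, dropout or
informative censoring — the scoring and regression machinery is insensitive
to LD, and independence keeps analytic expectations available for tests.
Passing tests therefore validate the pipeline's statistical behaviour, not
robustness to real-data pathologies like batch effects or ancestry
confounding.

The packaged `ra_101_synthetic.tsv` model is one fixed draw from this
generator (synthetic, as the filename says): it matches the real RA locus
list in size and schema so the scoring path is exercised identically, but
its positions, alleles, frequencies and odds ratios are simulated.

## Calibration studies

Two Monte-Carlo studies (module `radiotox.calibration`) characterize the
battery over replicate cohorts sharing the packaged model:

- **Null size** — 1000 cohorts (n = 500, γ = 0); the STAT-acute
  continuous-PRS multivariable p < .05 rate should sit in the 99% binomial
  band around 0.05.  Measured ≈ 0.05 with approximately uniform p-values.
- **Effect recovery** — 200 cohorts (n = 2000) with γ = 0.3 planted per
  standardized wPRS unit; the multivariable estimate should be unbiased
  with ~95% CI coverage.  Recovery is assessed on the *latent* outcome
  recorded in the cohort truth file (the realized per-patient mean latent
  value over acute visits): ordinal CTCAE thresholding attenuates slopes on
  the grade scale by a factor that depends on the grade distribution, so
  the grade-scale coefficient is a different (smaller) estimand than γ by
  construction, not by defect.  On the latent scale the mean estimate lands
  within a fraction of a percent of γ with coverage ≈ 0.95.

Replicate counts were chosen to keep each study within a few minutes on one
CPU while leaving the binomial noise well inside the stated bands.

## Known limitations

- Palindromic-variant handling assumes a strand-consistent imputation
  pipeline when `drop_ambiguous` is off.
- STAT with partially missing endpoints is a mean of fewer z-values, not a
  re-standardized score; its variance is patient-dependent.
- The battery fits linear models to bounded ordinal outcomes, as the
  analysis it implements did; it makes no claim that residuals are Gaussian
  (the calibration shows the resulting tests are nonetheless well-sized at
  the cohort sizes used).
- Toxicity beyond 730 days, mixed-effects trajectories, partitioned risk
  scores and spatial dose modelling are out of scope.
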