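# Methods

`thyroht` implements a complete analysis chain for predicting biochemical
hypothyroidism (HT) after intensity-modulated radiotherapy of the neck,
driven by thyroid dose-volume metrics. This note records the models, the
defaults, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Dose-band metrics

The input per patient is a cumulative dose-volume histogram (DVH): the
percentage `V(d)` of thyroid volume receiving at least `d` Gy, plus the
absolute gland volume in cm³. From it we evaluate the classical nested
metrics `V_x` for x = 10..60 Gy by linear interpolation on the cumulative
curve ("more than x" and "at least x" coincide on a continuous curve, so no
strictness convention is needed). Because `V_10 ⊇ V_20 ⊇ …`, the nested
metrics are strongly collinear; the analysis therefore works with the
disjoint 10-Gy **band metrics**

    V_0,10 = 100 − V_10,   V_a,b = V_a − V_b   (a, b adjacent decades),

which, together with the >60 Gy residual, partition the gland: they sum to
100% by construction (enforced to 1e−6). Aggregate bands such as
`V_30,60 = V_30 − V_60` equal the sum of their constituent 10-Gy bands;
this identity is asserted rather than assumed. Validation is strict
throughout — a non-monotone curve or band vector raises instead of being
repaired, so generator or parsing bugs surface immediately.

Doses beyond the last grid point evaluate to 0%; doses between 0 Gy and the
first positive grid point interpolate from (0, 100%). DVH files are
two-column delimited text (comma or tab, auto-detected), rows re-sorted by
dose, duplicate doses rejected with the offending value named.

## Endpoint and survival summaries

Time to HT runs from the end of radiotherapy to the first TSH elevation;
patients without HT are censored at last follow-up or death (death is
censoring — no competing-risk estimator, deliberately). The primary
endpoint is HT within a fixed horizon, default 24 months. Patients censored
*strictly before* the horizon carry no information about the binary
endpoint and are excluded (and counted); an event at exactly the horizon
counts as within it, and censoring at exactly the horizon is retained —
the boundary convention that maximizes data retention.

Cumulative incidence is 1 minus the Kaplan-Meier survivor function
(lifelines); groups are compared by the two-group log-rank test. Baseline
comparisons between patients with and without 2-year HT use the Wilcoxon
rank-sum test for continuous variables (summaries are median/IQR, so a
rank test, not a t-test) and the Pearson chi-square without continuity
correction for categorical ones (correction is exposed as an option).
Collinearity among band metrics is diagnosed with pairwise Spearman rho
(midrank ties); a constant column yields a missing correlation, never 0.

## Predictor selection

Candidates are thyroid volume plus the six disjoint bands. The chain:

1. **Univariate screen** — one single-predictor logistic fit per candidate,
   flagged at Wald p < 0.05. Per-predictor failures are recorded, not fatal.
2. **LASSO** — L1-penalized logistic regression on internally standardized
   predictors (mean 0, sd 1). The penalty is a glmnet-style lambda
   (mean deviance + λ‖β‖₁); it is chosen by 10-fold cross-validated
   deviance with a fixed, seed-derived fold assignment. The default rule is
   the minimum-mean-deviance lambda; the sparser 1-SE rule is exposed as an
   option. The min rule is deliberately anti-sparse — it reliably retains
   true effects but often keeps noise predictors; the 1-SE rule is the one
   that achieves near-perfect sparsity in our selection-consistency checks.
   An all-zero solution is a valid empty selection, not an error.
3. **Backward elimination** — iterative refitting, dropping the predictor
   with the largest Wald p ≥ 0.05 (ties: larger p, then lexically larger
   name) until all survivors are significant. The trace of strictly nested
   candidate sets is recorded.

Odds ratios are reported per stated increment — per cm³ for volume, per
10 percentage points for bands — with Wald 95% intervals (matching the
presentation convention of clinical dose-response tables). Fits use
statsmodels maximum likelihood; (quasi-)perfect separation is detected (a
runaway coefficient or a singular Hessian) and raised explicitly naming the
predictors, never silently returned.

## Threshold-dose inference

The biological model: thyroid follicles are independent functional units
destroyed above some threshold dose, so the best dose predictor should be
the volume fraction between that threshold and the top of the clinical
dose range. Three candidate aggregates — `V_40,50`, `V_30,60`, `V_40,60` —
are each paired with thyroid volume in a two-variable logistic model; the
models are compared by the area under the ROC curve of their fitted linear
predictors, and the winner localizes the threshold.

AUC is the midrank Mann-Whitney statistic (ties weigh one half), computed
in-sample — matching a single-cohort analysis; cross-validated AUC is not
the default. The 95% interval uses the DeLong structural-components
variance (a symmetric Wald interval, clipped to [0, 1]). The midrank
implementation is verified against exhaustive case-control pair
enumeration to 1e−12. AUC ties between candidates are surfaced to the
caller, never silently broken.

The `threshold_recovery_experiment` closes the loop: cohorts are generated
with a known threshold and the comparison's win fractions are tabulated.
At the calibrated defaults (n = 2000 per replicate) the true-threshold
candidate wins a clear plurality (about 0.65–0.70 when 30 Gy is true,
about 0.90 for `V_40,60` when 40 Gy is true), and with no dose effect the
three candidates win roughly equally often — the comparison carries real
signal about the threshold, which is the premise the inference rests on.

## Cutpoints and risk strata

The final continuous predictors are dichotomized by a minimum-p scan:
every distinct observed value is a candidate cut (as "≤ cut" vs "> cut"),
cuts leaving under 10% of subjects on either side are excluded, and the
cut minimizing the chi-square p of the 2×2 table against the 2-year
endpoint wins (ties go to the smallest cut). Because the scanned minimum p
is strongly anti-conservative, the Miller-Siegmund corrected p over the
scanned quantile window is reported alongside it; below the z = 1 validity
bound of the asymptotic formula the corrected p is reported as 1. The scan
uses the binary fixed-horizon endpoint in a chi-square test rather than a
survival log-rank — with a fixed-horizon binary endpoint the two coincide
in intent, and the chi-square admits an exact brute-force oracle.

Crossing the volume cut with the band cut yields four risk cohorts with
per-cohort n, events and exact incidence (rounded only at presentation);
boundary values fall on the "≤" side. Merging similar cohorts is
caller-directed with provenance recorded — no automatic similarity rule.
Per-stratum Kaplan-Meier curves and pairwise log-rank tests cover the full
follow-up. A row-level fixture rebuilt from the published four-cohort
counts of the reference NPC cohort (n = 545; only the counts are real,
the row values are labelled placeholders) validates the stratification
arithmetic exactly: 8.0 / 13.8 / 19.9 / 36.8%, merged low-risk 11.7%,
overall 25.3%.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline is validated.

| parameter | default | meaning |
|---|---|---|
| `tv_mean`, `tv_sd`, `tv_min` | 16, 4.5, 4 cm³ | thyroid volume ~ truncated normal |
| `dvh_midpoint_mean/sd` | 47, 6 Gy | per-patient sigmoid DVH midpoint |
| `dvh_steepness_mean/sd/min` | 6, 1.5, 0.5 Gy | sigmoid steepness (resampled below min) |
| `true_threshold` | 30 Gy | dose above which follicle damage accrues |
| `beta0` | −1.3161 | intercept of the 2-year HT logistic |
| `beta_tv` | ln 0.94 /cm³ | protective volume effect |
| `beta_band` | ln 1.16 /10% | harmful effect of V_threshold,60 |
| `weibull_shape/scale` | 1.6, 30.43 mo | latent event-time law (median ≈ 24.2 mo) |
| `late_event_rate` | 0.34 | HT after the horizon among 2-year non-events |
| `censor_rate` | 0.10 | early-dropout fraction, Uniform(6, 60) mo |
| `admin_entry_months` | 24 | administrative close-out ~ Uniform(24, 60) mo |

The DVH is a two-parameter sigmoid in dose, rescaled to 100% at 0 Gy and
0% at 70 Gy on a 1-Gy grid — monotone by construction, concentrating dose
mass in the 30–60 Gy range typical of neck irradiation without
thyroid-specific planning constraints. Under the defaults the simulated
volume median is ≈ 16 cm³ (IQR ≈ 13–19), the `V_40,50` median ≈ 34%, and
≈ 58% of patients exceed 80% on `V_30,60` — bracketing the values reported
for real NPC cohorts.

The outcome model parameterizes the **2-year HT probability directly**:
p = expit(β₀ + β_tv·volume + β_band·V_threshold,60/10), with the intercept
solved numerically so the marginal 2-year rate is 25.3% at the default
laws. This choice makes the generative coefficients the exact estimand of
the two-variable logistic fit on the 2-year endpoint, so parameter
recovery is a clean test of the estimation chain (bias < 10%, coverage
≈ 95% at n = 2000 over 200 replicates). Event times for 2-year events are
Weibull draws conditioned inside the horizon; late events (covariate-
independent, rate 0.34) keep the cumulative incidence rising after 2 years
with the latent median time-to-HT near 24 months. Censoring combines
administrative close-out with a small early-dropout fraction, producing a
realistic ~3% excluded-within-horizon rate. Clinical covariates (age, sex,
stage, chemotherapy) are drawn independently of outcome by default; an
optional `covariate_effects` flag adds a younger-age/female excess risk
for exercising the baseline-comparison machinery.

What the generator does **not** emulate: anatomical dose gradients and
planning constraints (the sigmoid family is one plausible emulation of
cumulative DVH shapes, not a dose-calculation model); TSH assay dynamics
(the event is consumed as a binary diagnosis plus date); any dependence of
censoring or late events on covariates; inter-metric correlation structure
beyond what the shared sigmoid induces. Passing tests on synthetic cohorts
therefore demonstrate the *internal validity* of the estimation chain —
they do not certify the clinical coefficient values, which only the
restricted patient data could.

## Numerical and reproducibility choices

- Stage seeds are derived by hashing (global seed, stage name) with
  blake2b, truncated below 2³¹, so adding a stage never perturbs earlier
  stages and a run is reproducible byte-for-byte from one integer.
- L1 fits use liblinear with a pinned internal seed; CV folds are
  stratified with a fixed, seed-derived assignment.
- The logistic separation guard triggers on |coef| > 20 on the working
  scale or a singular Hessian.
- Band conservation and aggregate identities use absolute tolerance 1e−6;
  the AUC-vs-enumeration oracle is exact to 1e−12.
- Cutpoint scan tie-break: smallest cut; candidate-model AUC tie-break:
  surfaced as a tie (deterministic label order only for reporting).
- Degenerate inputs fail loudly: empty cohorts, single-class outcomes,
  constant markers and inadmissible cuts all raise; an all-censored KM
  input returns a flagged zero curve with a warning.

## Known limitations

- In-sample (apparent) AUC overstates out-of-sample discrimination; the
  package offers no internal bootstrap validation of cutoffs, mirroring
  the single-cohort design it implements.
- The minimum-p cutoff remains data-dredging even with the
  Miller-Siegmund correction reported; corrected p is approximate (an
  asymptotic supremum bound, invalid below z = 1 where it saturates at 1).
- The Weibull/late-event construction reproduces marginal anchors (2-year
  rate, latent median time) but not the full shape of a real incidence
  curve; KM comparisons on synthetic data are qualitative.
- Problem sizes for the Monte-Carlo validations (200 replicates at
  n = 2000; 10,000 curves for conservation; 1,000 small datasets for the
  AUC oracle; 200 datasets for the cutpoint oracle) were chosen to make
  Monte-Carlo error small relative to the asserted margins.
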