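# Methods

## The diagnostic problem and the screening rule

Patients with a painful or failed total knee arthroplasty either have a
periprosthetic joint infection (PJI, defined by consensus criteria that
this package takes as the ground-truth label) or an aseptic failure.
The index test is the serum albumin-to-globulin ratio (AGR), a
dimensionless quantity from a routine biochemistry panel. Infection and
chronic inflammation lower albumin and raise globulins, so the screen
calls a patient **positive when AGR ≤ c**. The boundary value itself is
positive: with false negatives costed three times false positives, the
inclusive rule is the conservative tie-break toward sensitivity, and the
data never force the distinction (observing AGR exactly at the cutoff
has probability zero under the continuous model).

## Cost-weighted cutoff selection

For a cutoff c with false positives FP(c) and false negatives FN(c),
the objective is the misclassification cost

    L(c) = cost_FP · FP(c) + cost_FN · FN(c),   cost_FN / cost_FP = 3 by default.

Candidate cutoffs are midpoints between consecutive distinct marker
values plus a sentinel half a minimal gap outside each extreme, so each
candidate induces a distinct 2×2 table and every achievable table is
represented once. `optimal_cutoff_single` minimizes L exhaustively on
that grid; ties break toward the larger cutoff (more sensitive).

`bootstrap_optimal_cutoff` stabilizes the choice: B resamples of size N
drawn with replacement from the pooled cohort (the resample unit is the
patient; stratified resampling is available as an option), the cost
curve evaluated per replicate on the grid frozen from the original
sample, and the final cutoff minimizing the **mean** cost across
replicates. The mean-cost rule is a single deterministic minimization
consistent with the stated motivation for bootstrapping (stability);
the median and IQR of per-replicate minimizers are reported alongside as
a dispersion diagnostic. A replicate that happens to miss one class
contributes only the cost terms it has; at N = 237 such replicates are
astronomically rare and are counted, not redrawn. Cost evaluation uses
sorted-array bisection, O((N + G) log N) per replicate, so B = 1000 on
N = 237 runs in well under a second.

Under the calibrated study conditions the cost minimum is **shallow**:
with heavily overlapping groups and a 3:1 penalty, the expected cost of
the best interior cutoff (~104 per 237 patients) is only a few points
below the everyone-positive boundary (108). Bootstrap cutoffs on
study-sized cohorts therefore vary widely (replicate IQRs of ±0.2 are
typical) — an honest property of the problem, not an implementation
artifact, and the reason the selected cutoff is validated against a
closed-form oracle (below) rather than against a single published
number.

### Known-truth oracle

For two log-normal populations the expected cost is differentiable and
its minimizer solves the density-ratio condition
f_inf(c)/f_asep(c) = (cost_FP·n_asep)/(cost_FN·n_inf), a quadratic in
ln c; with σ_inf > σ_asep the smaller root (the decreasing branch of the
ratio) is the minimum. `lognormal_cost_optimal_threshold` implements
this closed form. The recovery test draws groups LN(0, 0.15) vs
LN(ln 1.6, 0.075) at n = 2000 per group — dispersions chosen tighter
than the study calibration so the cost minimum is sharply identified and
the test measures optimizer accuracy (within ±0.03 of the analytic
1.3815 across seeds) rather than the identifiability limit of a flat
objective.

## ROC and AUC

The empirical ROC uses the unique observed marker values as thresholds
plus ∓∞ sentinels, so the curve always spans (0,0)–(1,1). Ties take
simultaneous vertical-plus-horizontal steps; the trapezoidal area then
equals the Mann–Whitney concordance probability, which the test suite
asserts against an exhaustive pair-counting oracle. The default AUC
interval is DeLong's placement-value variance with a normal interval
clipped to [0,1]; a class-stratified percentile bootstrap (2000
replicates, seeded) is retained for comparison because asymmetric
intervals near 1 are better served by resampling.

## Diagnostic accuracy and intervals

Sensitivity, specificity, PPV, NPV and accuracy come from the 2×2 table
at the selected cutoff. Intervals are Clopper–Pearson exact
(Beta-quantile) by default — the method reproduces the published
sensitivity and specificity bands when fed the published counts — with
Wilson as an option. Rendered percentages round half-up to integers,
matching clinical-journal presentation; full-precision proportions are
always carried alongside in reports. PPV and NPV intervals are simple
binomial intervals at the cohort's prevalence and do not transport to
other prevalences; the prevalence identity
PPV = Se·π/(Se·π + (1−Sp)(1−π)) is enforced as a test invariant.

## Group statistics

- **Mann–Whitney U**: midranks for ties; exact enumeration when both
  n ≤ 8 and no ties, else normal approximation with tie-corrected
  variance and continuity correction (delegated to scipy). Null
  rejection rate at n = 40/group is ~4.8% at α = 0.05.
- **Chi-squared / Fisher**: Pearson chi-squared without continuity
  correction unless any expected cell < 5, then Fisher's exact
  (two-sided, summing tables no more probable than observed). The choice
  is recorded per row. A zero marginal degenerates to Fisher with p = 1.
- **Spearman**: Pearson correlation of midranks, t-approximation p with
  n − 2 df, complete-case pair dropping; constant inputs leave ρ
  undefined rather than raising.
- **Logistic regression**: IRLS (Newton) with step-halving so the
  log-likelihood is non-decreasing; convergence when max |score| < 1e−8
  or relative log-likelihood change < 1e−10, at most 50 iterations.
  Wald statistic (b/se)², df = 1, chi-squared p. Non-convergence,
  |b| > 15, or an exploding standard error (> 10³) flags the row as
  suspected separation instead of printing a silently meaningless
  estimate. The report design is "univariate age-adjusted": one model
  per focal confounder with age always included, one row per focal
  coefficient — the shape a single-coefficient-per-variable table
  implies, which a jointly-fitted multivariable model could not produce.

## The false-positive confounder analysis

Restricted to aseptic patients, split at the cutoff into false
positives and true negatives. Each confounder gets a Mann–Whitney (or
chi-squared/Fisher) comparison between strata; Spearman correlates AGR
with each confounder **across the whole aseptic subset** (the published
population for these correlations is ambiguous; the pooled choice keeps
the correlation estimable when one stratum is small and is configurable
in the API); and the age-adjusted logistic models take FP status as the
outcome. Degenerate strata raise errors naming the empty stratum.

## Synthetic cohort generator

What it emulates: two groups of fixed size (129 infected, 108 aseptic)
whose per-variable medians and IQRs match the published summary table —
age (years), sex (male proportion 40% vs 43%), BMI (kg/m²), CCI, ESR
(mm/h), CRP (mg/L), synovial WBC (cells/µL), synovial PMN (%), AGR.
Strictly positive right-skewed variables are log-normal with
μ = ln(median) (median reproduced exactly) and
σ = (ln Q3 − ln Q1)/(2·z₀.₇₅), z₀.₇₅ ≈ 0.67449 (log-IQR matched;
printed quartiles reproduced exactly only when log-symmetric — the
median is the headline statistic, so it gets the exact anchor). The
bounded PMN percentage uses the same calibration on logit(x/100); CCI
is a rounded log-normal clamped at 0; sex is Bernoulli per group.

Confounders with no published distribution (INR, creatinine, uremia,
GOT, GPT, ALP) default to adult reference-range log-normals identical in
both groups — INR 1.0 (0.94–1.08), creatinine 0.9 (0.75–1.1) mg/dL,
urea 35 (28–45) mg/dL, GOT 22 (17–28) U/L, GPT 20 (14–28) U/L, ALP 75
(60–95) U/L — so the confounder stage runs end to end under the null.

Covariates are independent within group by default; a Gaussian-copula
correlation matrix can be supplied for planted-confounder experiments
(latent multivariate normal pushed through each marginal transform).
Determinism: one stated seed; each variable draws from its own
deterministically spawned substream, so identical seeds give identical
cohorts and editing one variable's spec does not perturb the others.

What it does **not** emulate — and therefore what passing tests do not
establish about real data: joint correlation structure between
laboratory markers (independence is a simplification; the real AGR–ALP
or AGR–BMI dependence is unknown), measurement error and repeat visits,
the discreteness of recorded laboratory values, non-log-normal tail
behaviour, and any true confounder shift in the false-positive stratum.
Under the calibrated separation the implied AUC is
Φ((μ_asep−μ_inf)/√(σ_inf²+σ_asep²)) ≈ 0.82, bracketing checks use the
band [0.78, 0.88] around the published 0.85.

## Numerical choices and problem sizes

Tolerances: IRLS as above; CSV round-trips are exact to ≥ 6 significant
digits (`%.10g` formatting); interval bounds clipped to [0,1]; cost
ties broken toward sensitivity. Degenerate inputs raise (empty classes,
non-positive AGR, all-identical markers) or report absence (undefined
PPV, undefined ρ) as the operation's contract states.

Test-suite problem sizes are chosen to keep the full run under a minute
on one CPU while leaving Monte-Carlo error well inside the asserted
bands: calibration round-trips at n = 10⁵ per group (1% relative),
bootstrap cutoff recovery at n = 2000/group with B = 500, AUC
consistency over 200 study-sized cohorts, type-I error over 5000 null
replicates, coverage over 2000 binomial draws, IRLS recovery at
n = 5·10⁴.

## Known limitations

- The published cutoff 1.43 and AUC 0.85 came from unpublished
  patient-level data; nothing here can or does reproduce them directly.
  The synthetic substitutes validate the machinery, not the clinical
  numbers.
- The bootstrap aggregation rule (mean cost over replicates) is one
  reasonable reading of "bootstrap internal validation"; summaries of
  per-replicate minimizers are reported so users can compare.
- PPV/NPV intervals are prevalence-bound binomial intervals; no
  likelihood-based or logit-transformed alternatives are offered.
- The generator's reference-range confounders make the false-positive
  logistic stage a null experiment by construction; planted-effect
  cohorts must be built explicitly (see the copula option).
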