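# Methods

## The screening model

The Pro55+ score is a logistic prediction: each of the ten food items is
mapped through a coding table to a numeric value `x_i`, anthropometric
covariates (age in years, a female indicator with male as reference,
weight in kg, height in cm) are appended, and

```
linear predictor  η = β₀ + Σ β_i x_i + Σ β_c z_c
score             p = 1 / (1 + exp(−η))
```

is the predicted probability of protein intake below 1.0 g/kg adjusted
body weight per day. The equation is pure data: coding maps, coefficients,
the sex reference level and whether the weight covariate is raw or
adjusted weight all live in a YAML configuration, validated strictly on
load (missing or extra items are schema errors) and round-tripping
exactly through save/load. Scoring is pure and deterministic; a response
with any missing item is excluded, never imputed, matching how validation
studies handle incomplete questionnaires.

The **bundled configuration is a synthetic stand-in**. The published
coefficient values live in supplementary material that is not distributed
here, so the shipped file carries the instrument's structure with
placeholder values chosen on two principles: every food coefficient is
negative (more of a protein source lowers the predicted risk), and the
per-item steps form a graded ladder (0.85, 0.65, 0.50, 0.32, 0.24, 0.20,
0.16, 0.10, 0.07, 0.04 per category step). The ladder is deliberate: each
step is smaller than the total span of the steps below it, which lets the
synthetic generator express any achievable linear predictor by a greedy
item choice with error below the smallest step (see below). Analyses of
real questionnaires must supply the published configuration instead.

### Adjusted body weight

BMI = weight / height²; adjusted body weight (aBW) equals the measured
weight inside the BMI band [22, 27] kg/m², the weight at BMI 27 above it,
and the weight at BMI 22 below it. Hence 22·h² ≤ aBW ≤ 27·h² and the
operation is idempotent. aBW is the denominator of the reference intake.

## Reference standard and eligibility

Per-day nutrient totals are averaged arithmetically over the recorded
days (three expected, any positive number accepted); protein intake in
g/kg aBW/d is classified low by strict `< threshold` with thresholds 1.0
and 0.8 g/kg aBW/d. Energy percentages use Atwater factors 4/9/4 kcal per
gram of protein/fat/carbohydrate (the conventional choice; other factor
sets shift E% by well under a point).

Eligibility filters: MMSE ≥ 24; no tube-feeding flag (an input column,
never inferred from intake); mean energy within the sample mean ± 3
sample standard deviations (n−1 SD, inclusive bounds, computed in a
single pass on the submitted sample — the band is not re-estimated after
exclusions; a zero-SD sample passes everyone); complete questionnaire and
dietary record. A participant failing several filters is logged once
under a fixed precedence — tube feeding > low MMSE > implausible energy >
incomplete data — chosen clinical-first so that reason counts partition
the excluded set deterministically.

## Diagnostic accuracy

*Positivity rule.* Screener-positive means score **strictly greater**
than the cut-off; a score equal to the cut-off is negative. This matches
the ≤ / > column convention of cut-off tables and is applied everywhere
(confusion tables, ROC operating points).

*Metrics and intervals.* Sensitivity, specificity, PPV and NPV are
binomial proportions; a zero denominator yields an undefined (NaN)
metric, not 0. Intervals default to Clopper–Pearson exact (Wilson and
Wald selectable). The exact interval guarantees at least nominal
coverage, verified in tests by pmf-weighted exact coverage sums rather
than simulation. Published validation reports do not always state their
interval method; intervals here are therefore reported, not treated as
reproduction targets.

*ROC and AUC.* The empirical curve is evaluated at every distinct score,
bracketed by (0,0) and (1,1) sentinels; the trapezoidal area equals the
Mann–Whitney statistic with ties counted ½ (a test enforces this identity
against `scipy.stats.mannwhitneyu` on exhaustively tied small instances).
The AUC interval uses DeLong's placement-based variance (a brute-force
O(mn) placement oracle pins the fast midrank implementation to 1e−12);
the Hanley–McNeil approximation is available as an alternative. The
Youden cut-off maximises sensitivity + specificity over observed
cut-offs; ties break toward the lower cut-off, i.e. the more sensitive
operating point, fitting the screener's rule-out purpose.

*Report formatting.* Percentages round to 1 decimal, probabilities to 2,
half away from zero; all JSON values are full precision, rounding is
applied only at report time.

## Sample size by exact binomial power

For n reference-positives, the critical count c is the smallest value
whose upper tail under p₀ is ≤ α/2 (two-sided; α one-sided), and power is
the upper tail of c under p₁ — exact sums, no normal approximation. The
minimum n is the smallest n whose power reaches the target. Exact power
saw-tooths in n, so monotonicity holds only for the running maximum; the
"smallest qualifying n" convention matches standard guidance tables. At
p₀ = 0.5, p₁ = 0.7, two-sided α = 0.05, power 0.8 this gives n = 49
(critical count 32, achieved power 0.810). The total cohort size is
n_pos / prevalence, ceiling-rounded by default (nearest-integer rounding
is exposed as an option; at prevalence 0.40 the two conventions give 123
and 122 respectively — printed totals in the literature are consistent
with nearest rounding, but the ceiling is the conservative design
choice).

## Synthetic cohort generator

The generator defines the study conditions for every test; its defaults
emulate a German community-dwelling 75+ cohort: age 81.6 ± 3.9 y, 61.8 %
female, BMI 28.0 ± 5.1 kg/m² (women's height 1.60 ± 0.06 m, men's
1.73 ± 0.07 m — typical for this age group; weight follows as BMI·h²),
MMSE clipped-normal 28 ± 1.5, energy 1770.1 ± 440.4 kcal/d, true protein
intake T ~ N(1.0, 0.3) g/kg aBW/d truncated at 0 (rejection sampling; at
these defaults the truncation moves the mean by < 0.1 %, so no
compensation is applied), and a design AUC of 0.62 at the 1.0 g/kg aBW/d
threshold.

*Score coupling.* The screener liability is
`L = −a·z_T + √(1−a²)·ε` with z_T the standardised intake. Because the
two classes are tail-truncated normals (z_T < z_thr vs ≥ z_thr), the
binormal shortcut `AUC = Φ(δ/√2)` is not exact; the coupling `a` is
instead calibrated by Gauss–Legendre quadrature over both truncated
classes and inverted with Brent's method, so the theoretical AUC of L
against the *latent* low-intake state equals the design value to 1e−10.
`a = 0` (design AUC 0.5) gives the null coupling. L maps to a score by
`expit(−1.586 + 2.24·L)`; these defaults place the score median near
0.17 with IQR ≈ 0.04–0.46, the scale this instrument shows in older
cohorts.

*Item back-fill.* Items are categorical, so a target linear predictor is
matched greedily: subtract the covariate contribution, then walk the
items in decreasing coefficient magnitude, always undershooting (item
contributions are one-signed; an overshoot could never be corrected).
With the bundled ladder the achieved linear predictor is within the
smallest item step (0.04) of the target for targets inside the
achievable range; extreme targets (≈1 % of subjects at default settings)
are clipped to the range ends. A `score_only` mode skips back-filling
for tests needing exact score control.

*Dietary days.* Recorded protein per day is `T·aBW` times a lognormal
day factor with coefficient of variation 0.25 (a typical within-person
day-to-day variation for protein). The reciprocal of a 3-day mean of
mean-one factors exceeds one in expectation (Jensen), which would bias
the g/kg classification toward "low" by ≈ 2.8 percentage points; day
factors therefore carry a `1 + CV²/n_days` rescale that cancels the
leading term of that bias. Energy couples to protein mass with a fixed
slope of 18.7 kcal per g (reproducing the observed energy gap between
low- and adequate-intake groups) plus residual noise sized so the
subject-level energy SD matches the design; fat takes a normal energy
share (38.8 ± 6.8 E%) and carbohydrate closes the energy balance.

*What the generator does not emulate:* food-level consumption patterns,
item-response marginals of any real population, under-reporting
(obesity-related or otherwise), correlations between anthropometry and
intake beyond the energy–protein link, and seasonal or weekday effects.
Passing pipeline tests on synthetic cohorts therefore demonstrates
correctness of the computational chain and calibration of the generator,
not field validity of any screener.

*Observed vs design margins.* Design SDs are latent between-subject
values; observed 3-day-mean SDs are slightly larger (day noise adds
(mean·CV/√3)² to the variance — e.g. energy SD ≈ 505 observed vs 440
designed). The empirical AUC measured against the *recorded* (noisy)
classification is attenuated relative to the design value by roughly
0.01 at defaults; the parameter-recovery test budgets for this within
its ±0.02 band.

*Planted exclusions* are drawn disjointly per reason from a seed derived
as generation seed + 1: MMSE replaced by uniform 15–23, a tube-feeding
flag, day energies scaled ×10 (far outside any ±3 SD band for realistic
energy CVs), or one random item blanked.

## Problem sizes used in tests

Module tests run at n ≤ 20 000 subjects; the parameter-recovery check
uses 20 seeds × 5 000 subjects through the full pipeline; the null-AUC
check uses one draw of 100 000 score-only subjects. These sizes put
Monte-Carlo noise well inside the asserted tolerances (±0.02 on AUC,
±2 pp on prevalence) while keeping the default suite around ten seconds.

## Known limitations

* The shipped coefficients are synthetic; no result obtained with the
  bundled configuration transfers to real screening.
* DeLong intervals are Wald-type on the AUC scale (truncated to [0, 1]);
  logit-scale intervals are not implemented.
* The eligibility precedence order is a convention; studies reporting
  disjoint exclusion counts rarely state theirs.
* The energy-plausibility rule is the ±3 SD band only; no under-reporting
  diagnostics (e.g. Goldberg cut-offs) are included.
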