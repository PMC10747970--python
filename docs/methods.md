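# Methods

This note documents the statistical procedures `gaitagree` implements,
the choices made where the methodology is genuinely open, and what the
synthetic-data validation does and does not establish.

## Data model and averaging

Raw input is one row per single-trial measurement: subject, parameter,
trial, side (left/right/na), system (reference/test), value.  Per
(subject, parameter, system) all trials and sides are averaged
arithmetically, giving one (reference, test) pair per subject — the
`PairedSeries` every stage consumes.  The two systems may contribute
unequal trial counts (acquisition protocols often differ); the average
is taken over whatever trials each system recorded.  Subjects measured
by only one system are dropped from that parameter with a warning
(listwise deletion; imputation would fabricate agreement information).
A parameter needs at least 3 complete pairs; all stages are designed for
the small cohorts typical of rare-disease validation studies (n ≈ 15).

Differences are always d_i = reference_i − test_i, so a positive
Bland–Altman bias means the test system under-reads.  This convention is
fixed in `AnalysisConfig` rather than configurable: flipping it
silently negates every bias and intercept and is a classic source of
sign errors when comparing reports.

## Paired testing

Normality is assessed with Shapiro–Wilk on the *differences*, not on
each system's arm: the paired t-test's assumption concerns d, and the
Wilcoxon signed-rank test's symmetry assumption likewise.  With
normality p ≥ α the paired t-test runs, otherwise Wilcoxon.  Wilcoxon
uses classic zero handling (zeros discarded), the exact null
distribution when the nonzero count is ≤ 25 with no tied absolute
differences, and otherwise the normal approximation with continuity
correction and midrank tie correction — the behaviour of mainstream
statistical packages at these sample sizes.  Degenerate inputs are
flagged rather than crashed on: all-zero differences yield the
no-difference convention (statistic 0, p = 1), constant nonzero
differences bypass the (undefined) gate into the Wilcoxon branch.

Calibration: over 100 000 null replicates (n = 15, both systems = common
Gaussian truth + independent noise) the gated procedure's measured
rejection rate was ≈ 0.051 at α = 0.05 — the gate's sample selection
inflates the level slightly, by well under the Monte-Carlo tolerance
any finite check uses.  `validate.null_type_one_error` recomputes this
on demand.

## Passing–Bablok regression

Estimation follows the original symmetric procedure for comparing two
methods over their natural range: all pairwise slopes
S_ij = (y_j − y_i)/(x_j − x_i), i < j; 0/0 pairs dropped; vertical pairs
contribute signed infinities that participate in the ordering but never
in averaging; slopes exactly −1 are excluded and K = #{S_ij < −1}
shifts the median index (this makes the estimator invariant under
swapping the axes).  The slope CI takes the order statistics at ranks
M1 + K and M2 + K with M1 = round((N − C)/2), M2 = N − M1 + 1, and
C = z_{1−α/2}·sqrt(n(n−1)(2n+5)/18); the intercept is
median(y − m·x), its bounds computed with the opposite slope bound.
Numerical choices, all documented so results are bit-reproducible:

* M1 rounds half away from zero (matches mainstream method-comparison
  implementations);
* the normal quantile z is used in C (no small-sample correction);
* if a central order statistic needed for the estimate is infinite, the
  fit is reported as degenerate;
* when n is too small for the requested level (n ≤ 4 at α = 0.05 the
  rank M1 + K falls below 1), a CI-undefined error is raised that still
  carries the point estimates.

Validation: the implementation is checked for *exact* agreement with an
exhaustive brute-force double loop on seeded datasets up to n = 12;
noiseless lines are recovered to machine precision; and in calibrated
simulations the slope CI covers the generative slope in ≈ 95% of 1000
replicates at n = 50, while the mean recovered slope over 1000
replicates of a stride-length-like model (n = 15, generative slope
2.10) is ≈ 2.10.

### Linearity check

Passing–Bablok regression presupposes a linear relation.  The cusum
check walks the points in order of increasing reference value (ties
broken by test value), accumulating the signs of the residuals
r_i = y_i − (q + m·x_i); zero residuals (within a relative tolerance of
1e−12, guarding exact lines against sign noise) are dropped.  The
statistic H = max_j |Σ_{i≤j} sign(r_i)| / sqrt(L) is compared against
the Kolmogorov–Smirnov critical value (≈ 1.358 at α = 0.05, computed
from the asymptotic distribution rather than hard-coded).  Ordering by
the reference axis is one of several conventions in circulation; it
differs from orderings that rank by a combination of both axes only
when the x- and y-ranks disagree strongly, which itself signals
non-linearity.  Note the excursion grows like sqrt(run length), so mild
curvature at small n passes: y = x² on x = 1..20 gives H ≈ 1.12
(linear verdict); on x = 1..40 it fails clearly.

## Bland–Altman analysis

bias = mean(d); SD of differences with n−1 denominator; limits of
agreement bias ± 1.96·SD (the multiplier is configurable — 1.96 is the
Gaussian 95% convention); bias CI = bias ± t_{1−α/2, n−1}·SD/√n.  Two
identities hold exactly by construction and are asserted property-wise:
midpoint(LoA) = bias and LoA half-width = multiplier·SD.  The bias CI
formula is the standard t-based one; published tables sometimes print
bounds not reproducible from any standard formula, which is why the
classifier accepts externally supplied intervals (below).

Trend diagnostics, reported but never entering the verdict (a
practitioner reads them alongside the plot): OLS slope of d on the pair
means with its two-sided p (proportional trend), and the Spearman
correlation of |d − bias| with the pair means (heteroscedasticity, the
fan shape).  Both are level-α tests of genuinely different pathologies:
a symmetric fan triggers only the second.

## Agreement classification

* proportional systematic error ⇔ 1 ∉ slope CI;
* constant systematic error ⇔ 0 ∉ intercept CI **or** 0 ∉ bias CI;
* agreement (no flags) / very close agreement (constant only) /
  no agreement (any proportional flag).

The constant-error rule is a disjunction because the two intervals have
very different power: the Passing–Bablok intercept CI inherits the
slope CI's width (at n = 15 it can span tens of units and hide a real
offset the bias CI resolves), while a proportional error can displace
the intercept without moving the bias.  Interval endpoints exactly at
the null value count as containing.  Interval *width* alone never fires
a flag, and paired-test p-values are carried as context only — a
significant paired test with all three CIs covering their null values
still classifies as agreement.  Widening any interval can never add an
error flag (tested as a property).

The classifier consumes plain intervals, so it also runs in
classification-only mode on precomputed tables
(`pipeline.classify_intervals`, CLI `classify`); applied to the printed
interval rows of the cohort in `gaitagree.datasets` it reproduces all
six published verdicts.

## Synthetic generator

The generator emulates a two-system validation cohort, not gait
biomechanics: per subject a latent truth per parameter ~ Normal(μ, σ²)
truncated to the physical range (bounds: ±6 SD or the physical range,
whichever is tighter; rejection sampling, failure after 100 retries);
per trial, reference = truth + N(0, σ_ref²) and
test = q + m·truth + N(0, σ_test²).  Defaults:

| parameter | μ | σ | units |
|---|---|---|---|
| cadence | 91.72 | 14.23 | steps/min |
| cycle duration | 1.36 | 0.33 | s |
| speed | 0.61 | 0.20 | m/s |
| stance phase | 63.96 | 2.92 | % cycle |
| swing phase | 36.83 | 3.92 | % cycle |
| stride length | 0.41 | 0.10 | m |

with n = 15 subjects, 4 trials, m = 1, q = 0, and noise SD 2% of the
truth mean — a 15-subject cohort of slow, short-stepping walkers with
instrument noise small against between-subject spread.  Gaussian truth
plus Gaussian additive noise matches the mean ± SD summaries and the
normality-gated framework such studies use.  Parameters are generated
independently by default; `consistent_kinematics` instead derives, on
the truth layer before noise, swing = 100 − stance,
cycle = 120/cadence (two steps per stride) and speed = stride/cycle.
Independence is the default because published per-parameter summary
moments need not be jointly consistent (the default table above is not:
0.41 m stride with 0.61 m/s × 1.36 s ≈ 0.83 m suggests the source
summary mixed stride and step definitions), and reproducing each
parameter's printed moments verbatim is the more useful default for
per-parameter validation.

`generate_null` forces m = 1, q = 0: both systems observe the same
truth with independent noise.  A fixed seed gives bit-identical output.

What passing on synthetic data does **not** show about real data: no
gait-event detection errors (which are structured, not Gaussian), no
within-subject trial-to-trial correlation beyond the shared truth, no
left/right asymmetry, no outliers or heavy tails unless injected, and
the two systems' recordings are simulated as simultaneous whereas real
protocols often record them in separate sessions.

## Monte-Carlo validation harness

`validate` derives one child generator per replicate from a master seed
(so summaries are reproducible and replicates independent) and reports
Monte-Carlo standard errors.  Problem sizes used by the standard runs
and the acceptance script: slope recovery 1000 replicates at n = 15;
CI coverage 1000 replicates at n = 50; type-I error 5000 null
replicates at n = 15; end-to-end verdict-dominance 100–200 replicated
studies per scenario.  With all three decision CIs independently at
~95% coverage, the joint probability of an *agreement* verdict under
interchangeable systems sits near 0.90 (slope and intercept misses
largely coincide; bias misses are nearly independent of them) — the
verdict-dominance checks therefore allow binomial Monte-Carlo tolerance
around that value.

## Known limitations

* Rank CIs are undefined below n = 5 at α = 0.05 (point estimates are
  still produced); all CIs are approximate at small n.
* No multiple-testing correction across parameters (deliberate: each
  parameter is reported as its own comparison).
* No confidence intervals for the limits of agreement themselves, and
  no repeated-measures Bland–Altman variant.
* The cusum linearity check has low power at small n (see above).
* Weighted/Deming alternatives to Passing–Bablok are out of scope.
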