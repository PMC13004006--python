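# Methods

This note documents the models, numerical choices and known limitations
behind `iolscore`.

## Scoring

Both scores are total, deterministic maps from raw measurements; missing
measurements raise an error (complete-case analysis downstream, no
imputation).

**Band inclusivity.** All printed middle bands are treated as closed
intervals and the 0- and 2-score bands as strict inequalities: e.g.
cervical length scores 1 on exactly [11, 20] mm, 0 strictly above 20 and
2 strictly below 11. Where the printed bands leave a gap (stiffness
between 8.0 and 8.1 kPa in the inner third, say), the closed middle band
absorbs it: the comparison is `>upper → 0`, `≥lower → 1`, else `2`, at
full floating precision. Every component map is piecewise constant and
monotone in the clinically favorable direction, a property the test
suite enforces.

**Elastography aggregation.** The component is defined by zone-specific
bands for the inner/middle/outer cervical thirds *and* by a mean-based
final assignment. The default strategy scores each third with its own
band and rounds the arithmetic mean of the three sub-scores half-up,
which keeps every zone-specific threshold operative. Two alternatives
are exposed: a majority vote (median) of the three sub-scores, and
banding the mean stiffness against the averaged thresholds (upper 8.0,
lower 6.6 kPa). On concordant thirds all strategies agree; they differ
only for strongly discordant profiles.

**Angulation aggregation.** Three band statistics (anterior angle,
posterior angle, their sum) reduce to one 0–2 component the same way:
mean of the three band scores, rounded half-up, with a sum-band-only
alternative. The symmetric treatment of both aggregated components was a
design choice; no single reduction is canonical.

**Rounding.** Half-up, `floor(x + 0.5)`: a mean sub-score of exactly 0.5
scores 1, and 1.5 scores 2. This keeps the two aggregated components
monotone.

**Bishop score.** The original 1964 table (maximum 13): dilatation
0/1–2/3–4/≥5 cm → 0–3; effacement <40/40–50/60–70/≥80% → 0–3 (values
between printed columns take the highest band they reach); station
−3/−2/−1 or 0/+1 or +2 → 0–3; consistency firm/medium/soft → 0–2;
position posterior/mid/anterior → 0–2. Modified (13+) variants are out
of scope.

## ROC analysis

The empirical AUC is computed from midranks,
`A = (R⁺ − m(m+1)/2)/(mn)`, which counts tied positive–negative pairs
as ½ and equals the trapezoidal area under the empirical curve exactly
(the suite checks agreement to 1e−12, with and without ties).

Two SE estimators are provided. Hanley–McNeil depends only on (A, m, n):
`Var = [A(1−A) + (m−1)(Q₁−A²) + (n−1)(Q₂−A²)]/(mn)` with
`Q₁ = A/(2−A)`, `Q₂ = 2A²/(1+A)`; it is what classical packages print
and is exact at A ∈ {0, 1}. DeLong uses per-subject placement values
(computed with midranks in O(n log n)) and is the default for inference
because it is consistent under ties and supplies the covariance needed
for the paired test. The paired comparison uses the 2×2 placement
covariance; when two identical score vectors are compared the variance
of the difference is exactly zero and the p-value is defined as 1.

Confidence intervals are `A ± z·SE` truncated to [0, 1] after the
normal approximation; significance against A = 0.5 uses the two-sided z
statistic `(A − 0.5)/SE`.

Coordinate tables follow the convention of classical statistics
packages: cutoffs at min(observed)−1, the midpoints of consecutive
distinct observed values, and max(observed)+1; a subject is
test-positive when score ≥ cutoff, so higher scores predict vaginal
delivery, the first cutoff yields (sens, FPR) = (1, 1) and the last
(0, 0). Optimal-cutoff selection rules (Youden etc.) are deliberately
not implemented; the table is reported as-is.

## Logistic regression

Maximum likelihood via iteratively reweighted least squares; weights are
floored at 1e−10, convergence is declared when the largest coefficient
change falls below 1e−8 (default cap 100 iterations), and the Wald
covariance is the inverse observed information at the optimum. A
coefficient magnitude exceeding 30 on the log-odds scale triggers an
explicit separation error rather than silently returning divergent
estimates. The adjusted model treats the composite total as a continuous
predictor by default (odds ratio per point), with a low/intermediate/high
dummy coding available; maternal age enters uncentered in years.

## Synthetic cohort generator

A single latent readiness factor `L ~ N(μ, σ²)` drives everything:

* continuous measurements are linear in L plus Gaussian noise, truncated
  to physiologic ranges (cervical length 0–50 mm, stiffness 0–30 kPa,
  angles 40–220°, head–perineum distance 10–80 mm). Truncation (not
  resampling) keeps per-subject reproducibility simple; at the default
  parameters ~1% of cervical-length draws and far fewer of the other
  measurements hit a bound. Slopes are negative
  for cervical length, HPD and stiffness and positive for the angles, so
  all markers co-vary the way cervical ripening does;
* head position and the five Bishop components are ordinal cutpoints on
  L plus component-specific noise, mapped to representative raw values
  (e.g. dilatation levels → 0 / 1.5 / 3.5 / 5 cm), so Bishop totals are
  realistic integers. Because every component loads on the same L, the
  composite and Bishop scores are positively correlated (ρ ≈ 0.8 at the
  defaults), tunable through the component noise SDs;
* the outcome follows
  `logit P(vaginal) = β₀ + 1.5·L + 0.6·multiparous − 0.02·(age − 30.8)`.

Demographic defaults are the study-population marginals: 56%
nulliparous; indications 31/23/19/12/15% (post-term, hypertensive
disorders, PROM, fetal growth restriction, other); 74% induced after 36
weeks; methods 50/15/35% (dinoprostone, oxytocin, combined); age
30.8 ± 5.4 years truncated to [18, 50], with the location parameter
solved (Brent's method) so the *truncated* mean equals the configured
30.8 rather than drifting ~0.05 years. The source cohort's
vaginal-delivery rate was not published; the default intercept
β₀ = 0.95 was chosen numerically to give a marginal rate of ≈0.70,
and both the rate and the intercept are explicit, configurable
assumptions. A single shared factor (rather than a multi-factor model)
is the simplest structure consistent with all markers indexing the same
underlying cervical readiness.

**Reproducibility.** One root seed; subject *i* draws a fixed-layout
vector from `SeedSequence(seed, spawn_key=(i,))`, so cohorts are
bit-identical under the same seed and a cohort prefix is invariant to
the total size requested.

**Category calibration.** `calibrate_category_distribution` tunes
(μ, log σ) of the latent factor so the generated low/intermediate/high
composite-category fractions hit a target split (e.g. 29/48/23%). The
objective — worst absolute deviation of the three fractions, evaluated
on a 6,000-subject cohort regenerated with common random numbers — is
deterministic given the seed, so a two-stage grid (σ ∈ [0.3, 1.3],
μ ∈ [−1.5, 1.5]) followed by Nelder–Mead polish converges reproducibly
in ~150 evaluations. If the tolerance (default ±2%) is unreachable the
error carries the best configuration found. Narrowing σ concentrates
totals in the intermediate band; shifting μ trades low against high.

**What the generator does and does not emulate.** It reproduces the
published demographic marginals, the category split, and a plausible
monotone coupling between markers and outcome. It does **not** emulate
the source study's joint distribution (which was never published), its
exact AUCs or sensitivity/specificity pairs, non-integer Bishop
recording, operator measurement error, or any effect-modification
structure beyond the additive parity and age terms. Passing tests
therefore validate the statistical machinery and the generator's own
calibration targets — not clinical performance claims on real data.

## Problem sizes used in checks

Marginal calibration is verified on 20,000-subject cohorts (binomial
Monte-Carlo tolerance, 3 SE; category split ±3 points); the paired-test
size uses 2,000 null replicates at n = 200 with a 70% positive rate
(acceptance band 3.5–6.5%, ±3 binomial SE around nominal); Wald coverage
uses 1,000 cohorts at n = 500 (band 93–97%); slope recovery averages 5
cohorts at n = 2,000 (±0.1 on a true log-OR of 0.9). Oracle equivalence
for the AUC runs 1,000 random small instances against exhaustive
pair counting.

## Known limitations

* The Wald odds-ratio intervals are asymptotic; with rare outcomes or
  small strata, profile-likelihood or exact intervals would be
  preferable (not implemented).
* The DeLong test assumes the same subjects under both scores; no
  unpaired comparison is provided.
* The generator's truncation slightly compresses the age SD
  (≈5.2 observed vs 5.4 nominal) and, at extreme latent configurations,
  the measurement SDs.
* Smoothed/binormal ROC fitting, partial AUC, calibration curves and
  decision-curve analysis are out of scope.
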