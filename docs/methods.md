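# Methods

This note documents the statistical models implemented in `rdscreen`, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions.

## Sharp RD estimation

Treatment is assigned deterministically at the cutoff: `above = 1[x >= c]`,
with the boundary on the treated side (a subject measured exactly at the
threshold receives the referral).  The main estimator is weighted least
squares on the fully interacted centered design

    Y = a0 + a1*Above + a2*t + a3*Above*t [+ a4*t^2 + a5*Above*t^2] + X k + v,
    t = x - c,

with kernel weights w = max(0, 1 - |t|/h) (triangular; a uniform kernel is
available).  Because the design is fully interacted in the polynomial terms,
`a1` equals the difference of the two side-specific local fits' intercepts
at the cutoff; this identity is verified numerically in the test suite.

**Covariates** enter additively with a shared intercept and no interaction
with side — they serve to absorb residual variance and small-sample
imbalance, not to redefine the estimand.  Categorical covariates expand to
indicator columns against the first level in sorted order (the reference);
rows with missing covariates are dropped listwise per fit and the dropped
count is recorded on the estimate.

**Inference.**  Standard errors are heteroskedasticity-consistent (HC1)
sandwich on the weighted fit — the default practice for local RD
regressions, since the local linear model is an approximation and residual
variance need not be constant in x.  A `classical` option gives the
homoskedastic weighted-least-squares variance.  Intervals and p-values are
conventional normal Wald at `alpha_level` (default 0.05); no bias-corrected
robust intervals are computed, so at large bandwidths with strong curvature
the intervals inherit smoothing bias.  This is a deliberate simplification
and a known deviation risk from bias-corrected practice.

**Default spec.**  Cutoff 25 kg/m² and bandwidth h = 2.9 kg/m² (analysis
window 22.1-27.9 kg/m²) define the reference analysis; `bandwidth="auto"`
switches to the plug-in selector below.  Local linear (order 1) is the
default; order 2 is the quadratic robustness variant.

## Plug-in bandwidth selection

The selector is a documented Imbens-Kalyanaraman-style plug-in, labelled
`plug-in (IK-style)` in output:

1. pilot bandwidth h1 = 1.84 · SD(x) · n^(-1/5);
2. density at the cutoff f(c) from the pilot-window count / (2 h1 n);
3. side residual variances s² at c from linear fits within the pilot window;
4. side curvatures m''(c) from global cubic fits;
5. h = C_K · [ (s²_- + s²_+)/f(c) / ((m''_+ - m''_-)² + r_- + r_+) ]^(1/5) · n^(-1/5),
   C_K = 3.4375 (triangular kernel), regularization
   r_j = 2160 s²_j / (n_pilot,j · h1⁴).

The selector is exactly equivariant to rescaling x about the cutoff,
invariant to shifting or rescaling the outcome, and shrinks at the n^(-1/5)
rate when the curvature difference dominates (all verified in tests).  The
regularization keeps h finite when the side curvatures coincide; under a
near-linear truth it then dominates the denominator, which yields a
conservative (small) h — on default synthetic cohorts h ≈ 1.0.  The selector
is not a numerical replica of any published implementation; a manual
bandwidth is always accepted and logged, and the reference analyses impose
h = 2.9 directly.

## Density (manipulation) test

A McCrary-style two-step test for a jump in the running variable's density
at the cutoff.  Bin width 2·SD(x)·n^(-1/2) (undersmoothed), with bin edges
aligned so no bin straddles c; normalized bin heights are then smoothed by
side-specific triangular-kernel local linear regression with the pilot
bandwidth from the selector.  The statistic is ln f₊(c) − ln f₋(c).  The
variance is built from the smoother weights and per-bin Poisson variances
f/(n·b) via the delta method, rather than from the asymptotic constant, so
it is self-consistent with the binned estimator actually used.  Monte-Carlo
calibration at the default cohort (n = 6561, smooth log-normal density)
gives a size of ~4-5% at the nominal 5% level, and power ~1.0 against a
bunching mass of 0.5 relocated across a 0.5-unit band at n = 5000.

## Covariate, attrition, and robustness diagnostics

* **Balance table**: within [c−h, c+h], side-specific level percentages with
  Wilson 95% intervals; per covariate a chi-square test of the side × level
  table, switching to an exact test when any expected cell is below 5
  (Fisher for 2×2; a seeded 2000-draw permutation chi-square for wider
  tables, analogous to simulated p-values in standard software).
* **Placebo continuity**: covariate level indicators refitted as outcomes in
  the linear-probability form of the RD model.
* **Attrition continuity**: the follow-up indicator refitted at h, 0.5h and
  1.5h on the full baseline table; a smooth side-level difference in
  follow-up (marginal imbalance) does not register, only a local jump does.
* **Placebo cutoffs** (24, 24.5, 25.5, 26): fitted using only observations
  on the relevant side of the true cutoff, so a genuine jump at c cannot
  leak into the placebo estimate; one-sided fitting is the standard
  conservative choice.  A placebo at the true cutoff reproduces the main
  fit exactly.
* **Donut RD** (radii 0.5, 1.0, 1.5): strict exclusion |x−c| < r; boundary
  points at exactly r are retained; excluded counts are recorded.
* **Bandwidth sensitivity**: multiplicative grid {0.5, 0.8, 1.0, 1.2, 1.5}·h.
* **Age coding**: the covariate-adjusted fit rerun with age categorical
  (35-39, 40-49, 50-59, 60-69, 70+) versus continuous.

## Binary outcomes: modified Poisson RD

"Modified Poisson" is read conventionally: Poisson-family log-link
estimating equations applied to a 0/1 outcome with a robust sandwich
variance, giving directly interpretable risk ratios.  The RD design is the
same centered specification (unadjusted by default); triangular kernel
weights multiply the estimating equations as frequency-type weights, and
the sandwich uses the weighted score outer product.  Newton iteration is
capped at 100 steps with a 1e-8 coefficient-change tolerance; separation
(an all-0 or all-1 side) raises an error, and fitted risks above 1 at
convergence are flagged on the result.  With uniform weights and no trend
terms the fit collapses to the closed-form 2×2 risk ratio, which the tests
verify to 1e-6.

At realistic effective event counts the estimator carries the usual O(1/n)
second-order MLE bias (a few tenths of a percent on the risk-ratio scale at
n = 20,000 with a 0.2 baseline risk); this is a property of modified
Poisson itself — a statsmodels GLM fit of the same data is numerically
identical — and is visible only in very large Monte-Carlo aggregates.

## Heterogeneity and power

Subgroup analysis uses a single saturated model: the full RD design
interacted with subgroup-level indicators, giving one discontinuity per
level; equality across levels is tested by a joint Wald chi-square on the
interaction contrasts (L−1 degrees of freedom).  Per-level p-values are
unadjusted for multiplicity.  Levels with fewer than order+1 usable points
on either side are reported as inestimable.

Power is purely simulation-based: for each injected τ the generator is
rerun with fresh substream seeds, the main model is refitted, and the
two-sided rejection rate at α is recorded with its binomial Monte-Carlo SE.
Fit failures count as non-rejections and are logged.  At the default study
geometry (n = 6561 subjects, ~3000 in the 2.9-unit window, noise SD below)
the design has ~5% size at τ = 0 and ~80-85% power at τ = 0.8 kg/m².

## The synthetic-cohort generator

The generator emulates the statistical structure the RD analysis assumes,
not any real population:

* **Running variable**: log-normal with median 24.5 and SD 4 kg/m²
  (right-skewed, unimodal); the shape parameters are solved in closed form.
  With zero bunching mass the density is continuous at the cutoff by
  construction.
* **Outcome means**: side-specific polynomials in t = x − c; default
  E[Y|x] = 25 + 0.85 t (BMI persistence with regression to the mean) with an
  injectable discontinuity τ added on the treated side.  Default τ = 0.
* **Noise**: residual SD 2.75 kg/m².  This value was calibrated once so that
  the main local-linear fit at the default geometry has a standard error of
  ≈0.28 kg/m², the precision implied by a reported headline interval of
  width ~1.1 kg/m² in the motivating study design; it makes simulated power
  at τ = 0.8 land near the study's qualitative 85% figure without adopting
  that figure as a target.
* **Covariates**: categorical marginals resembling a rural Southeast-Asian
  adult cohort, independent of x by default (continuity holds trivially);
  optional smooth log-odds dependence on x and an optional probability jump
  at the cutoff exist purely to stress-test the balance and placebo
  diagnostics.  A continuous age consistent with the age bins is generated
  alongside the age group.
* **Binary outcomes**: Bernoulli draws from risk = exp(intercept + slope·t +
  jump·above); configurations implying risk > 1 raise an error rather than
  clip silently.
* **Attrition**: follow-up probability interpolates smoothly (normal-CDF
  ramp, scale 3 kg/m²) between side levels 0.461 and 0.546, reproducing a
  marginal follow-up imbalance with no discontinuity at the cutoff; a
  non-smooth variant with a genuine jump exists for stress tests.  Lost
  subjects keep their baseline row with outcomes set missing, so attrition
  diagnostics can use the full baseline table.
* **Bunching**: a configurable fraction of subjects just below the cutoff is
  mirrored across it (recorder-interference emulation); the same mechanism
  is exposed as `inject_manipulation` for existing tables.
* **Determinism**: one global seed split into named per-stage substreams;
  identical (config, seed) gives byte-identical CSV output.

What the generator does **not** emulate: real joint dependence between
covariates and outcomes, measurement heaping at round BMI values,
item-level instruments (only the ≥600 MET-minute activity classification
rule is provided), or the demographic composition of any actual population.
Passing tests therefore demonstrate correctness of the estimators under the
assumed data-generating structure, not agreement with any study's data.

## Numerical conventions and problem sizes

* WLS is solved by QR on the sqrt(w)-scaled system; rank deficiency is
  detected from the QR diagonal and reported with the collinear column
  names.  Oracle tests compare against direct normal-equations solves and
  statsmodels to 1e-8.
* Wald quantiles are normal, not t; with window samples in the hundreds the
  difference is negligible.
* Degenerate inputs raise typed errors (configuration, input, sample-size,
  estimation/separation/convergence, selection), which the CLI maps to
  documented exit codes.
* Monte-Carlo problem sizes used by the test suite and acceptance script —
  500 replicates for coverage/size calibrations, 200 for density power and
  noisy recovery, 150-200 for risk-ratio recovery — keep the whole suite in
  the tens of seconds while leaving binomial Monte-Carlo error well inside
  the asserted bands.
* Rounding in rendered tables: descriptive percentages to two significant
  figures, balance proportions/differences and estimates to one decimal;
  machine outputs (JSON/CSV) always carry full precision, so every rendered
  number is re-derivable.
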