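# rdscreen

Sharp regression-discontinuity (RD) analysis of threshold-triggered health
screening, packaged as a tested, reusable pipeline.

## The problem

Community screening programmes often assign an intervention by a hard
threshold on a continuous measurement: everyone with baseline BMI ≥ 25 kg/m²
is told their result and handed a referral card, everyone below is not.
Because assignment is deterministic in the *running variable* x (baseline
BMI), subjects just above and just below the cutoff c are comparable in
everything except treatment, and the jump in mean outcomes at c identifies
the local intention-to-treat effect. `rdscreen` implements the full analysis
a biostatistician would run on such a cohort — estimation, bandwidth choice,
identification diagnostics, robustness battery, binary-outcome risk ratios,
subgroup heterogeneity, and design power — together with a seeded
synthetic-cohort generator, so every stage is testable without access to any
surveillance data.

## The model

For a continuous outcome Y (e.g. follow-up BMI) the estimand is the sharp
RD contrast at the cutoff, fitted by kernel-weighted least squares on the
fully interacted centered design within a bandwidth h:

    Y_i = α₀ + α₁·Above_i + α₂·(x_i − c) + α₃·Above_i·(x_i − c) [+ quadratic terms] + X_i κ + v_i

with `Above_i = 1[x_i ≥ c]`, triangular kernel weights
w_i = max(0, 1 − |x_i − c|/h), optional additive covariates with a shared
intercept, HC1 sandwich standard errors and normal Wald intervals.  α₁ is
the local average treatment effect at the cutoff.  Binary outcomes use the
same design in a modified Poisson regression (log link, robust sandwich
variance), so exp(α₁) is a risk ratio.  Supporting machinery includes a
documented IK-style plug-in MSE-optimal bandwidth selector, a McCrary-style
density-discontinuity (manipulation) test, covariate balance and placebo
continuity checks, attrition-continuity tests, placebo-cutoff / donut /
bandwidth-sensitivity robustness checks, interaction models with a joint
Wald heterogeneity test, and Monte-Carlo power estimation.

## Worked example

```python
import rdscreen as rd

# a synthetic screening cohort: 6561 adults, right-skewed BMI around the
# cutoff of 25, no true discontinuity (tau = 0), ~51% follow-up
cohort = rd.simulate_cohort(rd.SimConfig(n_subjects=6561, seed=11))

spec = rd.RDSpec()          # cutoff 25, h = 2.9, local linear, triangular kernel
est = rd.fit_sharp_rd(cohort, "bmi_fu", spec)
print(rd.render_estimate(est))

dens = rd.density_discontinuity_test(cohort["x"].to_numpy(), 25.0)
print(f"manipulation test: log-density diff {dens.log_diff:.3f}, p = {dens.p_value:.2f}")

flow = rd.sample_flow(eligible=13769, followed=7024, missing_rv=463)
print(f"analytic n = {flow['analytic_n']}, exclusion {flow['exclusion_pct']}%, "
      f"follow-up {flow['followup_pct']:.0f}%")
```

Output:

```
bmi_fu: -0.1 (95% CI -0.6 to 0.4), p=0.68, n=908+863, h=2.90, order=1
manipulation test: log-density diff -0.018, p = 0.87
analytic n = 6561, exclusion 6.6%, follow-up 51%
```

The fit line reports the discontinuity in follow-up BMI at the cutoff with
its Wald CI and the effective counts on each side; here the interval covers
zero, as it should for a cohort generated with no effect.  The manipulation
test finds no density jump at the cutoff (none was injected).  The flow
helper reproduces participant-flow arithmetic from raw counts.

The same pipeline is scriptable from the shell:

```bash
rdscreen simulate --n 6561 --seed 11 --out run/
rdscreen report --input run/cohort.csv --out run/report/
```

`report` writes descriptive and balance tables, the estimate grid across
polynomial orders and covariate sets, diagnostics JSON, and the RD and
density figures; every run records a manifest (config hash, seed, versions).

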