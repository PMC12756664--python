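"""Manipulation, balance, placebo, and attrition diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from rdscreen import (
    AttritionSpec,
    InputError,
    RDSpec,
    attrition_continuity_test,
    balance_frame,
    balance_table,
    covariate_placebo_rd,
    density_discontinuity_test,
    fit_sharp_rd,
    simulate_cohort,
)

from conftest import slim_config


def test_density_log_diff_small_for_symmetric_draw():
    rng = np.random.default_rng(0)
    x = rng.normal(25.0, 3.0, size=20000)
    res = density_discontinuity_test(x, 25.0)
    assert abs(res.log_diff) < 3.0 * res.se_log_diff
    assert res.f_left > 0 and res.f_right > 0
    assert 0.0 <= res.p_value <= 1.0


def test_density_test_rejects_injected_bunching():
    cfg = slim_config(n_subjects=5000, seed=1, bunching_mass=0.5, bunching_width=0.5)
    x = simulate_cohort(cfg)["x"].to_numpy()
    res = density_discontinuity_test(x, 25.0)
    assert res.log_diff > 0  # mass moved from left to right
    assert res.p_value < 0.001


def test_density_test_needs_fifty_points_per_side():
    rng = np.random.default_rng(0)
    with pytest.raises(InputError):
        density_discontinuity_test(rng.normal(20, 1, 500), 25.0)


def test_density_statistic_invariant_to_affine_rescaling():
    rng = np.random.default_rng(5)
    x = rng.lognormal(np.log(24.5), 0.16, size=8000)
    a, b = 2.0, 7.0
    r1 = density_discontinuity_test(x, 25.0)
    r2 = density_discontinuity_test(a * x + b, a * 25.0 + b)
    assert r2.log_diff == pytest.approx(r1.log_diff, abs=1e-10)
    assert r2.se_log_diff == pytest.approx(r1.se_log_diff, abs=1e-10)


def test_balance_percentages_sum_to_hundred_per_side(null_cohort, spec):
    rows = balance_table(null_cohort, spec, ["race", "education", "sex"])
    frame = balance_frame(rows)
    for cov, grp in frame.groupby("covariate"):
        assert grp.prop_above.sum() == pytest.approx(100.0, abs=1e-9)
        assert grp.prop_below.sum() == pytest.approx(100.0, abs=1e-9)
        for _, r in grp.iterrows():
            assert r.ci_above_low <= r.prop_above <= r.ci_above_high
            assert r.difference == pytest.approx(r.prop_above - r.prop_below)


def test_single_level_covariate_flagged_not_tested(null_cohort, spec):
    df = null_cohort.copy()
    df.attrs = dict(null_cohort.attrs)
    df["const"] = "only"
    rows = balance_table(df, spec, ["const"])
    assert rows[0].test_p is None
    assert "not tested" in rows[0].test_name


def test_exact_test_used_for_sparse_cells(spec):
    df = simulate_cohort(
        slim_config(
            n_subjects=400, seed=2,
            covariate_spec={"rare": {"levels": ["a", "b"], "probs": [0.985, 0.015]}},
        )
    )
    rows = balance_table(df, spec, ["rare"])
    assert rows[0].test_name in ("Fisher exact", "permutation exact")


def test_balance_p_uniform_under_independence(spec):
    pvals = []
    for s in range(120):
        df = simulate_cohort(
            slim_config(
                n_subjects=1500, seed=s,
                covariate_spec={"g": {"levels": ["a", "b"], "probs": [0.5, 0.5]}},
            )
        )
        pvals.append(balance_table(df, spec, ["g"])[0].test_p)
    assert kstest(pvals, "uniform").pvalue > 0.005


def test_constant_covariate_placebo_estimate_is_zero(null_cohort, spec):
    df = null_cohort.copy()
    df.attrs = dict(null_cohort.attrs)
    df["const"] = 1.0
    est = covariate_placebo_rd(df, spec, "const")
    assert est.tau_hat == pytest.approx(0.0, abs=1e-10)


def test_covariate_jump_recovered_by_placebo_fit(spec):
    taus = []
    for s in range(40):
        df = simulate_cohort(
            slim_config(
                n_subjects=8000, seed=s,
                covariate_spec={
                    "j": {"levels": ["a", "b"], "probs": [0.5, 0.5], "prob_jump": [-0.10, 0.10]}
                },
            )
        )
        taus.append(covariate_placebo_rd(df, spec, "j", "b").tau_hat)
    mc_se = np.std(taus) / np.sqrt(len(taus))
    assert np.mean(taus) == pytest.approx(0.10, abs=2 * mc_se)


def test_covariate_placebo_coverage_under_continuity(spec):
    covered = 0
    reps = 150
    for s in range(reps):
        df = simulate_cohort(
            slim_config(
                n_subjects=2000, seed=1000 + s,
                covariate_spec={"g": {"levels": ["a", "b"], "probs": [0.4, 0.6]}},
            )
        )
        est = covariate_placebo_rd(df, spec, "g", "b")
        covered += est.ci_low <= 0.0 <= est.ci_high
    assert 0.91 <= covered / reps <= 0.99


def test_full_followup_gives_zero_attrition_discontinuity(spec):
    df = simulate_cohort(slim_config(n_subjects=3000, seed=3, attrition_spec=AttritionSpec(1.0, 1.0)))
    results = attrition_continuity_test(df, spec)
    assert len(results) == 3
    for est in results:
        assert est.tau_hat == pytest.approx(0.0, abs=1e-10)


def test_smooth_marginal_attrition_difference_is_not_a_discontinuity(spec):
    """Side levels 0.461 vs 0.546 reached smoothly: no rejection at the cutoff."""
    df = simulate_cohort(
        slim_config(n_subjects=6561, seed=4, attrition_spec=AttritionSpec(0.461, 0.546, smooth=True))
    )
    # marginal imbalance is real ...
    assert df.loc[df.x >= 25, "followed_up"].mean() > df.loc[df.x < 25, "followed_up"].mean()
    # ... but the local discontinuity test does not reject
    est = attrition_continuity_test(df, spec)[0]
    assert est.p_value > 0.05


def test_abrupt_attrition_jump_is_detected(spec):
    df = simulate_cohort(
        slim_config(n_subjects=20000, seed=5, attrition_spec=AttritionSpec(0.30, 0.70, smooth=False))
    )
    est = attrition_continuity_test(df, spec)[0]
    assert est.p_value < 1e-6
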