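"""Sharp RD estimation: exact recovery, algebraic identities, oracle equivalence."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rdscreen import (
    EstimationError,
    InputError,
    RDSpec,
    SampleSizeError,
    assign_treatment,
    fit_rd_grid,
    fit_sharp_rd,
    kernel_weights,
    simulate_cohort,
    triangular_weights,
)
from rdscreen.core import DEFAULT_COVARIATE_SETS, wls_fit

from conftest import noiseless_config, random_small_table


@pytest.mark.parametrize("x, expected", [(25.0, 1), (24.999, 0), (27.9, 1), (10.0, 0)])
def test_boundary_belongs_to_the_treated_side(x, expected):
    assert assign_treatment(x, 25.0) == expected


def test_assign_treatment_rejects_non_finite():
    with pytest.raises(InputError):
        assign_treatment(float("nan"), 25.0)


def test_triangular_kernel_shape():
    c, h = 25.0, 2.0
    assert triangular_weights(c, c, h) == 1.0
    assert triangular_weights(c + h, c, h) == 0.0
    assert triangular_weights(c - h / 2, c, h) == 0.5
    u = kernel_weights([24.0, 25.0, 26.5], c, h, "uniform")
    assert u.tolist() == [1.0, 1.0, 1.0]
    assert kernel_weights(c + h, c, h, "uniform") == 0.0


@pytest.mark.parametrize("order", [1, 2])
@pytest.mark.parametrize("covset", ["none", "demographic"])
def test_noiseless_tau_recovered_exactly(order, covset):
    df = simulate_cohort(noiseless_config(n_subjects=4000, seed=5))
    spec = RDSpec(order=order, covariate_set=DEFAULT_COVARIATE_SETS[covset])
    est = fit_sharp_rd(df, "bmi_fu", spec)
    assert est.tau_hat == pytest.approx(0.8, abs=1e-8)


def test_constant_outcome_gives_zero_effect_and_slopes():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x": rng.uniform(22, 28, 500), "y": 7.0})
    est = fit_sharp_rd(df, "y", RDSpec())
    assert est.tau_hat == pytest.approx(0.0, abs=1e-10)
    for name, value in est.coefficients.items():
        if name != "intercept":
            assert value == pytest.approx(0.0, abs=1e-10)
    assert est.coefficients["intercept"] == pytest.approx(7.0)


def test_tau_equals_side_intercept_difference():
    """Fully interacted regression = two separate side fits (covariate-free)."""
    rng = np.random.default_rng(7)
    df = random_small_table(rng, 400)
    spec = RDSpec()
    est = fit_sharp_rd(df, "y", spec)
    w = triangular_weights(df.x.to_numpy(), 25.0, 2.9)
    intercepts = {}
    for side, mask in (("left", (df.x < 25).to_numpy()), ("right", (df.x >= 25).to_numpy())):
        mask = mask & (w > 0)
        t = df.x.to_numpy()[mask] - 25.0
        X = np.column_stack([np.ones(mask.sum()), t])
        beta, _, _ = wls_fit(X, df.y.to_numpy()[mask], w[mask])
        intercepts[side] = beta[0]
    assert est.tau_hat == pytest.approx(intercepts["right"] - intercepts["left"], abs=1e-9)


def test_wls_matches_brute_force_normal_equations_and_statsmodels():
    rng = np.random.default_rng(42)
    df = random_small_table(rng, 150)
    est = fit_sharp_rd(df, "y", RDSpec())
    x = df.x.to_numpy()
    w = triangular_weights(x, 25.0, 2.9)
    keep = w > 0
    t = x[keep] - 25.0
    above = (x[keep] >= 25).astype(float)
    X = np.column_stack([np.ones(keep.sum()), above, t, above * t])
    y = df.y.to_numpy()[keep]
    # independent oracle: direct normal-equations solve
    W = np.diag(w[keep])
    beta_oracle = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    assert est.tau_hat == pytest.approx(beta_oracle[1], abs=1e-8)
    # independent oracle for the sandwich SE: statsmodels WLS/HC1
    res = sm.WLS(y, X, weights=w[keep]).fit(cov_type="HC1")
    assert est.tau_hat == pytest.approx(res.params[1], abs=1e-8)
    assert est.se == pytest.approx(res.bse[1], rel=1e-8)


def test_classical_se_matches_statsmodels():
    rng = np.random.default_rng(3)
    df = random_small_table(rng, 200)
    est = fit_sharp_rd(df, "y", RDSpec(se_type="classical"))
    x = df.x.to_numpy()
    w = triangular_weights(x, 25.0, 2.9)
    keep = w > 0
    t = x[keep] - 25.0
    above = (x[keep] >= 25).astype(float)
    X = np.column_stack([np.ones(keep.sum()), above, t, above * t])
    res = sm.WLS(df.y.to_numpy()[keep], X, weights=w[keep]).fit()
    assert est.se == pytest.approx(res.bse[1], rel=1e-8)


def test_missing_covariates_dropped_listwise_and_counted(null_cohort):
    df = null_cohort.copy()
    df.attrs = dict(null_cohort.attrs)
    df.loc[df.index[:200], "sex"] = np.nan
    est = fit_sharp_rd(df, "bmi_fu", RDSpec(covariate_set=("sex",)))
    in_window = (np.abs(df.x - 25) < 2.9) & df.bmi_fu.notna()
    expected_drop = int((in_window & df.sex.isna()).sum())
    assert est.n_dropped_missing == expected_drop


def test_rank_deficient_design_names_collinear_columns(null_cohort):
    df = null_cohort.copy()
    df.attrs = dict(null_cohort.attrs)
    df["dup"] = df["x"] - 25.0  # duplicates the trend column
    with pytest.raises(EstimationError, match="dup|x_c"):
        fit_sharp_rd(df, "bmi_fu", RDSpec(covariate_set=("dup",)))


def test_too_few_points_per_side_raises():
    df = pd.DataFrame({"x": [24.9, 25.1, 25.2, 25.3], "y": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(SampleSizeError):
        fit_sharp_rd(df, "y", RDSpec())


def test_grid_is_two_by_five_and_recovers_noiseless_tau():
    df = simulate_cohort(noiseless_config(n_subjects=4000, seed=12))
    grid = fit_rd_grid(df, "bmi_fu", RDSpec())
    assert grid.shape == (2, 5)
    for order in grid.orders:
        for label in grid.set_labels:
            cell = grid.estimate(order, label)
            assert not isinstance(cell, str), cell
            assert cell.tau_hat == pytest.approx(0.8, abs=1e-8)


def test_grid_reports_per_cell_errors_without_aborting():
    df = simulate_cohort(noiseless_config(n_subjects=1500, seed=1, covariate_spec={}))
    grid = fit_rd_grid(df, "bmi_fu", RDSpec())  # covariate columns absent
    cell_ok = grid.estimate(1, "none")
    cell_bad = grid.estimate(1, "demographic")
    assert not isinstance(cell_ok, str)
    assert isinstance(cell_bad, str) and "InputError" in cell_bad
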