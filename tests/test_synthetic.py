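"""Generator behaviour: determinism, injected structure, attrition, manipulation."""

import math

import numpy as np
import pandas as pd
import pytest

from rdscreen import (
    AttritionSpec,
    BinaryOutcomeSpec,
    ConfigurationError,
    InputError,
    SimConfig,
    inject_manipulation,
    lognormal_params,
    read_cohort_csv,
    simulate_cohort,
    write_cohort_csv,
)
from rdscreen.synthetic import PRIMARY_OUTCOME

from conftest import noiseless_config, slim_config


def test_degenerate_noiseless_null_outcome_is_exactly_zero():
    cfg = slim_config(
        n_subjects=50, mean_fn_left=(0.0,), mean_fn_right=(0.0,), tau=0.0,
        noise_sd=0.0, attrition_spec=AttritionSpec(1.0, 1.0), seed=3,
    )
    df = simulate_cohort(cfg)
    assert (df[PRIMARY_OUTCOME] == 0.0).all()


def test_noiseless_tau_is_an_exact_jump_at_the_cutoff():
    df = simulate_cohort(noiseless_config(n_subjects=400, covariate_spec={}, seed=9))
    t = df["x"] - 25.0
    expected = 25.0 + 0.85 * t + 0.8 * (df["x"] >= 25.0)
    assert np.allclose(df[PRIMARY_OUTCOME], expected, atol=1e-12)


def test_identical_config_and_seed_give_byte_identical_csv(tmp_path):
    cfg = SimConfig(n_subjects=300, seed=21)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_csv(simulate_cohort(cfg), p1)
    write_cohort_csv(simulate_cohort(cfg), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_csv_round_trip_is_lossless(tmp_path):
    df = simulate_cohort(SimConfig(n_subjects=200, seed=4))
    path = tmp_path / "cohort.csv"
    write_cohort_csv(df, path)
    back = read_cohort_csv(path)
    assert back.attrs["cutoff"] == 25.0
    pd.testing.assert_frame_equal(df.reset_index(drop=True), back, check_dtype=False)
    with pytest.raises(InputError):
        bad = tmp_path / "bad.csv"
        bad.write_text("x,y\n1,2\n")
        read_cohort_csv(bad)


def test_side_means_match_configured_mean_functions():
    cfg = slim_config(n_subjects=20000, seed=6, attrition_spec=AttritionSpec(1.0, 1.0))
    df = simulate_cohort(cfg)
    for side, mask in (("left", df.x < 25), ("right", df.x >= 25)):
        t = df.loc[mask, "x"] - 25.0
        expected = (25.0 + 0.85 * t + (0.0 if side == "left" else cfg.tau)).mean()
        observed = df.loc[mask, PRIMARY_OUTCOME].mean()
        bound = 3.0 * cfg.noise_sd / math.sqrt(mask.sum())
        assert abs(observed - expected) < bound


def test_attrition_fraction_within_binomial_bounds():
    att = AttritionSpec(0.461, 0.546, smooth=False)
    df = simulate_cohort(slim_config(n_subjects=20000, seed=8, attrition_spec=att))
    for p_cfg, mask in ((0.461, df.x < 25), (0.546, df.x >= 25)):
        n = int(mask.sum())
        realized = df.loc[mask, "followed_up"].mean()
        half_width = 2.576 * math.sqrt(p_cfg * (1 - p_cfg) / n)
        assert abs(realized - p_cfg) < half_width
    lost = df["followed_up"] == 0
    assert df.loc[lost, PRIMARY_OUTCOME].isna().all()
    assert df.loc[~lost, PRIMARY_OUTCOME].notna().all()


def test_running_variable_matches_lognormal_target():
    mu, sigma = lognormal_params(24.5, 4.0)
    assert math.exp(mu) == pytest.approx(24.5)
    var = (math.exp(sigma**2) - 1.0) * math.exp(2 * mu + sigma**2)
    assert math.sqrt(var) == pytest.approx(4.0)
    df = simulate_cohort(slim_config(n_subjects=50000, seed=2))
    assert np.median(df.x) == pytest.approx(24.5, abs=0.15)
    assert df.x.std() == pytest.approx(4.0, abs=0.2)
    assert (df.x > 0).all()
    assert df.subject_id.is_unique
    assert ((df.above == 1) == (df.x >= 25.0)).all()


def test_implied_risk_above_one_raises_instead_of_clipping():
    cfg = slim_config(
        n_subjects=500, seed=1,
        binary_outcome_spec={"ev": BinaryOutcomeSpec(math.log(0.9), 0.5, 0.0)},
    )
    with pytest.raises(ConfigurationError, match="ev"):
        simulate_cohort(cfg)


@pytest.mark.parametrize(
    "field, value",
    [
        ("n_subjects", 0),
        ("noise_sd", -1.0),
        ("bunching_mass", 1.0),
        ("attrition_spec", AttritionSpec(1.2, 0.5)),
        ("rv_distribution", ("weibull", {})),
    ],
)
def test_invalid_configurations_raise_naming_the_field(field, value):
    with pytest.raises(ConfigurationError):
        simulate_cohort(slim_config(**{field: value}))


def test_manipulation_mass_zero_is_identity(null_cohort):
    out = inject_manipulation(null_cohort, 0.0, 0.5)
    pd.testing.assert_frame_equal(out, null_cohort)


def test_manipulation_moves_the_stated_fraction():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x": rng.uniform(20, 30, 4000)})
    df["above"] = (df.x >= 25).astype(int)
    df.attrs["cutoff"] = 25.0
    before_donor = int(((df.x >= 24.5) & (df.x < 25)).sum())
    before_target = int(((df.x >= 25) & (df.x <= 25.5)).sum())
    out = inject_manipulation(df, 0.5, 0.5, seed=1)
    moved = before_donor - int(((out.x >= 24.5) & (out.x < 25)).sum())
    assert moved == round(0.5 * before_donor)
    assert int(((out.x >= 25) & (out.x <= 25.5)).sum()) == before_target + moved
    assert ((out.above == 1) == (out.x >= 25)).all()
    # all other fields untouched
    assert (out.index == df.index).all()


def test_manipulation_on_empty_donor_stratum_raises():
    df = pd.DataFrame({"x": np.full(100, 28.0), "above": 1})
    df.attrs["cutoff"] = 25.0
    with pytest.raises(InputError):
        inject_manipulation(df, 0.5, 0.5)
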