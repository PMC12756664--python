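"""Shared fixtures: slim seeded cohorts and reference fit specifications."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rdscreen import AttritionSpec, RDSpec, SimConfig, simulate_cohort


def slim_config(**overrides) -> SimConfig:
    """A cohort config with only the primary outcome (fast for Monte Carlo)."""
    defaults = dict(covariate_spec={}, binary_outcome_spec={}, extra_continuous={})
    defaults.update(overrides)
    return SimConfig(**defaults)


def noiseless_config(**overrides) -> SimConfig:
    """Noise-free linear cohort with tau = 0.8 and full follow-up."""
    defaults = dict(
        tau=0.8,
        noise_sd=0.0,
        attrition_spec=AttritionSpec(1.0, 1.0),
        binary_outcome_spec={},
        extra_continuous={},
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Default-condition cohort (all covariates and outcomes), no discontinuity."""
    return simulate_cohort(SimConfig(n_subjects=6561, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort() -> pd.DataFrame:
    """Noise-free cohort with an exact 0.8 discontinuity and full follow-up."""
    return simulate_cohort(noiseless_config(n_subjects=6561, seed=5, covariate_spec=None))


@pytest.fixture()
def spec() -> RDSpec:
    return RDSpec()


def random_small_table(rng: np.random.Generator, n: int = 120) -> pd.DataFrame:
    """Small random RD table for oracle-equivalence checks."""
    x = rng.uniform(20.0, 30.0, size=n)
    y = (
        1.0
        + 0.5 * (x >= 25.0)
        + 0.3 * (x - 25.0)
        - 0.2 * (x >= 25.0) * (x - 25.0)
        + rng.normal(0.0, 1.0, size=n)
    )
    df = pd.DataFrame({"x": x, "y": y})
    df.attrs["cutoff"] = 25.0
    return df
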