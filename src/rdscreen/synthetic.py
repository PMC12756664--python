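"""Seeded synthetic cohorts with the statistical structure a sharp RD analysis assumes.

The generator emulates a population-based adult cohort screened with a BMI
threshold at 25 kg/m2: a right-skewed unimodal running variable, smooth
side-specific conditional outcome means with an injectable discontinuity
``tau``, covariates continuous at the cutoff, binary outcomes generated on
the log-risk scale, configurable differential attrition by side, and an
optional bunching mass at the cutoff for stress-testing manipulation
diagnostics.  Every draw is deterministic given ``(config, seed)``; one
global seed is split into named per-stage substreams.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, InputError

logger = logging.getLogger("rdscreen")

#: Name of the primary continuous outcome column (follow-up BMI, kg/m2).
PRIMARY_OUTCOME = "bmi_fu"

#: Version tag written on the first line of every cohort CSV.
COHORT_FORMAT_VERSION = 1

#: Age bins used throughout: label -> (low, high) in years, high exclusive.
AGE_BINS: dict[str, tuple[float, float]] = {
    "35-39": (35.0, 40.0),
    "40-49": (40.0, 50.0),
    "50-59": (50.0, 60.0),
    "60-69": (60.0, 70.0),
    "70+": (70.0, 85.0),
}

# Default covariate marginals: category weights chosen to resemble a rural
# Southeast-Asian adult cohort (weights are normalised, so they need not sum
# to exactly 100).  Covariates are independent of the running variable by
# default, so covariate continuity at the cutoff holds by construction.
DEFAULT_COVARIATE_SPEC: dict[str, dict] = {
    "age_group": {"levels": list(AGE_BINS), "probs": [8, 23, 34, 25, 9.8]},
    "sex": {"levels": ["female", "male"], "probs": [60, 40]},
    "marital": {"levels": ["not_married", "married"], "probs": [15, 85]},
    "race": {
        "levels": ["malay", "chinese", "indian", "orang_asli", "other"],
        "probs": [64, 23, 12, 1.1, 0.5],
    },
    "education": {
        "levels": ["no_formal", "primary", "secondary", "tertiary"],
        "probs": [3.1, 47, 46, 3.7],
    },
    "income": {
        "levels": ["<1000", "1000-1999", "2000-2999", "3000+"],
        "probs": [45, 33, 13, 9.8],
    },
    "occupation": {
        "levels": ["paid_employee", "self_employed", "homemaker", "not_working", "pensioner_other"],
        "probs": [24, 19, 39, 11, 6.9],
    },
    "smoking": {"levels": [0, 1], "probs": [86, 14]},
    "alcohol": {"levels": [0, 1], "probs": [97.4, 2.6]},
    "activity": {"levels": [0, 1], "probs": [86, 14]},
}

#: Residual SD (kg/m2) of follow-up BMI about its conditional mean.  Chosen so
#: that the main local-linear fit at the default cohort size and bandwidth has
#: a standard error close to 0.28 kg/m2, the precision implied by the study
#: design this generator emulates (see docs/methods.md).
DEFAULT_NOISE_SD = 2.75


@dataclass(frozen=True)
class ContinuousOutcomeSpec:
    """Generative model for one continuous outcome.

    ``mean_fn_left``/``mean_fn_right`` are polynomial coefficient lists
    (ascending order) for E[Y|X] in centered coordinates t = x - cutoff on
    each side; ``tau`` is added to the right-side mean (the injected
    discontinuity); ``noise_sd`` is the residual standard deviation.
    """

    mean_fn_left: tuple[float, ...] = (25.0, 0.85)
    mean_fn_right: tuple[float, ...] = (25.0, 0.85)
    tau: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD


@dataclass(frozen=True)
class BinaryOutcomeSpec:
    """Log-risk model for one binary outcome.

    risk(x) = exp(intercept + slope * (x - cutoff) + jump * 1[x >= cutoff]).
    Configurations implying risk > 1 for any generated subject raise a
    :class:`ConfigurationError` rather than clipping silently.
    """

    log_risk_intercept: float
    log_risk_slope: float = 0.0
    log_risk_jump: float = 0.0


@dataclass(frozen=True)
class AttritionSpec:
    """Follow-up probability model.

    With ``smooth=True`` the probability interpolates between the side levels
    through a normal CDF of width ``scale`` centered at the cutoff, so there
    is no discontinuity at the cutoff even when the side levels differ (a
    marginal imbalance without a local jump).  With ``smooth=False`` the
    probability is a per-side constant, which *does* jump at the cutoff and is
    intended for stress-testing the attrition-continuity diagnostic.

    Defaults mirror the marginal follow-up imbalance typical of BMI cohorts
    (about 46% below vs 55% above the overweight threshold).
    """

    p_left: float = 0.461
    p_right: float = 0.546
    smooth: bool = True
    scale: float = 3.0

    def probability(self, x: np.ndarray, cutoff: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.smooth:
            return self.p_left + (self.p_right - self.p_left) * norm.cdf(
                (x - cutoff) / self.scale
            )
        return np.where(x >= cutoff, self.p_right, self.p_left)


# Secondary continuous outcomes: systolic/diastolic blood pressure (mm Hg)
# and random glucose (mmol/L), with mild positive dependence on baseline BMI.
DEFAULT_EXTRA_CONTINUOUS: dict[str, ContinuousOutcomeSpec] = {
    "sbp_fu": ContinuousOutcomeSpec((128.0, 0.8), (128.0, 0.8), 0.0, 15.0),
    "dbp_fu": ContinuousOutcomeSpec((78.0, 0.5), (78.0, 0.5), 0.0, 10.0),
    "glucose_fu": ContinuousOutcomeSpec((6.2, 0.08), (6.2, 0.08), 0.0, 2.0),
}

# Follow-up binary outcomes (behaviors, care use, mental health), generated on
# the log-risk scale with no jump under the default null.
DEFAULT_BINARY_SPEC: dict[str, BinaryOutcomeSpec] = {
    "smoker_fu": BinaryOutcomeSpec(math.log(0.14)),
    "active_fu": BinaryOutcomeSpec(math.log(0.14)),
    "htn_screen_fu": BinaryOutcomeSpec(math.log(0.35), 0.01),
    "depression_fu": BinaryOutcomeSpec(math.log(0.10)),
}


def lognormal_params(median: float, sd: float) -> tuple[float, float]:
    """Return (mu, sigma) of a log-normal with the given median and SD.

    median = exp(mu); sd^2 = (exp(sigma^2) - 1) exp(2 mu + sigma^2), solved in
    closed form via the quadratic in u = exp(sigma^2).
    """
    if median <= 0 or sd <= 0:
        raise ConfigurationError("rv_distribution: median and sd must be positive")
    mu = math.log(median)
    ratio = (sd / median) ** 2
    u = (1.0 + math.sqrt(1.0 + 4.0 * ratio)) / 2.0
    return mu, math.sqrt(math.log(u))


@dataclass(frozen=True)
class SimConfig:
    """Full generative model for a synthetic screening cohort.

    The defaults define the reference study conditions used throughout the
    test suite: 6561 subjects, a log-normal running variable with median
    24.5 kg/m2 and SD 4 kg/m2 around a cutoff of 25, a linear BMI
    persistence mean with no discontinuity (``tau = 0``), smooth
    side-differential attrition, and no bunching.
    """

    n_subjects: int = 6561
    cutoff: float = 25.0
    rv_distribution: tuple[str, Mapping[str, float]] = field(
        default_factory=lambda: ("lognormal", {"median": 24.5, "sd": 4.0})
    )
    mean_fn_left: tuple[float, ...] = (25.0, 0.85)
    mean_fn_right: tuple[float, ...] = (25.0, 0.85)
    tau: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    covariate_spec: Mapping[str, dict] | None = None
    binary_outcome_spec: Mapping[str, BinaryOutcomeSpec] | None = None
    extra_continuous: Mapping[str, ContinuousOutcomeSpec] | None = None
    attrition_spec: AttritionSpec = field(default_factory=AttritionSpec)
    bunching_mass: float = 0.0
    bunching_width: float = 0.5
    seed: int = 0

    # -- resolved (defaulted) component specs ------------------------------
    @property
    def covariates(self) -> Mapping[str, dict]:
        if self.covariate_spec is None:
            return DEFAULT_COVARIATE_SPEC
        return self.covariate_spec

    @property
    def binary_outcomes(self) -> Mapping[str, BinaryOutcomeSpec]:
        if self.binary_outcome_spec is None:
            return DEFAULT_BINARY_SPEC
        return self.binary_outcome_spec

    @property
    def continuous_outcomes(self) -> Mapping[str, ContinuousOutcomeSpec]:
        extras = DEFAULT_EXTRA_CONTINUOUS if self.extra_continuous is None else self.extra_continuous
        primary = ContinuousOutcomeSpec(
            tuple(self.mean_fn_left), tuple(self.mean_fn_right), self.tau, self.noise_sd
        )
        return {PRIMARY_OUTCOME: primary, **extras}

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects: must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if not (0.0 <= self.bunching_mass < 1.0):
            raise ConfigurationError("bunching_mass: must be in [0, 1)")
        if self.bunching_width <= 0:
            raise ConfigurationError("bunching_width: must be > 0")
        att = self.attrition_spec
        for name, p in (("p_left", att.p_left), ("p_right", att.p_right)):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"attrition_spec.{name}: must be in [0, 1]")
        family, params = self.rv_distribution
        if family not in ("lognormal", "normal", "uniform"):
            raise ConfigurationError(f"rv_distribution: unknown family {family!r}")
        for cov, spec in self.covariates.items():
            levels, probs = spec.get("levels"), spec.get("probs")
            if not levels or probs is None or len(levels) != len(probs):
                raise ConfigurationError(f"covariate_spec[{cov!r}]: levels/probs mismatch")
            if min(probs) < 0 or sum(probs) <= 0:
                raise ConfigurationError(f"covariate_spec[{cov!r}]: invalid probabilities")
            jump = spec.get("prob_jump")
            if jump is not None and len(jump) != len(levels):
                raise ConfigurationError(f"covariate_spec[{cov!r}]: prob_jump length mismatch")


def _draw_running(rng: np.random.Generator, n: int, dist: tuple[str, Mapping[str, float]]) -> np.ndarray:
    family, params = dist
    if family == "lognormal":
        mu, sigma = lognormal_params(params["median"], params["sd"])
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    if family == "normal":
        if params["sd"] <= 0:
            raise ConfigurationError("rv_distribution: sd must be positive")
        return rng.normal(params["mean"], params["sd"], size=n)
    if family == "uniform":
        if params["high"] <= params["low"]:
            raise ConfigurationError("rv_distribution: high must exceed low")
        return rng.uniform(params["low"], params["high"], size=n)
    raise ConfigurationError(f"rv_distribution: unknown family {family!r}")


def _relocate_mass(
    rng: np.random.Generator, x: np.ndarray, cutoff: float, mass: float, width: float
) -> np.ndarray:
    """Mirror a fraction ``mass`` of points from [cutoff-width, cutoff) to at/above the cutoff."""
    donors = np.flatnonzero((x >= cutoff - width) & (x < cutoff))
    if donors.size == 0:
        raise InputError(
            f"no subjects in the donor stratum [{cutoff - width}, {cutoff}); cannot relocate mass"
        )
    k = int(round(mass * donors.size))
    moved = rng.choice(donors, size=k, replace=False)
    out = x.copy()
    out[moved] = 2.0 * cutoff - out[moved]
    return out


def _draw_categorical(
    rng: np.random.Generator, x: np.ndarray, cutoff: float, spec: dict, name: str
) -> np.ndarray:
    levels = list(spec["levels"])
    base = np.asarray(spec["probs"], dtype=float)
    base = base / base.sum()
    n = x.size
    x_coefs = spec.get("x_coefs")
    jump = spec.get("prob_jump")
    if x_coefs is None and jump is None:
        idx = rng.choice(len(levels), size=n, p=base)
    else:
        logp = np.log(base)[None, :]
        if x_coefs is not None:
            logp = logp + np.outer(x - cutoff, np.asarray(x_coefs, dtype=float))
        probs = np.exp(logp - logp.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        if probs.shape[0] == 1:
            probs = np.repeat(probs, n, axis=0)
        if jump is not None:
            probs[x >= cutoff] = probs[x >= cutoff] + np.asarray(jump, dtype=float)[None, :]
            if (probs < -1e-12).any() or np.abs(probs.sum(axis=1) - 1.0).max() > 1e-8:
                raise ConfigurationError(
                    f"covariate_spec[{name!r}]: prob_jump yields invalid probabilities"
                )
            probs = np.clip(probs, 0.0, 1.0)
            probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.asarray([levels[i] for i in idx], dtype=object)


def _polyval(coeffs: Sequence[float], t: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(t, np.asarray(coeffs, dtype=float))


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a subject-level cohort table from a :class:`SimConfig`.

    Returns a DataFrame with columns ``subject_id``, ``x`` (running variable),
    ``above`` (sharp 0/1 assignment, x >= cutoff), the covariates, an ``age``
    column consistent with ``age_group`` when that covariate is present, the
    continuous and binary follow-up outcomes, and ``followed_up``.  Outcomes
    of subjects lost to follow-up are missing (NaN), never fabricated; the
    cutoff is stored in ``df.attrs['cutoff']``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_x, r_bunch, r_cov, r_out, r_bin, r_att = (np.random.default_rng(s) for s in ss.spawn(6))
    n, c = config.n_subjects, config.cutoff

    x = _draw_running(r_x, n, config.rv_distribution)
    if config.bunching_mass > 0:
        x = _relocate_mass(r_bunch, x, c, config.bunching_mass, config.bunching_width)
    above = (x >= c).astype(int)
    t = x - c

    data: dict[str, np.ndarray] = {
        "subject_id": np.asarray([f"S{i:06d}" for i in range(n)], dtype=object),
        "x": x,
        "above": above,
    }

    for name, spec in config.covariates.items():
        col = _draw_categorical(r_cov, x, c, spec, name)
        if all(isinstance(l, (int, np.integer)) for l in spec["levels"]):
            col = col.astype(int)
        data[name] = col
    if "age_group" in data:
        lows = np.array([AGE_BINS[g][0] for g in data["age_group"]])
        highs = np.array([AGE_BINS[g][1] for g in data["age_group"]])
        data["age"] = lows + r_cov.random(n) * (highs - lows)

    right = above.astype(bool)
    for name, spec in config.continuous_outcomes.items():
        mean = np.where(right, _polyval(spec.mean_fn_right, t) + spec.tau, _polyval(spec.mean_fn_left, t))
        noise = r_out.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        data[name] = mean + noise

    for name, spec in config.binary_outcomes.items():
        risk = np.exp(spec.log_risk_intercept + spec.log_risk_slope * t + spec.log_risk_jump * above)
        if (risk > 1.0).any():
            raise ConfigurationError(
                f"binary_outcome_spec[{name!r}]: implied risk exceeds 1 "
                f"(max {risk.max():.3f}); refusing to clip silently"
            )
        data[name] = r_bin.binomial(1, np.clip(risk, 0.0, 1.0)).astype(float)

    p_follow = config.attrition_spec.probability(x, c)
    followed = r_att.binomial(1, p_follow)
    df = pd.DataFrame(data)
    df["followed_up"] = followed
    lost = df["followed_up"] == 0
    outcome_cols = list(config.continuous_outcomes) + list(config.binary_outcomes)
    df.loc[lost, outcome_cols] = np.nan
    df.attrs["cutoff"] = c
    return df


def inject_manipulation(
    table: pd.DataFrame,
    mass: float,
    width: float,
    cutoff: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Relocate a fraction of subjects from just below to at/above the cutoff.

    Emulates recorder interference: ``mass`` of the subjects with x in
    [cutoff - width, cutoff) have their running variable mirrored across the
    cutoff into (cutoff, cutoff + width]; ``above`` is recomputed and all
    other fields are unchanged.  ``mass = 0`` returns an unchanged copy.
    """
    if not (0.0 <= mass < 1.0):
        raise InputError("mass must be in [0, 1)")
    if width <= 0:
        raise InputError("width must be > 0")
    c = table.attrs.get("cutoff", 25.0) if cutoff is None else cutoff
    out = table.copy()
    out.attrs = dict(table.attrs)
    if mass == 0.0:
        return out
    rng = np.random.default_rng(seed)
    x = out["x"].to_numpy(dtype=float)
    out["x"] = _relocate_mass(rng, x, c, mass, width)
    out["above"] = (out["x"] >= c).astype(int)
    return out


# ---------------------------------------------------------------------------
# CSV round-trip with a versioned header line
# ---------------------------------------------------------------------------

def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 CSV with a versioned comment header.

    The first line records the format version and the cutoff, e.g.
    ``# rdscreen-cohort v1 cutoff=25.0``; missing values are empty fields.
    """
    c = table.attrs.get("cutoff", 25.0)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# rdscreen-cohort v{COHORT_FORMAT_VERSION} cutoff={c!r}\n")
        table.to_csv(fh, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv` (lossless round-trip)."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# rdscreen-cohort v"):
            raise InputError(f"{path}: not an rdscreen cohort CSV (missing version header)")
        fields = header.split()
        version = int(fields[2].lstrip("v"))
        if version > COHORT_FORMAT_VERSION:
            raise InputError(f"{path}: cohort format v{version} is newer than supported")
        cutoff = float(fields[3].split("=", 1)[1])
        df = pd.read_csv(fh)
    df.attrs["cutoff"] = cutoff
    return df
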