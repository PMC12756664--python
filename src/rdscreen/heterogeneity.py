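"""Subgroup heterogeneity and simulation-based power for the sharp RD design.

Heterogeneity is assessed in a single saturated model: the full RD design
(intercept, treatment, trend, interaction, and quadratic terms when
requested) is interacted with the subgroup indicator, so every level gets
its own discontinuity estimate; equality of the level-specific effects is
tested with a joint Wald chi-square on the interaction contrasts.  Per-level
p-values are unadjusted for multiplicity.

Power is estimated by Monte Carlo: simulate a cohort under an injected
effect tau, fit the main model, and record the two-sided rejection rate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .core import RDSpec, _base_design, kernel_weights, fit_sharp_rd, resolve_bandwidth, wls_fit
from .errors import InputError, SampleSizeError
from .synthetic import PRIMARY_OUTCOME, SimConfig, simulate_cohort

logger = logging.getLogger("rdscreen")


@dataclass
class SubgroupLevel:
    """Discontinuity estimate for one subgroup level."""

    level: str
    tau_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_left: int
    n_right: int
    estimable: bool = True


@dataclass
class SubgroupEstimate:
    """Per-level RD effects plus a joint heterogeneity test."""

    subgroup: str
    levels: list[SubgroupLevel]
    p_heterogeneity: float
    outcome: str
    h_used: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [l.level for l in self.levels],
                "tau_hat": [l.tau_hat for l in self.levels],
                "se": [l.se for l in self.levels],
                "ci_low": [l.ci_low for l in self.levels],
                "ci_high": [l.ci_high for l in self.levels],
                "p_value": [l.p_value for l in self.levels],
                "estimable": [l.estimable for l in self.levels],
            }
        )


@dataclass
class PowerResult:
    """Monte-Carlo rejection rate for one injected effect size."""

    tau: float
    n_left: int
    n_right: int
    h: float
    noise_sd: float
    alpha_level: float
    replicates: int
    seed: int
    power: float
    mc_se: float
    n_failed: int = 0


def interaction_rd(
    table: pd.DataFrame, outcome: str, spec: RDSpec, subgroup: str
) -> SubgroupEstimate:
    """Fully interacted subgroup RD model with a joint Wald heterogeneity test.

    Levels with fewer than ``order + 1`` usable points on either side are
    reported as inestimable (their rows are excluded from the joint fit).
    A single-level subgroup reproduces the pooled fit exactly and has no
    heterogeneity p-value (NaN).
    """
    if subgroup not in table.columns:
        raise InputError(f"subgroup column {subgroup!r} not found")
    h = resolve_bandwidth(table, outcome, spec)
    c = spec.cutoff

    x = table["x"].to_numpy(dtype=float)
    y_all = table[outcome].to_numpy(dtype=float)
    w_all = kernel_weights(x, c, h, spec.kernel)
    use = (w_all > 0) & np.isfinite(y_all) & table[subgroup].notna().to_numpy()
    if spec.donut_radius > 0:
        use &= np.abs(x - c) >= spec.donut_radius

    sub = table.loc[use]
    levels = sorted(sub[subgroup].unique())
    if len(levels) < 1:
        raise InputError(f"subgroup {subgroup!r} has no populated levels in the window")

    need = spec.order + 1
    level_info: list[SubgroupLevel] = []
    estimable_levels = []
    for lev in levels:
        mask = (sub[subgroup] == lev).to_numpy()
        nl = int(((sub["x"] < c).to_numpy() & mask).sum())
        nr = int(((sub["x"] >= c).to_numpy() & mask).sum())
        ok = nl >= need and nr >= need
        level_info.append(
            SubgroupLevel(str(lev), np.nan, np.nan, np.nan, np.nan, np.nan, nl, nr, ok)
        )
        if ok:
            estimable_levels.append(lev)
    if not estimable_levels:
        raise SampleSizeError(f"no level of {subgroup!r} has enough points on both sides")

    keep = sub[subgroup].isin(estimable_levels).to_numpy()
    sub = sub.loc[keep]
    xs = sub["x"].to_numpy(dtype=float)
    t = xs - c
    above = (xs >= c).astype(float)
    y = sub[outcome].to_numpy(dtype=float)
    w = kernel_weights(xs, c, h, spec.kernel)

    base_cols, base_names = _base_design(t, above, spec.order)
    cols, names, tau_idx = [], [], {}
    for lev in estimable_levels:
        d = (sub[subgroup] == lev).to_numpy(dtype=float)
        for col, nm in zip(base_cols, base_names):
            if nm == "above":
                tau_idx[lev] = len(cols)
            cols.append(d * col)
            names.append(f"{subgroup}[{lev}]:{nm}")
    X = np.column_stack(cols)
    beta, cov, _ = wls_fit(X, y, w, spec.se_type)

    z = norm.ppf(1.0 - spec.alpha_level / 2.0)
    by_level = {info.level: info for info in level_info}
    for lev in estimable_levels:
        i = tau_idx[lev]
        tau = float(beta[i])
        se = float(np.sqrt(max(cov[i, i], 0.0)))
        info = by_level[str(lev)]
        info.tau_hat = tau
        info.se = se
        info.ci_low = tau - z * se
        info.ci_high = tau + z * se
        info.p_value = float(2.0 * norm.sf(abs(tau) / se)) if se > 0 else float(tau != 0)

    if len(estimable_levels) >= 2:
        idx = [tau_idx[lev] for lev in estimable_levels]
        R = np.zeros((len(idx) - 1, X.shape[1]))
        for r, i in enumerate(idx[1:]):
            R[r, idx[0]] = 1.0
            R[r, i] = -1.0
        diff = R @ beta
        V = R @ cov @ R.T
        stat = float(diff @ np.linalg.solve(V, diff))
        p_het = float(chi2.sf(stat, len(idx) - 1))
    else:
        p_het = float("nan")

    return SubgroupEstimate(
        subgroup=subgroup, levels=level_info, p_heterogeneity=p_het, outcome=outcome, h_used=h
    )


def estimate_power(
    config: SimConfig,
    spec: RDSpec,
    tau_grid: tuple[float, ...] = (0.0, 0.4, 0.8, 1.2),
    replicates: int = 500,
    seed: int = 0,
) -> list[PowerResult]:
    """Monte-Carlo power of the main RD fit over a grid of injected effects.

    For each tau the cohort generator is rerun with fresh substream seeds,
    the main model is fitted, and the fraction of two-sided rejections at
    ``spec.alpha_level`` is recorded with its binomial Monte-Carlo SE.
    Simulation or fit failures count as non-rejections and are logged.
    Deterministic given ``seed``.
    """
    if replicates < 100:
        raise InputError("replicates must be >= 100 for a stable power estimate")
    results = []
    for j, tau in enumerate(tau_grid):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), j]))
        rep_seeds = rng.integers(0, 2**31 - 1, size=replicates)
        rejects, failures = 0, 0
        n_left = n_right = 0
        h = float("nan")
        for s in rep_seeds:
            cfg = dataclasses.replace(config, tau=float(tau), seed=int(s))
            try:
                cohort = simulate_cohort(cfg)
                est = fit_sharp_rd(cohort, PRIMARY_OUTCOME, spec)
            except Exception as exc:  # noqa: BLE001 - counted as non-rejection
                failures += 1
                logger.warning("power replicate failed at tau=%.3g: %s", tau, exc)
                continue
            n_left, n_right, h = est.n_left, est.n_right, est.h_used
            rejects += est.p_value < spec.alpha_level
        power = rejects / replicates
        results.append(
            PowerResult(
                tau=float(tau),
                n_left=n_left,
                n_right=n_right,
                h=h,
                noise_sd=config.noise_sd,
                alpha_level=spec.alpha_level,
                replicates=replicates,
                seed=seed,
                power=power,
                mc_se=float(np.sqrt(power * (1.0 - power) / replicates)),
                n_failed=failures,
            )
        )
    return results


def power_frame(results: list[PowerResult]) -> pd.DataFrame:
    """Power results as a tidy DataFrame."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
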