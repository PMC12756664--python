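"""Validity diagnostics for the RD identification assumptions.

Three families of checks:

* **Manipulation**: a McCrary-style two-step density-discontinuity test —
  an undersmoothed histogram whose bin edges are aligned at the cutoff
  (no bin straddles it), followed by side-specific triangular-kernel local
  linear regression of the normalised bin heights; the statistic is the
  log-density difference at the cutoff with a delta-method standard error
  built from per-bin Poisson variances.
* **Covariate continuity**: a balance table of side-specific level
  percentages with Wilson 95% CIs and chi-square (or exact, when any
  expected cell is below 5) tests, plus placebo RD fits that treat
  covariate indicators as outcomes.
* **Attrition continuity**: RD fits of the follow-up indicator at the main
  bandwidth and at 50% / 150% of it, run on the full baseline table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, norm
from statsmodels.stats.proportion import proportion_confint

from .core import RDEstimate, RDSpec, fit_sharp_rd, resolve_bandwidth, triangular_weights
from .errors import InputError
from .bandwidth import pilot_bandwidth

logger = logging.getLogger("rdscreen")


@dataclass
class DensityTestResult:
    """Result of the density-discontinuity (manipulation) test."""

    f_left: float
    f_right: float
    log_diff: float
    se_log_diff: float
    p_value: float
    bin_width: float
    n_bins: int
    bandwidth: float
    method_label: str = "McCrary-style binned local linear"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class BalanceRow:
    """One covariate level of the balance table (percent scale)."""

    covariate: str
    level: str
    prop_above: float
    ci_above: tuple[float, float]
    prop_below: float
    ci_below: tuple[float, float]
    difference: float
    test_p: float | None
    test_name: str


def _side_density_at_cutoff(mids, heights, counts, c, h, n, bin_width):
    """Local linear intercept at c and its variance from per-bin Poisson noise."""
    w = triangular_weights(mids, c, h)
    keep = w > 0
    if keep.sum() < 2:
        raise InputError("too few histogram bins within the density-test bandwidth")
    M = np.column_stack([np.ones(keep.sum()), mids[keep] - c])
    W = np.diag(w[keep])
    A = np.linalg.inv(M.T @ W @ M) @ (M.T @ W)
    s = A[0]  # linear-smoother weights of the intercept
    f_hat = float(s @ heights[keep])
    var_bins = heights[keep] / (n * bin_width)  # Var(count/(n b)) ~ f/(n b)
    var = float(s**2 @ var_bins)
    return f_hat, var


def density_discontinuity_test(x, c: float) -> DensityTestResult:
    """McCrary-style test for a discontinuity in the running-variable density at ``c``.

    Bin width 2*SD(x)*n^(-1/2) (undersmoothed), edges aligned at the cutoff;
    the smoothing bandwidth is the selector's pilot rule 1.84*SD(x)*n^(-1/5).
    The statistic is ln f_right(c) - ln f_left(c); the p-value uses a normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    n_left, n_right = int((x < c).sum()), int((x >= c).sum())
    if n_left < 50 or n_right < 50:
        raise InputError(
            f"density test needs >= 50 points per side; got {n_left} below, {n_right} above"
        )

    sd = float(np.std(x))
    b = 2.0 * sd * n ** (-0.5)
    h = pilot_bandwidth(x)

    # bin edges aligned so that c is an edge: no bin straddles the cutoff
    lo = c - b * np.ceil((c - x.min()) / b)
    hi = c + b * np.ceil((x.max() - c) / b)
    edges = lo + b * np.arange(round((hi - lo) / b) + 1)
    counts, edges = np.histogram(x, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    heights = counts / (n * b)

    left_bins = mids < c
    f_left, v_left = _side_density_at_cutoff(
        mids[left_bins], heights[left_bins], counts[left_bins], c, h, n, b
    )
    f_right, v_right = _side_density_at_cutoff(
        mids[~left_bins], heights[~left_bins], counts[~left_bins], c, h, n, b
    )
    if f_left <= 0 or f_right <= 0:
        raise InputError("estimated density at the cutoff is non-positive on one side")

    log_diff = float(np.log(f_right) - np.log(f_left))
    se = float(np.sqrt(v_left / f_left**2 + v_right / f_right**2))
    p = float(2.0 * norm.sf(abs(log_diff) / se)) if se > 0 else float(log_diff != 0)
    return DensityTestResult(
        f_left=f_left,
        f_right=f_right,
        log_diff=log_diff,
        se_log_diff=se,
        p_value=p,
        bin_width=b,
        n_bins=int(len(mids)),
        bandwidth=h,
    )


def _covariate_test(table_2xk: np.ndarray, rng: np.random.Generator | None):
    """Chi-square test of side x level, exact when any expected cell < 5.

    For 2x2 tables the exact test is Fisher's; for wider tables a seeded
    Monte-Carlo permutation test of the chi-square statistic is used
    (analogous to simulated p-values in standard software).
    """
    if table_2xk.shape[1] < 2:
        return None, "single level (not tested)"
    total = table_2xk.sum()
    expected = np.outer(table_2xk.sum(axis=1), table_2xk.sum(axis=0)) / total
    if (expected >= 5).all():
        stat, p, _, _ = chi2_contingency(table_2xk, correction=False)
        return float(p), "chi-square"
    if table_2xk.shape == (2, 2):
        _, p = fisher_exact(table_2xk)
        return float(p), "Fisher exact"
    # Monte-Carlo exact test: permute side labels, recompute chi-square
    rng = np.random.default_rng(0) if rng is None else rng
    stat_obs, _, _, _ = chi2_contingency(table_2xk, correction=False)
    n_above = int(table_2xk[0].sum())
    levels = np.repeat(np.arange(table_2xk.shape[1]), table_2xk.sum(axis=0).astype(int))
    n_perm, hits = 2000, 0
    k = table_2xk.shape[1]
    for _ in range(n_perm):
        perm = rng.permutation(levels)
        above_counts = np.bincount(perm[:n_above], minlength=k)
        below_counts = np.bincount(perm[n_above:], minlength=k)
        tab = np.vstack([above_counts, below_counts])
        exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.nansum((tab - exp) ** 2 / np.where(exp > 0, exp, np.nan))
        hits += s >= stat_obs - 1e-12
    return float((hits + 1) / (n_perm + 1)), "permutation exact"


def balance_table(
    table: pd.DataFrame,
    spec: RDSpec,
    covariates: list[str],
    seed: int = 0,
    outcome: str = "bmi_fu",
) -> list[BalanceRow]:
    """Side-specific covariate composition within the analysis window.

    For each level of each categorical covariate: the percentage above and
    below the cutoff with Wilson 95% CIs, the percentage-point difference,
    and a per-covariate chi-square (or exact) p-value attached to every row
    of that covariate.  ``outcome`` is only consulted when the spec asks for
    an automatic bandwidth.
    """
    h = resolve_bandwidth(table, outcome, spec)
    c = spec.cutoff
    window = table[(table["x"] >= c - h) & (table["x"] <= c + h)]
    above = window["x"] >= c
    rng = np.random.default_rng(seed)

    rows: list[BalanceRow] = []
    for cov in covariates:
        col = window[cov].dropna()
        levels = sorted(col.unique())
        counts = np.zeros((2, len(levels)))
        for j, lev in enumerate(levels):
            counts[0, j] = int(((col == lev) & above.loc[col.index]).sum())
            counts[1, j] = int(((col == lev) & ~above.loc[col.index]).sum())
        p_val, test_name = _covariate_test(counts, rng)
        if p_val is None:
            logger.warning("balance: covariate %r has a single level; not tested", cov)
        n_above, n_below = counts.sum(axis=1)
        for j, lev in enumerate(levels):
            pa = 100.0 * counts[0, j] / n_above if n_above else 0.0
            pb = 100.0 * counts[1, j] / n_below if n_below else 0.0
            ci_a = proportion_confint(counts[0, j], n_above, alpha=0.05, method="wilson")
            ci_b = proportion_confint(counts[1, j], n_below, alpha=0.05, method="wilson")
            rows.append(
                BalanceRow(
                    covariate=cov,
                    level=str(lev),
                    prop_above=pa,
                    ci_above=(100.0 * ci_a[0], 100.0 * ci_a[1]),
                    prop_below=pb,
                    ci_below=(100.0 * ci_b[0], 100.0 * ci_b[1]),
                    difference=pa - pb,
                    test_p=p_val,
                    test_name=test_name,
                )
            )
    return rows


def balance_frame(rows: list[BalanceRow]) -> pd.DataFrame:
    """Balance rows as a tidy DataFrame (percent scale, 1 value per level)."""
    return pd.DataFrame(
        {
            "covariate": [r.covariate for r in rows],
            "level": [r.level for r in rows],
            "prop_above": [r.prop_above for r in rows],
            "ci_above_low": [r.ci_above[0] for r in rows],
            "ci_above_high": [r.ci_above[1] for r in rows],
            "prop_below": [r.prop_below for r in rows],
            "ci_below_low": [r.ci_below[0] for r in rows],
            "ci_below_high": [r.ci_below[1] for r in rows],
            "difference": [r.difference for r in rows],
            "test_p": [r.test_p for r in rows],
            "test": [r.test_name for r in rows],
        }
    )


def covariate_placebo_rd(
    table: pd.DataFrame, spec: RDSpec, covariate: str, level=None
) -> RDEstimate:
    """Placebo RD treating a covariate (level indicator) as the outcome.

    The covariate level is recoded 0/1 and fitted with the linear-probability
    form of the sharp RD model (no covariate adjustment); under continuity
    the discontinuity estimate should be near zero.
    """
    if covariate not in table.columns:
        raise InputError(f"covariate column {covariate!r} not found")
    work = table.copy()
    work.attrs = dict(table.attrs)
    col = work[covariate]
    if level is None:
        values = col.astype(float)
        name = f"placebo[{covariate}]"
    else:
        values = (col == level).astype(float)
        values[col.isna()] = np.nan
        name = f"placebo[{covariate}={level}]"
    work[name] = values
    placebo_spec = dataclasses.replace(spec, covariate_set=())
    return fit_sharp_rd(work, name, placebo_spec)


def attrition_continuity_test(
    table: pd.DataFrame, spec: RDSpec, multipliers: tuple[float, ...] = (1.0, 0.5, 1.5)
) -> list[RDEstimate]:
    """RD fits of the follow-up indicator at h and scaled bandwidths.

    Uses the full baseline table (``followed_up`` is observed for everyone),
    so a smooth side-level difference in follow-up does not register as a
    discontinuity — only a genuine local jump at the cutoff does.
    """
    if "followed_up" not in table.columns:
        raise InputError("table has no 'followed_up' column")
    if table["followed_up"].isna().any():
        raise InputError("'followed_up' must be observed for every baseline row")
    h = resolve_bandwidth(table, "followed_up", spec)
    results = []
    for m in multipliers:
        s = dataclasses.replace(spec, bandwidth=h * m, covariate_set=())
        results.append(fit_sharp_rd(table, "followed_up", s))
    return results
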