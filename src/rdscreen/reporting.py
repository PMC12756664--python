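"""Descriptive tables, printed-number arithmetic, figures, and renderers.

Rounding conventions follow epidemiological reporting practice: descriptive
percentages to two significant figures (integers at or above 10%, one
decimal below), balance proportions and differences to one decimal, effect
estimates and CI bounds to one decimal.  Machine outputs use ASCII minus
signs; every number in a rendered table is re-derivable from the underlying
JSON/CSV results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import RDEstimate, RDSpec, fit_sharp_rd, resolve_bandwidth
from .errors import InputError

logger = logging.getLogger("rdscreen")


# ---------------------------------------------------------------------------
# Printed-number arithmetic
# ---------------------------------------------------------------------------

def percent_share(n: int, total: int) -> float:
    """Descriptive percentage with two-significant-figure rounding.

    >= 10% rounds to an integer (34.1 -> 34); below 10% keeps one decimal
    (9.82 -> 9.8).  Returns 0 for an empty category.
    """
    if total <= 0:
        raise InputError("total must be positive")
    p = 100.0 * n / total
    return float(round(p)) if p >= 10 else round(p, 1)


def proportion_difference(p_above: float, p_below: float) -> float:
    """Percentage-point difference (above minus below), one decimal."""
    return round(p_above - p_below, 1)


def analysis_window(c: float, h: float) -> tuple[float, float]:
    """The analysis window [c - h, c + h] in running-variable units."""
    return (c - h, c + h)


def clinical_bmi_bound(bmi: float, fraction: float = 0.05) -> float:
    """BMI decrease equivalent to a given fractional weight loss, one decimal.

    BMI is proportional to weight at fixed height, so a 5% weight loss at a
    given BMI corresponds to a BMI drop of 0.05 * BMI.
    """
    return round(fraction * bmi, 1)


def sample_flow(eligible: int, followed: int, missing_rv: int) -> dict[str, float]:
    """Participant-flow arithmetic from eligibility to the analytic sample.

    Returns the analytic n (followed minus missing running variable), the
    exclusion percentage (1 decimal, of those followed) and the follow-up
    percentage (integer, of those eligible).
    """
    if not (0 <= missing_rv <= followed <= eligible):
        raise InputError("sample flow counts must satisfy 0 <= missing <= followed <= eligible")
    return {
        "eligible": eligible,
        "followed": followed,
        "missing_running_variable": missing_rv,
        "analytic_n": followed - missing_rv,
        "exclusion_pct": round(100.0 * missing_rv / followed, 1),
        "followup_pct": float(round(100.0 * followed / eligible)),
    }


# ---------------------------------------------------------------------------
# Descriptive (Table-1 style) report
# ---------------------------------------------------------------------------

def descriptive_table(
    table: pd.DataFrame, spec: RDSpec, characteristics: list[str] | None = None,
    outcome: str = "bmi_fu",
) -> pd.DataFrame:
    """Counts and percentages per characteristic level, full sample and window.

    Empty categories are rendered as ``0 (0)`` rather than omitted.  The
    window is [c - h, c + h].
    """
    h = resolve_bandwidth(table, outcome, spec)
    c = spec.cutoff
    window = table[(table["x"] >= c - h) & (table["x"] <= c + h)]
    if characteristics is None:
        skip = {"subject_id", "x", "above", "followed_up", "age"}
        characteristics = [
            col for col in table.columns
            if col not in skip and (table[col].dtype == object or table[col].nunique() <= 10)
        ]
    n_full, n_win = len(table), len(window)
    rows = []
    for ch in characteristics:
        levels = sorted(table[ch].dropna().unique())
        for lev in levels:
            nf = int((table[ch] == lev).sum())
            nw = int((window[ch] == lev).sum())
            rows.append(
                {
                    "characteristic": ch,
                    "level": str(lev),
                    "n_full": nf,
                    "pct_full": percent_share(nf, n_full),
                    "n_window": nw,
                    "pct_window": percent_share(nw, n_win) if n_win else 0.0,
                }
            )
    return pd.DataFrame(rows)


def render_descriptive(desc: pd.DataFrame) -> str:
    """Human-readable text rendering of a descriptive table."""
    lines = [f"{'characteristic':<14} {'level':<18} {'full n (%)':>14} {'window n (%)':>14}"]
    for _, r in desc.iterrows():
        full = f"{r.n_full} ({r.pct_full:g})"
        win = f"{r.n_window} ({r.pct_window:g})"
        lines.append(f"{r.characteristic:<14} {r.level:<18} {full:>14} {win:>14}")
    return "\n".join(lines)


def render_estimate(est: RDEstimate) -> str:
    """One-line human-readable rendering of an RD estimate (1-decimal style)."""
    return (
        f"{est.outcome}: {est.tau_hat:.1f} ({100 * (1 - est.alpha_level):.0f}% CI "
        f"{est.ci_low:.1f} to {est.ci_high:.1f}), p={est.p_value:.2f}, "
        f"n={est.n_left}+{est.n_right}, h={est.h_used:.2f}, order={est.order}"
    )


def render_grid(grid) -> str:
    """Text rendering of an order x covariate-set estimate grid."""
    lines = []
    for order in grid.orders:
        label = {1: "Local linear", 2: "Local quadratic"}.get(order, f"order {order}")
        lines.append(label)
        for set_label in grid.set_labels:
            cell = grid.estimate(order, set_label)
            if isinstance(cell, str):
                lines.append(f"  {set_label:<32} failed: {cell}")
            else:
                lines.append(
                    f"  {set_label:<32} {cell.tau_hat:.1f} "
                    f"({cell.ci_low:.1f} to {cell.ci_high:.1f})  p={cell.p_value:.2f}"
                )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def rd_plot(
    table: pd.DataFrame,
    outcome: str,
    spec: RDSpec,
    fit: RDEstimate | None = None,
    bins_per_side: int = 20,
):
    """Binned-scatter RD figure with side-specific fits and pointwise CI bands.

    Bin edges are aligned at the cutoff so no bin straddles it; thick lines
    are the side fits, thin lines the pointwise Wald bands, and a dashed
    vertical line marks the cutoff.  Returns a matplotlib Figure.
    """
    h = resolve_bandwidth(table, outcome, spec)
    c = spec.cutoff
    if fit is None or fit.covariate_set:
        fit = fit_sharp_rd(table, outcome, dataclasses.replace(spec, covariate_set=()))

    sub = table[(table["x"] >= c - h) & (table["x"] <= c + h)].dropna(subset=[outcome])
    fig, ax = plt.subplots(figsize=(7, 5))
    for side, (lo, hi) in (("below", (c - h, c)), ("above", (c, c + h))):
        edges = np.linspace(lo, hi, bins_per_side + 1)
        idx = np.clip(np.digitize(sub["x"], edges) - 1, 0, bins_per_side - 1)
        mask = (sub["x"] >= lo) & (sub["x"] < hi) if side == "below" else (sub["x"] >= lo) & (sub["x"] <= hi)
        # points sit at the within-bin mean of x, so a correct linear fit
        # passes exactly through noiseless bin means
        xs = [sub.loc[mask & (idx == i), "x"].mean() for i in range(bins_per_side)]
        means = [sub.loc[mask & (idx == i), outcome].mean() for i in range(bins_per_side)]
        ax.plot(xs, means, "o", ms=4, color="0.4")

        grid_t = np.linspace(lo - c, hi - c, 60)
        above = 1.0 if side == "above" else 0.0
        coef = fit.coefficients
        pred = coef["intercept"] + coef["above"] * above + coef["x_c"] * grid_t
        pred = pred + coef["above:x_c"] * above * grid_t
        if fit.order == 2:
            pred = pred + coef["x_c^2"] * grid_t**2 + coef["above:x_c^2"] * above * grid_t**2
        ax.plot(grid_t + c, pred, lw=2.2, color="C0")
        if fit.vcov is not None:
            G = np.zeros((grid_t.size, len(fit.column_names)))
            G[:, 0] = 1.0
            G[:, 1] = above
            G[:, 2] = grid_t
            G[:, 3] = above * grid_t
            if fit.order == 2:
                G[:, 4] = grid_t**2
                G[:, 5] = above * grid_t**2
            se = np.sqrt(np.einsum("ij,jk,ik->i", G, fit.vcov, G))
            from scipy.stats import norm as _norm

            z = _norm.ppf(1 - spec.alpha_level / 2)
            ax.plot(grid_t + c, pred - z * se, lw=0.8, color="C0")
            ax.plot(grid_t + c, pred + z * se, lw=0.8, color="C0")
    ax.axvline(c, ls="--", color="k", lw=1)
    ax.set_xlabel("running variable (baseline BMI, kg/m$^2$)")
    ax.set_ylabel(outcome)
    ax.set_title(f"Sharp RD at {c:g} (h = {h:.2f})")
    return fig


def density_histogram_plot(x, c: float, bin_width: float | None = None):
    """Histogram of the running variable with a dashed line at the cutoff."""
    x = np.asarray(x, dtype=float)
    if bin_width is None:
        bin_width = 2.0 * float(np.std(x)) * x.size ** (-0.5)
    lo = c - bin_width * np.ceil((c - x.min()) / bin_width)
    hi = c + bin_width * np.ceil((x.max() - c) / bin_width)
    edges = lo + bin_width * np.arange(round((hi - lo) / bin_width) + 1)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.hist(x, bins=edges, density=True, color="0.7", edgecolor="0.4")
    ax.axvline(c, ls="--", color="k", lw=1)
    ax.set_xlabel("running variable (baseline BMI, kg/m$^2$)")
    ax.set_ylabel("density")
    return fig


def forest_plot(estimates: list[RDEstimate], labels: list[str]):
    """Forest-style plot of estimates with CIs (bandwidth-sensitivity view)."""
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(estimates) + 1.5))
    ys = np.arange(len(estimates))[::-1]
    for y, est in zip(ys, estimates):
        ax.plot([est.ci_low, est.ci_high], [y, y], color="C0", lw=1.5)
        ax.plot(est.tau_hat, y, "o", color="C0")
    ax.axvline(0.0, ls="--", color="k", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels(labels)
    ax.set_xlabel("discontinuity estimate")
    return fig


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable sha256 over a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def write_manifest(path, config_obj, seed: int | None) -> dict:
    """Write a run manifest (config hash, seed, versions) as JSON; returns it."""
    import rdscreen

    manifest = {
        "config_sha256": config_hash(config_obj),
        "seed": seed,
        "rdscreen_version": rdscreen.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
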