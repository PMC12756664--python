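"""Risk-ratio RD for binary outcomes via modified Poisson regression.

"Modified Poisson" here means Poisson-family log-link estimating equations
applied to a 0/1 outcome, with a robust sandwich variance — the conventional
device for estimating risk ratios directly.  The RD design is the same
centered specification as the continuous model,

    log E[Y | x] = a0 + a1*Above + a2*(x - c) + a3*Above*(x - c),

with triangular kernel weights multiplying the estimating equations as
frequency-type weights; exp(a1) is the risk ratio at the cutoff.  Newton
iteration is capped at 100 steps with a 1e-8 coefficient-change tolerance.
Binary fits are unadjusted by default.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import RDEstimate, RDSpec, fit_sharp_rd, kernel_weights, resolve_bandwidth
from .errors import ConvergenceError, InputError, SampleSizeError, SeparationError

logger = logging.getLogger("rdscreen")

MAX_ITER = 100
COEF_TOL = 1e-8


def classify_activity(met_min):
    """1 iff weekly activity is at least 600 MET-minutes (guideline threshold)."""
    arr = np.asarray(met_min, dtype=float)
    out = (arr >= 600.0).astype(int)
    return int(out) if arr.ndim == 0 else out


@dataclass
class RiskRatioEstimate:
    """A fitted risk-ratio discontinuity for a binary outcome."""

    log_rr: float
    rr: float
    se_log_rr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_left: int
    n_right: int
    outcome: str
    h_used: float = np.nan
    n_iter: int = 0
    converged: bool = True
    risks_above_one: bool = False
    coefficients: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def weighted_poisson_irls(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, max_iter: int = MAX_ITER, tol: float = COEF_TOL
):
    """Newton/IRLS solver for weighted Poisson log-link estimating equations.

    Returns ``(beta, cov, n_iter)`` where ``cov`` is the robust sandwich
    H^-1 (sum of weighted score outer products) H^-1 with H = X' diag(w mu) X.
    Raises :class:`ConvergenceError` (with the step-size trace in the
    message) if the coefficient change has not fallen below ``tol`` within
    ``max_iter`` iterations.
    """
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log(max(float(np.average(y, weights=w)), 1e-10))
    trace = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        score = X.T @ (w * (y - mu))
        H = (X * (w * mu)[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}: {exc}") from exc
        beta = beta + step
        delta = float(np.max(np.abs(step)))
        trace.append(delta)
        if delta < tol:
            mu = np.exp(X @ beta)
            H = (X * (w * mu)[:, None]).T @ X
            Hinv = np.linalg.inv(H)
            Xs = X * (w * (y - mu))[:, None]
            cov = Hinv @ (Xs.T @ Xs) @ Hinv
            return beta, cov, it
    raise ConvergenceError(
        f"Poisson estimating equations did not converge in {max_iter} iterations; "
        f"last 5 coefficient changes: {[f'{d:.3g}' for d in trace[-5:]]}"
    )


def fit_binary_rd(
    table: pd.DataFrame, outcome: str, spec: RDSpec, include_slopes: bool = True
) -> RiskRatioEstimate:
    """Modified Poisson RD fit of a binary outcome; returns a risk ratio.

    ``include_slopes=False`` drops the running-variable trend terms (design is
    intercept + treatment only), in which case the fit with uniform weights
    collapses to the closed-form 2x2 risk ratio.
    """
    if outcome not in table.columns:
        raise InputError(f"outcome column {outcome!r} not found")
    h = resolve_bandwidth(table, outcome, spec)
    c = spec.cutoff

    x = table["x"].to_numpy(dtype=float)
    y_all = table[outcome].to_numpy(dtype=float)
    w_all = kernel_weights(x, c, h, spec.kernel)
    use = (w_all > 0) & np.isfinite(y_all)
    if spec.donut_radius > 0:
        use &= np.abs(x - c) >= spec.donut_radius
    xs, y, w = x[use], y_all[use], w_all[use]
    if not np.isin(y, (0.0, 1.0)).all():
        raise InputError(f"outcome {outcome!r} is not 0/1")
    t = xs - c
    above = (xs >= c).astype(float)

    n_left, n_right = int((above == 0).sum()), int((above == 1).sum())
    for side, mask in (("below", above == 0), ("above", above == 1)):
        if mask.sum() == 0:
            raise SampleSizeError(f"no usable observations {side} the cutoff at h={h:.3g}")
        if y[mask].min() == y[mask].max():
            raise SeparationError(
                f"outcome {outcome!r} is constant ({y[mask][0]:.0f}) {side} the cutoff; "
                "risk ratio not identified"
            )

    if include_slopes:
        X = np.column_stack([np.ones_like(t), above, t, above * t])
        names = ["intercept", "above", "x_c", "above:x_c"]
        if spec.order == 2:
            X = np.column_stack([X, t**2, above * t**2])
            names += ["x_c^2", "above:x_c^2"]
    else:
        X = np.column_stack([np.ones_like(t), above])
        names = ["intercept", "above"]

    beta, cov, n_iter = weighted_poisson_irls(y, X, w)
    mu = np.exp(X @ beta)
    risks_above_one = bool((mu > 1.0).any())
    if risks_above_one:
        logger.warning("fit %s: %d fitted risks exceed 1 at convergence", outcome, int((mu > 1).sum()))

    log_rr = float(beta[1])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    z = norm.ppf(1.0 - spec.alpha_level / 2.0)
    p = 2.0 * norm.sf(abs(log_rr) / se) if se > 0 else (0.0 if log_rr != 0 else 1.0)
    return RiskRatioEstimate(
        log_rr=log_rr,
        rr=float(np.exp(log_rr)),
        se_log_rr=se,
        ci_low=float(np.exp(log_rr - z * se)),
        ci_high=float(np.exp(log_rr + z * se)),
        p_value=float(p),
        n_left=n_left,
        n_right=n_right,
        outcome=outcome,
        h_used=h,
        n_iter=n_iter,
        converged=True,
        risks_above_one=risks_above_one,
        coefficients=dict(zip(names, (float(b) for b in beta))),
    )


def secondary_outcome_battery(
    table: pd.DataFrame, spec: RDSpec, outcomes: dict[str, str]
) -> dict[str, RDEstimate | RiskRatioEstimate | str]:
    """Consolidated RD report over a dictionary of secondary outcomes.

    ``outcomes`` maps column name -> 'continuous' | 'binary'.  Continuous
    outcomes go through the linear RD fit (unadjusted), binary outcomes
    through the modified Poisson fit; per-outcome failures are reported as
    strings without aborting the battery.
    """
    results: dict[str, RDEstimate | RiskRatioEstimate | str] = {}
    unadjusted = dataclasses.replace(spec, covariate_set=())
    for name, kind in outcomes.items():
        try:
            if kind == "continuous":
                results[name] = fit_sharp_rd(table, name, unadjusted)
            elif kind == "binary":
                results[name] = fit_binary_rd(table, name, unadjusted)
            else:
                raise InputError(f"outcome {name!r}: unknown kind {kind!r}")
        except Exception as exc:  # noqa: BLE001 - reported per outcome
            logger.warning("secondary outcome %s failed: %s", name, exc)
            results[name] = f"{type(exc).__name__}: {exc}"
    return results


def battery_frame(results: dict) -> pd.DataFrame:
    """Battery results as a tidy DataFrame (one row per outcome)."""
    rows = []
    for name, res in results.items():
        if isinstance(res, str):
            rows.append({"outcome": name, "error": res})
        elif isinstance(res, RiskRatioEstimate):
            rows.append(
                {
                    "outcome": name, "kind": "binary", "estimate": res.rr,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p_value": res.p_value, "scale": "risk ratio", "error": "",
                }
            )
        else:
            rows.append(
                {
                    "outcome": name, "kind": "continuous", "estimate": res.tau_hat,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p_value": res.p_value, "scale": "outcome units", "error": "",
                }
            )
    return pd.DataFrame(rows)
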