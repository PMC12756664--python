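"""Robustness battery: placebo cutoffs, donut RD, bandwidth sensitivity, age coding.

Placebo cutoffs interior to one side of the true cutoff are fitted using only
that side's data, so the genuine jump at the true cutoff cannot contaminate
the placebo estimate; a placebo at the true cutoff reproduces the main fit.
Donut RD refits after deleting observations strictly within the donut radius.
Bandwidth sensitivity refits at a multiplicative grid around the reference h.
The age-specification check refits the covariate-adjusted model with age
coded categorically (5 bins) versus continuously.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .bandwidth import SENSITIVITY_MULTIPLIERS, scale_bandwidth
from .core import RDEstimate, RDSpec, fit_sharp_rd, resolve_bandwidth

logger = logging.getLogger("rdscreen")

PLACEBO_CUTOFFS = (24.0, 24.5, 25.5, 26.0)
DONUT_RADII = (0.5, 1.0, 1.5)


def placebo_cutoff_scan(
    table: pd.DataFrame,
    outcome: str,
    spec: RDSpec,
    cutoffs: tuple[float, ...] = PLACEBO_CUTOFFS,
) -> list[RDEstimate]:
    """Refit the RD model at pseudo-cutoffs where no discontinuity should exist.

    For a placebo cutoff below the true one, only observations below the true
    cutoff are used (both pseudo-groups untreated), and symmetrically above;
    the treated indicator is recomputed at each placebo cutoff inside the fit.
    """
    true_c = spec.cutoff
    results = []
    for cp in cutoffs:
        if cp < true_c:
            sub = table[table["x"] < true_c]
        elif cp > true_c:
            sub = table[table["x"] >= true_c]
        else:
            sub = table
        sub = sub.copy()
        sub.attrs = dict(table.attrs)
        results.append(fit_sharp_rd(sub, outcome, dataclasses.replace(spec, cutoff=cp)))
    return results


def donut_rd(
    table: pd.DataFrame,
    outcome: str,
    spec: RDSpec,
    radii: tuple[float, ...] = DONUT_RADII,
) -> list[RDEstimate]:
    """Refit after excluding observations strictly within each donut radius.

    Boundary points at exactly the radius distance are retained; the excluded
    count is recorded on each estimate.
    """
    return [
        fit_sharp_rd(table, outcome, dataclasses.replace(spec, donut_radius=r))
        for r in radii
    ]


def bandwidth_sensitivity(
    table: pd.DataFrame,
    outcome: str,
    spec: RDSpec,
    multipliers: tuple[float, ...] = SENSITIVITY_MULTIPLIERS,
) -> list[RDEstimate]:
    """Refit at each multiple of the reference bandwidth (0.5x ... 1.5x).

    The multiplier-1.0 fit reproduces the main estimate exactly.
    """
    h = resolve_bandwidth(table, outcome, spec)
    return [
        fit_sharp_rd(table, outcome, dataclasses.replace(spec, bandwidth=scale_bandwidth(h, m)))
        for m in multipliers
    ]


def age_specification_check(
    table: pd.DataFrame, outcome: str, spec: RDSpec
) -> tuple[RDEstimate, RDEstimate]:
    """Covariate-adjusted fits differing only in age coding (categorical vs continuous).

    Returns ``(categorical, continuous)``.  If the spec's covariate set names
    neither age column, ``age_group`` / ``age`` are added to it.
    """
    covs = list(spec.covariate_set)
    covs_cat = ["age_group" if c == "age" else c for c in covs]
    if "age_group" not in covs_cat:
        covs_cat.append("age_group")
    covs_cont = ["age" if c == "age_group" else c for c in covs_cat]
    est_cat = fit_sharp_rd(table, outcome, dataclasses.replace(spec, covariate_set=tuple(covs_cat)))
    est_cont = fit_sharp_rd(table, outcome, dataclasses.replace(spec, covariate_set=tuple(covs_cont)))
    return est_cat, est_cont


def robustness_report(
    table: pd.DataFrame, outcome: str, spec: RDSpec
) -> dict[str, list[RDEstimate] | tuple[RDEstimate, RDEstimate]]:
    """Run all four robustness checks and return them keyed by check name."""
    return {
        "placebo_cutoffs": placebo_cutoff_scan(table, outcome, spec),
        "donut": donut_rd(table, outcome, spec),
        "bandwidth_sensitivity": bandwidth_sensitivity(table, outcome, spec),
        "age_specification": age_specification_check(table, outcome, spec),
    }
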