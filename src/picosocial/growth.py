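"""Specific growth-rate estimation from cell-count time series.

The default estimator is the two-point form

    mu = (ln(N_t) - ln(N)) / t        [day^-1]

with N the density at inoculation and N_t the density after t days —
exactly the quantity used for semi-continuous batch cultures growing
exponentially and density-independently. A log-linear OLS fit over all
sampling days is available as an opt-in robustness alternative.

Multi-transfer series (e.g. the 14-day direct co-culture assay spanning
two transfers) are split at transfer boundaries, where densities reset
to the inoculum, and the per-transfer estimates are averaged per well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CountSeries


@dataclass(frozen=True)
class GrowthEstimate:
    well_id: str
    mu: float  # day^-1
    method: str  # "two_point" | "log_linear"
    t_span: float  # days used
    fit_r2: float | None = None  # log-linear only

    def __post_init__(self) -> None:
        if not self.t_span > 0:
            raise ValueError("t_span must be > 0")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")


def estimate_growth_two_point(n0: float, nt: float, t: float) -> float:
    """Two-point specific growth rate, day^-1.

    Negative values are permitted (a declining culture); non-positive
    densities or time spans are domain errors.
    """
    if not n0 > 0:
        raise ValueError(f"n0 must be > 0, got {n0}")
    if not nt > 0:
        raise ValueError(f"nt must be > 0, got {nt}")
    if not t > 0:
        raise ValueError(f"t must be > 0, got {t}")
    return (np.log(nt) - np.log(n0)) / t


def estimate_growth_loglinear(
    times: np.ndarray, densities: np.ndarray, well_id: str = ""
) -> GrowthEstimate:
    """OLS slope of ln(density) on time, with its r^2.

    Falls back to the two-point estimator (with a warning) when fewer
    than three time points are available.
    """
    times = np.asarray(times, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if np.any(densities <= 0):
        raise ValueError("densities must be > 0")
    if len(times) < 3:
        warnings.warn(
            f"well {well_id or '?'}: <3 time points, falling back to the "
            "two-point estimator",
            stacklevel=2,
        )
        mu = estimate_growth_two_point(
            densities[0], densities[-1], times[-1] - times[0]
        )
        return GrowthEstimate(well_id, mu, "two_point", times[-1] - times[0])
    res = stats.linregress(times, np.log(densities))
    return GrowthEstimate(
        well_id=well_id,
        mu=float(res.slope),
        method="log_linear",
        t_span=float(times[-1] - times[0]),
        fit_r2=float(res.rvalue**2),
    )


def estimate_series(series: CountSeries, method: str = "two_point") -> GrowthEstimate:
    """Per-well growth estimate, averaging across transfers.

    Each transfer is estimated on its own (densities reset at transfer
    boundaries) and the per-transfer rates are averaged; ``t_span`` is
    the total time used.
    """
    if method not in ("two_point", "log_linear"):
        raise ValueError(f"unknown method {method!r}")
    transfers = (
        series.transfer
        if series.transfer is not None
        else np.ones(len(series.times), dtype=int)
    )
    mus, spans, r2s = [], [], []
    for tr in np.unique(transfers):
        mask = transfers == tr
        t = series.times[mask]
        d = series.densities[mask]
        if len(t) < 2:
            continue
        if method == "two_point":
            mus.append(estimate_growth_two_point(d[0], d[-1], t[-1] - t[0]))
        else:
            est = estimate_growth_loglinear(t, d, series.well_id)
            mus.append(est.mu)
            if est.fit_r2 is not None:
                r2s.append(est.fit_r2)
        spans.append(t[-1] - t[0])
    if not mus:
        raise ValueError(f"well {series.well_id}: no transfer with >= 2 points")
    return GrowthEstimate(
        well_id=series.well_id,
        mu=float(np.mean(mus)),
        method=method,
        t_span=float(np.sum(spans)),
        fit_r2=float(np.mean(r2s)) if r2s else None,
    )


def estimate_growth_table(
    counts: pd.DataFrame, method: str = "two_point"
) -> pd.DataFrame:
    """Tidy growth table: one row per well x population.

    Keeps the design keys (focal, partner, scenario, env, replicate
    indices) alongside ``mu``, the method, the time span used and the
    log-linear r^2 where applicable.
    """
    from .simulate import counts_to_series

    rows = []
    for series in counts_to_series(counts):
        est = estimate_series(series, method=method)
        rows.append(
            {
                "well_id": series.well_id,
                "focal": series.focal,
                "partner": series.partner,
                "scenario": series.scenario,
                "env": series.env,
                "bio_rep": series.bio_rep,
                "tech_rep": series.tech_rep,
                "population": series.population,
                "mu": est.mu,
                "method": est.method,
                "t_span": est.t_span,
                "fit_r2": est.fit_r2,
            }
        )
    return pd.DataFrame(rows)
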