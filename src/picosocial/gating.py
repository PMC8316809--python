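"""Rectangular threshold gating of cytometry-like event tables.

Events are retained when they clear independent per-channel minima on
size (fsc) and chlorophyll fluorescence (fl3), which excludes debris and
dead cells from counts; retained events with green fluorescence above a
third threshold are classified as the GFP-transformed partner population
in direct co-cultures. No clustering or compensation is performed —
events arrive as tidy tables, not vendor FCS binaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

REQUIRED_CHANNELS = ("fsc", "fl3")


@dataclass(frozen=True)
class GateConfig:
    """Per-channel minimum thresholds and the sampled volume.

    Thresholds are instrument-agnostic; defaults match the synthetic
    event generator's channel placement and must be recalibrated for
    real instruments via configuration.
    """

    fsc_min: float = 100.0
    fl3_min: float = 50.0
    green_min: float = 100.0
    sample_volume: float = 0.05  # ml

    def __post_init__(self) -> None:
        for name in ("fsc_min", "fl3_min", "green_min"):
            v = getattr(self, name)
            if not (v >= 0) or v != v:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not self.sample_volume > 0:
            raise ValueError("sample_volume must be > 0")


@dataclass
class GatedCounts:
    """Result of gating one event table."""

    n_total: int
    n_retained: int
    density: float  # cells ml^-1
    retained: pd.DataFrame


@dataclass
class GfpSplit:
    """Wild-type vs GFP partition of a gated event table."""

    n_wildtype: int
    n_gfp: int
    wildtype_density: float
    gfp_density: float


def gate_events(events: pd.DataFrame, gates: GateConfig) -> GatedCounts:
    """Retain events with ``fsc >= fsc_min`` and ``fl3 >= fl3_min``.

    Density is retained count divided by the sampled volume. An empty
    table yields density 0 with a warning rather than an error.
    """
    for chan in REQUIRED_CHANNELS:
        if chan not in events.columns:
            raise KeyError(f"event table lacks required channel column {chan!r}")
    if len(events) == 0:
        warnings.warn("empty event table: gated density is 0", stacklevel=2)
        return GatedCounts(0, 0, 0.0, events)
    keep = (events["fsc"] >= gates.fsc_min) & (events["fl3"] >= gates.fl3_min)
    retained = events.loc[keep]
    return GatedCounts(
        n_total=len(events),
        n_retained=len(retained),
        density=len(retained) / gates.sample_volume,
        retained=retained,
    )


def classify_gfp(gated: pd.DataFrame, gates: GateConfig) -> GfpSplit:
    """Split already-gated events into wild-type and GFP populations.

    Events with ``green >= green_min`` count as GFP; the two densities
    always sum to the gated density.
    """
    if "green" not in gated.columns:
        raise KeyError("event table lacks required channel column 'green'")
    n_gfp = int((gated["green"] >= gates.green_min).sum())
    n_wt = len(gated) - n_gfp
    return GfpSplit(
        n_wildtype=n_wt,
        n_gfp=n_gfp,
        wildtype_density=n_wt / gates.sample_volume,
        gfp_density=n_gfp / gates.sample_volume,
    )


def count_well(
    events: pd.DataFrame, gates: GateConfig, split_gfp: bool = False
) -> dict:
    """Gate one well's events and optionally split the GFP population.

    Returns a flat record suitable for a tidy counts table.
    """
    g = gate_events(events, gates)
    rec = {
        "n_events": g.n_total,
        "n_gated": g.n_retained,
        "density": g.density,
    }
    if split_gfp:
        s = classify_gfp(g.retained, gates)
        rec.update(
            wildtype_density=s.wildtype_density,
            gfp_density=s.gfp_density,
        )
    return rec
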