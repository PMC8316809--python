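"""Carbon budgets: net photosynthesis vs the carbon demand of growth.

Per-cell O2 evolution rates are converted to biomass-specific carbon
fixation through the photosynthetic quotient (PQ, mol O2 evolved per mol
C fixed) and the cellular carbon quota:

    np_c_specific = (np_o2 / PQ * 12.011) / carbon_quota      [h^-1]

The carbon demand of observed growth is the instantaneous biomass-
specific accretion rate mu/24 (h^-1) at fixed quota. Their ratio is the
NP-to-growth carbon ratio; the surplus percentage (ratio - 1) x 100 says
how much photosynthate beyond growth demand is available for exudation,
storage or other processes. A surplus <= 0 flags use of storage or
external carbon, not negative photosynthesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CARBON_MOLAR_MASS, DEFAULT_PQ


@dataclass(frozen=True)
class PhotoPhysRecord:
    """Per-cell photophysiology of one culture well.

    Rates are umol O2 cell^-1 h^-1; the quota is ug C cell^-1. When
    gross photosynthesis is given, respiration R = GP - NP is expected
    to be non-negative (warned about, not rejected, when violated —
    measurement error can produce NP > GP).
    """

    well_id: str
    np_o2: float
    carbon_quota: float
    gp_o2: float | None = None

    def __post_init__(self) -> None:
        if not self.carbon_quota > 0:
            raise ValueError("carbon_quota must be > 0")
        if self.gp_o2 is not None and self.gp_o2 - self.np_o2 < 0:
            warnings.warn(
                f"well {self.well_id}: GP < NP implies negative respiration",
                stacklevel=2,
            )

    @property
    def respiration_o2(self) -> float | None:
        return None if self.gp_o2 is None else self.gp_o2 - self.np_o2


@dataclass(frozen=True)
class CarbonBudget:
    """NP and growth in common carbon units, and their ratio."""

    well_id: str
    np_c_specific: float  # h^-1
    growth_c_specific: float  # h^-1
    np_growth_ratio: float | None  # dimensionless; None when mu <= 0
    surplus_pct: float | None  # percent
    label: str  # storage_use | balanced | surplus | undefined
    reason: str = ""


def o2_to_specific_carbon(
    np_o2: float, pq: float = DEFAULT_PQ, carbon_quota: float = 1.5e-7
) -> float:
    """Convert umol O2 cell^-1 h^-1 to ug C fixed per ug C biomass per hour."""
    if not pq > 0:
        raise ValueError(f"pq must be > 0, got {pq}")
    if not carbon_quota > 0:
        raise ValueError(f"carbon_quota must be > 0, got {carbon_quota}")
    return (np_o2 / pq * CARBON_MOLAR_MASS) / carbon_quota


def growth_carbon_demand(mu: float) -> float:
    """Biomass-specific carbon demand (h^-1) of growth at rate mu (day^-1).

    Instantaneous form mu/24 at fixed carbon quota; the compound form
    exp(mu/24) - 1 differs by under 2% for mu <= 1 day^-1.
    """
    return mu / 24.0


def budget(
    record: PhotoPhysRecord, mu: float, pq: float = DEFAULT_PQ
) -> CarbonBudget:
    """Carbon budget of one well from its photophysiology and growth."""
    np_c = o2_to_specific_carbon(record.np_o2, pq, record.carbon_quota)
    demand = growth_carbon_demand(mu)
    if mu <= 0:
        return CarbonBudget(
            well_id=record.well_id,
            np_c_specific=np_c,
            growth_c_specific=demand,
            np_growth_ratio=None,
            surplus_pct=None,
            label="undefined",
            reason="non_positive_growth",
        )
    ratio = np_c / demand
    surplus = (ratio - 1.0) * 100.0
    if np.isclose(ratio, 1.0, rtol=0, atol=1e-12):
        label = "balanced"
    elif ratio < 1.0:
        label = "storage_use"
    else:
        label = "surplus"
    return CarbonBudget(
        well_id=record.well_id,
        np_c_specific=np_c,
        growth_c_specific=demand,
        np_growth_ratio=ratio,
        surplus_pct=surplus,
        label=label,
    )


def monoculture_allocation(budgets: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate monoculture carbon allocation of each lineage.

    Averages the NP/growth ratio and surplus percentage over technical
    replicates of the monoculture wells, yielding one row per focal
    lineage x env x biological replicate — the allocation baseline the
    reactiveness models regress responses against.
    """
    mono = budgets[budgets["scenario"] == "monoculture"]
    return (
        mono.groupby(["focal", "env", "bio_rep"], as_index=False)[
            ["np_growth_ratio", "surplus_pct"]
        ].mean()
    )


def reactiveness_table(responses: pd.DataFrame, budgets: pd.DataFrame) -> pd.DataFrame:
    """Join response records with the focal lineage's monoculture budget."""
    alloc = monoculture_allocation(budgets)
    return responses.merge(alloc, on=["focal", "env", "bio_rep"], how="inner")


def budget_table(
    photophys: pd.DataFrame, growth: pd.DataFrame, pq: float = DEFAULT_PQ
) -> pd.DataFrame:
    """Join photophysiology and growth tables into a tidy budget table.

    Joins on ``well_id`` (focal population only); wells missing from
    either table are dropped.
    """
    g = growth
    if "population" in g.columns:
        g = g[g["population"] == "focal"]
    merged = photophys.merge(g[["well_id", "mu"]], on="well_id", how="inner")
    rows = []
    for _, r in merged.iterrows():
        b = budget(
            PhotoPhysRecord(
                well_id=r["well_id"],
                np_o2=r["np_o2_umol_cell_h"],
                gp_o2=r.get("gp_o2_umol_cell_h"),
                carbon_quota=r["carbon_quota_ugC"],
            ),
            mu=r["mu"],
            pq=pq,
        )
        rows.append(
            {
                "well_id": b.well_id,
                "focal": r.get("focal"),
                "partner": r.get("partner"),
                "scenario": r.get("scenario"),
                "env": r.get("env"),
                "bio_rep": r.get("bio_rep"),
                "tech_rep": r.get("tech_rep"),
                "mu": r["mu"],
                "np_c_specific": b.np_c_specific,
                "growth_c_specific": b.growth_c_specific,
                "np_growth_ratio": b.np_growth_ratio,
                "surplus_pct": b.surplus_pct,
                "label": b.label,
                "reason": b.reason,
            }
        )
    return pd.DataFrame(rows)
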