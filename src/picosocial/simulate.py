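"""Synthetic semi-continuous batch-culture experiments.

Generates daily cell-count time series, per-well photophysiology records
and flow-cytometry-like event tables with the statistical structure the
downstream analysis assumes:

* exponential, density-independent growth from a 100 cells ml^-1 inoculum
  to ~1e5 cells ml^-1 per transfer;
* four social-milieu scenarios — monoculture, membrane-separated
  co-culture (ThinCert), cell-free supernatant spike, and direct
  co-culture with a GFP-transformed partner — crossed with pCO2
  environment, lineage pairings and nested biological/technical
  replicates;
* multiplicative lognormal noise, with a lineage-level deviate shared by
  all wells of one biological replicate population and independent
  technical noise on every observed density.

Growth modulation enters as ``mu_eff = mu_mono * reactiveness(scenario,
partner)``; monoculture and self-pair controls always have multiplier 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    SCENARIOS,
    LineageProfile,
    gfp_partner_profile,
    calibrated_profiles,
)

COUNTS_COLUMNS = [
    "well_id", "focal", "partner", "scenario", "env",
    "bio_rep", "tech_rep", "population", "transfer", "day", "density",
]

PHOTOPHYS_COLUMNS = [
    "well_id", "focal", "partner", "scenario", "env", "bio_rep", "tech_rep",
    "np_o2_umol_cell_h", "gp_o2_umol_cell_h", "carbon_quota_ugC",
]

EVENT_COLUMNS = ["well_id", "fsc", "fl3", "green", "event_class"]

#: default photosynthetic quotient used to express NP as O2 evolution
DEFAULT_PQ = 1.4
#: grams (micrograms) of carbon per mole (micromole): molar mass of C
CARBON_MOLAR_MASS = 12.011
#: respiration as a share of gross photosynthesis, GP = NP / (1 - share)
RESPIRATION_SHARE = 0.3


def _lognormal_sigma(cv: float) -> float:
    """Log-scale s.d. of a lognormal with coefficient of variation `cv`."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class CountSeries:
    """Daily cell densities for one population in one culture well."""

    well_id: str
    focal: str
    partner: str | None
    scenario: str
    env: str
    bio_rep: int
    tech_rep: int
    times: np.ndarray  # days since inoculation
    densities: np.ndarray  # cells ml^-1
    population: str = "focal"  # "focal" or "gfp" (direct co-culture)
    transfer: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if t.shape != d.shape:
            raise ValueError("times and densities must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("densities must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "densities", d)


@dataclass(frozen=True)
class ExperimentDesign:
    """Full-factorial layout of lineages x scenarios x replicates.

    ``thincert`` and ``spike`` scenarios pair every ordered focal x
    partner combination including self-pairs (the controls); ``direct``
    pairs each focal lineage with the designated GFP partner and yields
    two interleaved count series per well (wild-type focal + GFP).
    """

    lineages: tuple[LineageProfile, ...]
    scenarios: tuple[str, ...] = SCENARIOS
    n_bio: int = 3
    n_tech: int = 3
    duration_days: int = 7
    transfer_days: int = 7
    inoculum: float = 100.0
    full_factorial: bool = True
    gfp_partner: LineageProfile | None = None
    seed: int = 0
    mu_ceiling: float = 3.0  # plausibility ceiling, day^-1
    #: per-scenario overrides of duration_days (e.g. {"direct": 14})
    scenario_durations: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if self.transfer_days <= 0:
            raise ValueError("transfer_days must be positive")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")
        if not self.inoculum > 0:
            raise ValueError("inoculum must be > 0")
        for scen in self.scenarios:
            if scen not in SCENARIOS:
                raise ValueError(f"unknown scenario label: {scen!r}")
        if "direct" in self.scenarios and self.gfp_partner is None:
            object.__setattr__(
                self,
                "gfp_partner",
                gfp_partner_profile(env=self.lineages[0].env),
            )
        for focal, partner, scenario in self.iter_pairs():
            mu_eff = focal.mu_mono * focal.reactiveness_for(
                scenario, partner.lineage_id if partner else None
            )
            if mu_eff > self.mu_ceiling:
                raise ValueError(
                    f"effective growth rate {mu_eff:.3g} day^-1 for "
                    f"{focal.lineage_id} in {scenario} exceeds the "
                    f"plausibility ceiling {self.mu_ceiling} day^-1"
                )

    def duration_for(self, scenario: str) -> int:
        return self.scenario_durations.get(scenario, self.duration_days)

    def n_transfers(self, scenario: str) -> int:
        return max(1, math.ceil(self.duration_for(scenario) / self.transfer_days))

    def iter_pairs(
        self,
    ) -> Iterable[tuple[LineageProfile, LineageProfile | None, str]]:
        """Ordered (focal, partner, scenario) combinations of the layout."""
        for scenario in self.scenarios:
            if scenario == "monoculture":
                for focal in self.lineages:
                    yield focal, None, scenario
            elif scenario == "direct":
                for focal in self.lineages:
                    yield focal, self.gfp_partner, scenario
            else:  # thincert, spike: full factorial incl. self-pairs
                for focal in self.lineages:
                    for partner in self.lineages:
                        yield focal, partner, scenario


def calibrated_design(
    env: str = "ambient",
    scenarios: Sequence[str] = SCENARIOS,
    seed: int = 0,
    **kwargs,
) -> ExperimentDesign:
    """Calibrated six-lineage design for one pCO2 environment.

    Direct co-culture runs for 14 days over two 7-day transfers; the
    other scenarios use a single 7-day transfer.
    """
    return ExperimentDesign(
        lineages=tuple(calibrated_profiles(env=env)),
        scenarios=tuple(scenarios),
        gfp_partner=gfp_partner_profile(env=env),
        duration_days=kwargs.pop("duration_days", 7),
        scenario_durations=kwargs.pop("scenario_durations", {"direct": 14}),
        seed=seed,
        **kwargs,
    )


@dataclass
class SimulationResult:
    """Tidy outputs of one simulated experiment."""

    counts: pd.DataFrame
    photophys: pd.DataFrame
    design: ExperimentDesign

    def metadata(self) -> dict:
        from . import __version__

        d = self.design
        return {
            "seed": d.seed,
            "version": __version__,
            "scenarios": list(d.scenarios),
            "lineages": [p.lineage_id for p in d.lineages],
            "env": sorted({p.env for p in d.lineages}),
            "n_bio": d.n_bio,
            "n_tech": d.n_tech,
            "duration_days": d.duration_days,
            "transfer_days": d.transfer_days,
            "inoculum": d.inoculum,
        }

    def count_series(self) -> list[CountSeries]:
        return counts_to_series(self.counts)


def counts_to_series(counts: pd.DataFrame) -> list[CountSeries]:
    """Split a tidy counts table into per-population CountSeries."""
    out = []
    keys = ["well_id", "population"]
    for (well_id, population), grp in counts.groupby(keys, sort=False):
        grp = grp.sort_values("day")
        first = grp.iloc[0]
        partner = first["partner"]
        out.append(
            CountSeries(
                well_id=well_id,
                focal=first["focal"],
                partner=None if pd.isna(partner) or partner == "" else partner,
                scenario=first["scenario"],
                env=first["env"],
                bio_rep=int(first["bio_rep"]),
                tech_rep=int(first["tech_rep"]),
                times=grp["day"].to_numpy(dtype=float),
                densities=grp["density"].to_numpy(dtype=float),
                population=population,
                transfer=grp["transfer"].to_numpy(dtype=int),
            )
        )
    return out


def _growth_curve(
    design: ExperimentDesign,
    scenario: str,
    mu: float,
    rng: np.random.Generator,
    cv_tech: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Days, transfer indices and noisy densities for one population."""
    days = np.arange(design.duration_for(scenario) + 1)
    n_tr = design.n_transfers(scenario)
    transfer = np.minimum(days // design.transfer_days, n_tr - 1)
    t_in = days - transfer * design.transfer_days
    dens = design.inoculum * np.exp(mu * t_in)
    if cv_tech > 0:
        sigma = _lognormal_sigma(cv_tech)
        dens = dens * np.exp(rng.normal(0.0, sigma, size=dens.shape))
    return days, transfer + 1, dens


def simulate_experiment(design: ExperimentDesign) -> SimulationResult:
    """Run the generator for one design.

    Densities follow ``N * exp(mu_eff * t)`` per transfer with
    multiplicative lognormal technical noise; each biological replicate
    population of a lineage carries one shared lognormal growth deviate
    (CV = ``cv_bio``) across all its wells. Per-well net photosynthesis
    is drawn around each profile's ``np_specific`` with the same nesting
    and expressed as umol O2 cell^-1 h^-1 via the photosynthetic
    quotient, alongside gross photosynthesis and the carbon quota.
    """
    rng = np.random.default_rng(design.seed)

    # one growth deviate and one NP deviate per biological replicate
    # population; shared across scenarios and partners
    all_profiles = list(design.lineages)
    if design.gfp_partner is not None:
        all_profiles.append(design.gfp_partner)
    bio_mu: dict[tuple[str, int], float] = {}
    bio_np: dict[tuple[str, int], float] = {}
    for prof in all_profiles:
        s_bio = _lognormal_sigma(prof.cv_bio)
        for b in range(1, design.n_bio + 1):
            key = (prof.lineage_id, b)
            if key in bio_mu:
                continue
            bio_mu[key] = math.exp(rng.normal(0.0, s_bio)) if s_bio > 0 else 1.0
            bio_np[key] = math.exp(rng.normal(0.0, s_bio)) if s_bio > 0 else 1.0

    count_rows: list[dict] = []
    photo_rows: list[dict] = []
    widx = 0
    for focal, partner, scenario in design.iter_pairs():
        partner_id = partner.lineage_id if partner is not None else None
        for b in range(1, design.n_bio + 1):
            for tr in range(1, design.n_tech + 1):
                widx += 1
                well_id = f"W{widx:05d}"
                base = {
                    "well_id": well_id,
                    "focal": focal.lineage_id,
                    "partner": partner_id,
                    "scenario": scenario,
                    "env": focal.env,
                    "bio_rep": b,
                    "tech_rep": tr,
                }
                populations = [("focal", focal, partner_id)]
                if scenario == "direct":
                    # the GFP partner grows alongside; it sees the focal
                    # lineage as its (non-self) partner
                    populations.append(("gfp", partner, focal.lineage_id))
                for pop_label, prof, pop_partner in populations:
                    mu_eff = prof.mu_mono * prof.reactiveness_for(
                        scenario, pop_partner
                    )
                    mu_well = mu_eff * bio_mu[(prof.lineage_id, b)]
                    days, transfer, dens = _growth_curve(
                        design, scenario, mu_well, rng, prof.cv_tech
                    )
                    for d, trf, den in zip(days, transfer, dens):
                        row = dict(base)
                        row.update(
                            population=pop_label,
                            transfer=int(trf),
                            day=int(d),
                            density=float(den),
                        )
                        count_rows.append(row)
                # photophysiology: one record per well, for the focal
                np_c = focal.np_specific * bio_np[(focal.lineage_id, b)]
                if focal.cv_tech > 0:
                    np_c *= math.exp(
                        rng.normal(0.0, _lognormal_sigma(focal.cv_tech))
                    )
                np_o2 = np_c * focal.carbon_quota * DEFAULT_PQ / CARBON_MOLAR_MASS
                photo_rows.append(
                    dict(
                        base,
                        np_o2_umol_cell_h=np_o2,
                        gp_o2_umol_cell_h=np_o2 / (1.0 - RESPIRATION_SHARE),
                        carbon_quota_ugC=focal.carbon_quota,
                    )
                )

    counts = pd.DataFrame(count_rows, columns=COUNTS_COLUMNS)
    photophys = pd.DataFrame(photo_rows, columns=PHOTOPHYS_COLUMNS)
    return SimulationResult(counts=counts, photophys=photophys, design=design)


@dataclass(frozen=True)
class EventChannelModel:
    """Lognormal channel distributions for the three event classes.

    Modes are placed so that intact cells sit well above the default
    size (fsc) and chlorophyll (fl3) gates, debris well below the fl3
    gate, and GFP-positive cells well above the green gate.
    """

    cell_fsc: tuple[float, float] = (250.0, 0.25)  # (median, log-sd)
    cell_fl3: tuple[float, float] = (300.0, 0.30)
    debris_fsc: tuple[float, float] = (30.0, 0.40)
    debris_fl3: tuple[float, float] = (5.0, 0.50)
    gfp_green: tuple[float, float] = (500.0, 0.30)
    dim_green: tuple[float, float] = (10.0, 0.40)


def simulate_events(
    series: CountSeries,
    debris_fraction: float = 0.1,
    gfp_fraction: float = 0.0,
    sample_volume: float = 0.05,
    day: float | None = None,
    n_events: int | None = None,
    channels: EventChannelModel = EventChannelModel(),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Flow-cytometry-like event table for one well at one sampling day.

    Cell counts are Poisson around ``density * sample_volume`` (so the
    expected gated count matches the series density) with debris added
    on top at the requested fraction of all events; pass ``n_events`` to
    fix the total instead, in which case debris is binomially thinned.
    The hidden ``event_class`` column (cell / gfp_cell / debris) is kept
    for validation only and is never consumed by the gating pipeline.
    """
    if not 0 <= debris_fraction < 1:
        raise ValueError("debris_fraction must be in [0, 1)")
    if not 0 <= gfp_fraction < 1:
        raise ValueError("gfp_fraction must be in [0, 1)")
    if not sample_volume > 0:
        raise ValueError("sample_volume must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    if n_events is not None:
        n_debris = int(rng.binomial(n_events, debris_fraction))
        n_cells = n_events - n_debris
    else:
        if day is None:
            density = float(series.densities[-1])
        else:
            idx = int(np.argmin(np.abs(series.times - day)))
            density = float(series.densities[idx])
        lam = density * sample_volume
        n_cells = int(rng.poisson(lam))
        n_debris = (
            int(rng.poisson(lam * debris_fraction / (1.0 - debris_fraction)))
            if debris_fraction > 0
            else 0
        )
    n_gfp = int(rng.binomial(n_cells, gfp_fraction)) if gfp_fraction > 0 else 0
    n_wt = n_cells - n_gfp

    def draw(mode: tuple[float, float], n: int) -> np.ndarray:
        median, sd = mode
        return median * np.exp(rng.normal(0.0, sd, size=n))

    fsc = np.concatenate([
        draw(channels.cell_fsc, n_wt),
        draw(channels.cell_fsc, n_gfp),
        draw(channels.debris_fsc, n_debris),
    ])
    fl3 = np.concatenate([
        draw(channels.cell_fl3, n_wt),
        draw(channels.cell_fl3, n_gfp),
        draw(channels.debris_fl3, n_debris),
    ])
    green = np.concatenate([
        draw(channels.dim_green, n_wt),
        draw(channels.gfp_green, n_gfp),
        draw(channels.dim_green, n_debris),
    ])
    event_class = np.array(
        ["cell"] * n_wt + ["gfp_cell"] * n_gfp + ["debris"] * n_debris
    )
    order = rng.permutation(len(event_class))
    return pd.DataFrame(
        {
            "well_id": series.well_id,
            "fsc": fsc[order],
            "fl3": fl3[order],
            "green": green[order],
            "event_class": event_class[order],
        },
        columns=EVENT_COLUMNS,
    )
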