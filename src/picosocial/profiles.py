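"""Lineage phenotype profiles and calibration presets.

A :class:`LineageProfile` bundles everything the synthetic experiment needs
to know about one picoplankton lineage (strain): its intrinsic monoculture
growth rate, how strongly it modulates growth when exposed to non-self
conspecifics in each social-milieu scenario ("reactiveness"), its
biomass-specific net photosynthesis, its cellular carbon quota, and the
noise levels of its biological and technical replicates.

The ``calibrated_profiles`` preset calibrates six lineages per pCO2
environment to the published phenotypic ranges for *Ostreococcus*:
monoculture growth rates spanning 0.45-1.1 day^-1, graded responsiveness
(direct co-culture > membrane-separated > supernatant spike), a mean
net-photosynthesis-to-growth carbon ratio of 1.92 in the ambient
environment, a 3.9-fold larger between-lineage growth variance and a
1.3-fold damped response under elevated pCO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

SCENARIOS = ("monoculture", "thincert", "spike", "direct")
PAIRED_SCENARIOS = ("thincert", "spike", "direct")

#: bounds of plausible monoculture growth (day^-1) for this organism
MU_RANGE = (0.45, 1.1)

ReactivenessMap = Mapping[str, Union[float, Mapping[str, float]]]


@dataclass(frozen=True)
class LineageProfile:
    """Phenotype of one lineage in one pCO2 environment.

    Parameters
    ----------
    lineage_id:
        Label for the lineage (strain).
    env:
        ``"ambient"`` or ``"elevated"`` pCO2 history.
    mu_mono:
        Intrinsic monoculture growth rate, day^-1. Must be positive.
    reactiveness:
        Per-scenario multiplicative growth modulation when a *non-self*
        partner is present. Each entry maps a scenario label to either a
        single multiplier (applied for every partner) or a
        ``{partner_id: multiplier}`` mapping. Monoculture and self-pairs
        always have multiplier 1.
    np_specific:
        Biomass-specific net photosynthesis, h^-1 in carbon units
        (ug C fixed per ug C biomass per hour).
    carbon_quota:
        Cellular carbon content, ug C per cell. Must be positive.
    cv_bio, cv_tech:
        Coefficients of variation of the biological-replicate growth
        deviate and of per-observation technical count noise.
    is_gfp:
        Marks the designated GFP-transformed partner lineage used in
        direct co-culture.
    """

    lineage_id: str
    env: str
    mu_mono: float
    reactiveness: ReactivenessMap = field(default_factory=dict)
    np_specific: float = 0.04
    carbon_quota: float = 1.5e-7
    cv_bio: float = 0.10
    cv_tech: float = 0.05
    is_gfp: bool = False

    def __post_init__(self) -> None:
        if self.env not in ("ambient", "elevated"):
            raise ValueError(f"env must be 'ambient' or 'elevated', got {self.env!r}")
        if not self.mu_mono > 0:
            raise ValueError(f"mu_mono must be > 0, got {self.mu_mono}")
        if not self.carbon_quota > 0:
            raise ValueError(f"carbon_quota must be > 0, got {self.carbon_quota}")
        if self.cv_bio < 0 or self.cv_tech < 0:
            raise ValueError("cv_bio and cv_tech must be >= 0")
        for scenario, value in self.reactiveness.items():
            if scenario not in SCENARIOS:
                raise ValueError(f"unknown scenario in reactiveness: {scenario!r}")
            values = value.values() if isinstance(value, Mapping) else (value,)
            if any(not v > 0 for v in values):
                raise ValueError(
                    f"reactiveness for scenario {scenario!r} must be > 0"
                )

    def reactiveness_for(self, scenario: str, partner: str | None) -> float:
        """Growth multiplier for this lineage in `scenario` with `partner`.

        Returns 1.0 for monoculture and for self-pairs (the experimental
        controls): modulation is a response to *non-self* cues only.
        """
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario: {scenario!r}")
        if scenario == "monoculture" or partner is None or partner == self.lineage_id:
            return 1.0
        value = self.reactiveness.get(scenario, 1.0)
        if isinstance(value, Mapping):
            return float(value.get(partner, 1.0))
        return float(value)


def regression_to_range_multiplier(
    mu_mono: float, gamma: float, target_mid: float | None = None
) -> float:
    """Reactiveness multiplier pulling growth towards the mid-range rate.

    ``multiplier = (target_mid / mu_mono) ** gamma`` with ``gamma`` in
    [0, 1]: slow growers speed up, fast growers slow down, and gamma = 0
    switches modulation off. ``target_mid`` defaults to the midpoint of
    the plausible growth range.
    """
    if not 0 <= gamma <= 1:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if target_mid is None:
        target_mid = 0.5 * (MU_RANGE[0] + MU_RANGE[1])
    return float((target_mid / mu_mono) ** gamma)


#: graded responsiveness: direct contact elicits the strongest modulation,
#: membrane-separated (ThinCert) co-culture an intermediate one, and
#: cell-free supernatant spikes the weakest.
DEFAULT_GAMMA = {"direct": 0.5, "thincert": 0.35, "spike": 0.2}

#: calibration: mean NP/growth carbon ratio in ambient monocultures; the
#: elevated-pCO2 surplus is 1.14-fold lower.
AMBIENT_NP_GROWTH_RATIO = 1.92
ELEVATED_SURPLUS_DAMPING = 1.14


def calibrated_profiles(
    env: str = "ambient",
    n_lineages: int = 6,
    gamma: Mapping[str, float] | None = None,
    cv_bio: float = 0.10,
    cv_tech: float = 0.05,
    carbon_quota: float = 1.5e-7,
) -> list[LineageProfile]:
    """Six calibrated lineages for one pCO2 environment.

    Ambient lineages span monoculture growth rates 0.45-1.1 day^-1.
    Elevated-pCO2 lineages grow faster on average, their between-lineage
    spread is sqrt(3.9)-fold wider (a 3.9-fold variance increase), and
    their reactiveness exponents are shrunk so that the average fold
    change induced by conspecifics is 1.3-fold lower.
    """
    if gamma is None:
        gamma = DEFAULT_GAMMA
    lo, hi = MU_RANGE
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    offsets = np.linspace(-1.0, 1.0, n_lineages)
    ambient_mus = mid + half * offsets
    if env == "ambient":
        mus = ambient_mus
        target = mid
        ratio = AMBIENT_NP_GROWTH_RATIO
        gamma_scale = 1.0
    elif env == "elevated":
        # faster mean growth and a sqrt(3.9)-wider spread (a 3.9-fold
        # between-lineage variance increase)
        target = mid + 0.1
        mus = np.clip(target + half * np.sqrt(3.9) * offsets, 0.1, None)
        ratio = 1.0 + (AMBIENT_NP_GROWTH_RATIO - 1.0) / ELEVATED_SURPLUS_DAMPING
        # responses to conspecifics are 1.3-fold weaker than ambient:
        # shrink the modulation exponent enough to also undo the wider
        # spread's amplification of the regression-to-range pull, so the
        # mean |log response| lands 1.3-fold below the ambient value
        amp_ambient = float(np.mean(np.abs(np.log(mid / ambient_mus))))
        amp_elevated = float(np.mean(np.abs(np.log(target / mus))))
        gamma_scale = amp_ambient / (1.3 * amp_elevated)
    else:
        raise ValueError(f"env must be 'ambient' or 'elevated', got {env!r}")

    profiles = []
    for i, mu in enumerate(mus):
        mu = float(mu)
        reactiveness = {
            scen: regression_to_range_multiplier(mu, g * gamma_scale, target)
            for scen, g in gamma.items()
        }
        profiles.append(
            LineageProfile(
                lineage_id=f"L{i + 1:02d}",
                env=env,
                mu_mono=mu,
                reactiveness=reactiveness,
                # np_specific set so NP/growth carbon ratio hits the preset
                np_specific=ratio * mu / 24.0,
                carbon_quota=carbon_quota,
                cv_bio=cv_bio,
                cv_tech=cv_tech,
            )
        )
    return profiles


def gfp_partner_profile(
    env: str = "ambient", mu_mono: float = 0.9, **kwargs
) -> LineageProfile:
    """The designated GFP-transformed partner used in direct co-culture."""
    return LineageProfile(
        lineage_id="GFP-Oth95",
        env=env,
        mu_mono=mu_mono,
        is_gfp=True,
        **kwargs,
    )
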