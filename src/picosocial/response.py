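"""Response ratios to conspecific cues and variance partitioning.

The response of a focal lineage to a social-milieu treatment is

    response = mu_focal_in_treatment / mu_focal_alone

so 1 means no change, >1 faster growth in mixed culture, <1 slower.
Technical replicates are averaged before anything else; biological
replicates are the inferential unit. Each treatment well is matched to
the mean monoculture growth of the same focal lineage, environment and
biological replicate, preferring the scenario's own self-pair control
(e.g. the same lineage on both sides of a ThinCert membrane) when one
exists.

Variance partitioning follows the mono- vs mixed-culture contrast of
within-lineage variability (mean over lineages of the replicate variance
of mu) and between-lineage variability (variance of lineage mean mu),
with fold changes of each across pCO2 environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def compute_response(mu_treatment: float, mu_alone: float) -> float:
    """Ratio of treatment growth to monoculture growth (dimensionless)."""
    if mu_alone == 0:
        raise ValueError("mu_alone must be non-zero")
    return mu_treatment / mu_alone


def _tech_averaged(growth: pd.DataFrame) -> pd.DataFrame:
    """Mean mu over technical replicates, focal populations only."""
    g = growth
    if "population" in g.columns:
        g = g[g["population"] == "focal"]
    keys = ["focal", "partner", "scenario", "env", "bio_rep"]
    g = g.copy()
    g["partner"] = g["partner"].fillna("")
    return g.groupby(keys, as_index=False, dropna=False)["mu"].mean()


def pair_treatment_with_monoculture(growth: pd.DataFrame) -> pd.DataFrame:
    """Build the tidy response table from a tidy growth table.

    One record per focal x non-self partner x scenario x env x
    biological replicate. The control mu is the same-replicate self-pair
    of the scenario when present, otherwise the monoculture scenario;
    records without any control are skipped with a logged identifier.
    Non-positive growth rates are flagged, not dropped.
    """
    avg = _tech_averaged(growth)

    controls: dict[tuple, float] = {}
    mono = avg[avg["scenario"] == "monoculture"]
    for _, r in mono.iterrows():
        controls[("monoculture", r["focal"], r["env"], r["bio_rep"])] = r["mu"]
    selfpairs = avg[(avg["scenario"] != "monoculture") & (avg["partner"] == avg["focal"])]
    for _, r in selfpairs.iterrows():
        controls[(r["scenario"], r["focal"], r["env"], r["bio_rep"])] = r["mu"]

    records = []
    treatments = avg[
        (avg["scenario"] != "monoculture") & (avg["partner"] != avg["focal"])
    ]
    for _, r in treatments.iterrows():
        key = (r["scenario"], r["focal"], r["env"], r["bio_rep"])
        mu_alone = controls.get(key, controls.get(("monoculture",) + key[1:]))
        if mu_alone is None:
            logger.warning(
                "no monoculture/self-pair control for focal=%s env=%s "
                "bio_rep=%s scenario=%s: record skipped",
                r["focal"], r["env"], r["bio_rep"], r["scenario"],
            )
            continue
        records.append(
            {
                "focal": r["focal"],
                "partner": r["partner"],
                "scenario": r["scenario"],
                "env": r["env"],
                "bio_rep": r["bio_rep"],
                "mu_treatment": r["mu"],
                "mu_alone": mu_alone,
                "response": compute_response(r["mu"], mu_alone),
                "flag": "negative_growth"
                if (r["mu"] <= 0 or mu_alone <= 0)
                else "",
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "focal", "partner", "scenario", "env", "bio_rep",
            "mu_treatment", "mu_alone", "response", "flag",
        ],
    )


@dataclass
class VarianceSummary:
    """Within- and between-lineage growth variance for one environment."""

    env: str
    within_lineage_var: float
    between_lineage_var: float
    n_lineages: int

    def __post_init__(self) -> None:
        if self.within_lineage_var < 0 or self.between_lineage_var < 0:
            raise ValueError("variances must be >= 0")


def variance_components(growth: pd.DataFrame, env: str | None = None) -> VarianceSummary:
    """Within- and between-lineage variance of growth rates.

    Technical replicates are averaged first; the replicate variance is
    then taken over biological replicates per lineage (lineages with a
    single replicate contribute nothing to the within component, logged)
    and the between component is the sample variance of lineage means.
    """
    g = growth
    if env is not None:
        g = g[g["env"] == env]
    else:
        envs = g["env"].unique()
        if len(envs) != 1:
            raise ValueError("growth table spans several envs; pass env=")
        env = envs[0]
    avg = _tech_averaged(g)
    per_lineage = avg.groupby("focal")["mu"]
    if per_lineage.ngroups < 2:
        raise ValueError("need >= 2 lineages for variance components")
    within_vars = []
    for lineage, mus in per_lineage:
        if len(mus) < 2:
            logger.info(
                "lineage %s has a single replicate: excluded from "
                "within-lineage variance", lineage,
            )
            continue
        within_vars.append(mus.var(ddof=1))
    lineage_means = per_lineage.mean()
    return VarianceSummary(
        env=env,
        within_lineage_var=float(np.mean(within_vars)) if within_vars else 0.0,
        between_lineage_var=float(lineage_means.var(ddof=1)),
        n_lineages=per_lineage.ngroups,
    )


def variance_contrast(growth: pd.DataFrame) -> pd.DataFrame:
    """Elevated-vs-ambient fold changes of the two variance components.

    Returns a tidy one-row-per-env table plus ``fold_within`` and
    ``fold_between`` (elevated / ambient) attached to the elevated row.
    """
    summaries = {
        env: variance_components(growth, env=env)
        for env in sorted(growth["env"].unique())
    }
    rows = []
    for env, s in summaries.items():
        rows.append(
            {
                "env": env,
                "within_lineage_var": s.within_lineage_var,
                "between_lineage_var": s.between_lineage_var,
                "n_lineages": s.n_lineages,
                "fold_within": np.nan,
                "fold_between": np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if {"ambient", "elevated"} <= set(summaries):
        amb, ele = summaries["ambient"], summaries["elevated"]
        mask = df["env"] == "elevated"
        if amb.within_lineage_var > 0:
            df.loc[mask, "fold_within"] = (
                ele.within_lineage_var / amb.within_lineage_var
            )
        if amb.between_lineage_var > 0:
            df.loc[mask, "fold_between"] = (
                ele.between_lineage_var / amb.between_lineage_var
            )
    return df
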