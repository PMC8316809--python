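"""Monte-Carlo operating characteristics of the inference layer.

Repeated-simulation studies that characterise the statistical procedures
rather than any one dataset: type-I error and power of the lineage LRT,
confidence-interval coverage of the reactiveness slope, AICc preference
under a true null association, and recovery of a planted between-lineage
variance fold change through the full generator -> growth-estimation ->
variance-partitioning pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import ModelSpec, fit_growth_model, lineage_effect_test
from .profiles import LineageProfile
from .response import variance_components
from .simulate import ExperimentDesign, simulate_experiment
from .growth import estimate_growth_table


def simulate_growth_anova(
    rng: np.random.Generator,
    n_lineages: int = 6,
    n_bio: int = 3,
    n_tech: int = 3,
    lineage_sd: float = 0.0,
    bio_sd: float = 0.0,
    resid_sd: float = 0.05,
    mean: float = 0.7,
) -> pd.DataFrame:
    """Tidy growth table with planted lineage / replicate / residual effects."""
    rows = []
    for i in range(n_lineages):
        a = rng.normal(0.0, lineage_sd) if lineage_sd > 0 else 0.0
        for b in range(1, n_bio + 1):
            u = rng.normal(0.0, bio_sd) if bio_sd > 0 else 0.0
            for _ in range(n_tech):
                rows.append(
                    {
                        "focal": f"L{i + 1:02d}",
                        "bio_rep": b,
                        "mu": mean + a + u + rng.normal(0.0, resid_sd),
                    }
                )
    return pd.DataFrame(rows)


def lrt_lineage_pvalues(
    n_reps: int,
    seed: int,
    n_lineages: int = 6,
    n_bio: int = 3,
    n_tech: int = 12,
    lineage_sd: float = 0.0,
    bio_sd: float = 0.0,
    resid_sd: float = 0.05,
) -> np.ndarray:
    """P-values of the lineage LRT over `n_reps` simulated datasets.

    With ``lineage_sd = 0`` this measures type-I error; with a positive
    planted effect it measures power. The default calibration size
    (6 lineages x 36 observations) is large enough for the asymptotic
    chi-square reference to hold.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        df = simulate_growth_anova(
            rng,
            n_lineages=n_lineages,
            n_bio=n_bio,
            n_tech=n_tech,
            lineage_sd=lineage_sd,
            bio_sd=bio_sd,
            resid_sd=resid_sd,
        )
        pvals[r] = lineage_effect_test(df)["p"]
    return pvals


def reactiveness_slope_study(
    n_reps: int,
    seed: int,
    slope: float = 0.005,
    intercept: float = 1.0,
    n_lineages: int = 6,
    n_bio: int = 3,
    n_partners: int = 5,
    surplus_bio_sd: float = 15.0,
    bio_sd: float = 0.03,
    resid_sd: float = 0.05,
) -> pd.DataFrame:
    """Slope recovery and 95% CI coverage for the reactiveness model.

    Each repeat plants ``response = intercept + slope * surplus_pct``
    plus a replicate-level random intercept and residual noise. The
    surplus predictor is measured per biological replicate (a lineage
    mean plus replicate-level spread) and each replicate contributes
    one response row per non-self partner, mirroring the pipeline's
    replicate structure. Records the slope estimate, its Wald CI,
    whether the CI covers the truth, and whether AICc prefers the
    predictor model over intercept-only.
    """
    rng = np.random.default_rng(seed)
    rows = []
    spec = ModelSpec(outcome="response", fixed_terms=("surplus_pct",),
                     group="focal", subgroup="bio_rep")
    null_spec = ModelSpec(outcome="response", group="focal", subgroup="bio_rep")
    for r in range(n_reps):
        recs = []
        for i in range(n_lineages):
            surplus_lineage = rng.uniform(-20.0, 100.0)
            for b in range(1, n_bio + 1):
                surplus = surplus_lineage + rng.normal(0.0, surplus_bio_sd)
                u = rng.normal(0.0, bio_sd)
                for _ in range(n_partners):
                    recs.append(
                        {
                            "focal": f"L{i + 1:02d}",
                            "bio_rep": b,
                            "surplus_pct": surplus,
                            "response": intercept + slope * surplus + u
                            + rng.normal(0.0, resid_sd),
                        }
                    )
        df = pd.DataFrame(recs)
        fit = fit_growth_model(df, spec)
        null = fit_growth_model(df, null_spec)
        lo, hi = fit.conf_int.loc["surplus_pct"]
        rows.append(
            {
                "slope_hat": float(fit.params["surplus_pct"]),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "covered": bool(lo <= slope <= hi),
                "aicc_prefers_predictor": fit.aicc_value < null.aicc_value,
            }
        )
    return pd.DataFrame(rows)


def _variance_profiles(
    rng: np.random.Generator,
    env: str,
    n_lineages: int,
    between_sd: float,
    mean_mu: float,
    cv_bio: float,
) -> list[LineageProfile]:
    mus = rng.normal(mean_mu, between_sd, size=n_lineages)
    mus = np.clip(mus, 0.05, 2.9)
    return [
        LineageProfile(
            lineage_id=f"L{i + 1:03d}",
            env=env,
            mu_mono=float(m),
            cv_bio=cv_bio,
            cv_tech=0.05,
        )
        for i, m in enumerate(mus)
    ]


def variance_fold_study(
    n_reps: int,
    seed: int,
    fold_between: float = 3.9,
    n_lineages: int = 60,
    n_bio: int = 10,
    ambient_between_sd: float = 0.1083,
    mean_mu: float = 0.775,
    cv_bio: float = 0.10,
) -> np.ndarray:
    """Recover a planted between-lineage variance fold via the pipeline.

    Each repeat draws ambient lineage means with the given between-
    lineage s.d. and elevated means with ``sqrt(fold_between)`` times
    that s.d., simulates monoculture batch cultures, estimates growth
    from the counts, and computes the elevated/ambient ratio of the
    between-lineage variance component. Returns the estimated folds.
    """
    rng = np.random.default_rng(seed)
    folds = np.empty(n_reps)
    for r in range(n_reps):
        between = {}
        for env, sd in (
            ("ambient", ambient_between_sd),
            ("elevated", ambient_between_sd * np.sqrt(fold_between)),
        ):
            profiles = _variance_profiles(
                rng, env, n_lineages, sd, mean_mu, cv_bio
            )
            design = ExperimentDesign(
                lineages=tuple(profiles),
                scenarios=("monoculture",),
                n_bio=n_bio,
                n_tech=1,
                seed=int(rng.integers(2**31)),
            )
            sim = simulate_experiment(design)
            growth = estimate_growth_table(sim.counts)
            between[env] = variance_components(growth, env=env).between_lineage_var
        folds[r] = between["elevated"] / between["ambient"]
    return folds
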