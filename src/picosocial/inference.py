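"""Mixed-model inference on growth rates and reactiveness.

Linear mixed-effects models with a random intercept structure over the
replicate hierarchy, likelihood-ratio tests (LRTs) for fixed effects,
and AICc model selection.

Conventions
-----------
* Lineage enters LRTs as a fixed categorical factor, so the test for a
  lineage effect has (levels - 1) degrees of freedom.
* LRTs compare maximum-likelihood fits (never REML) of nested fixed-
  effect structures on the same data; the reference distribution is the
  asymptotic chi-square.
* The random structure is a random intercept per biological-replicate
  population (the lineage x replicate cell). The nesting declaration
  defaults to the conventional reading (replicate within lineage); the
  reverse reading (lineage within replicate) is available via
  ``nesting="lineage_in_replicate"`` and, with a single random level,
  yields an identical fit.
* Singular (zero) random-effect variances are reported on the fit, not
  silently dropped, and the LRT refuses fits flagged as non-converged.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams

logger = logging.getLogger(__name__)

_SINGULAR_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed_terms`` are column names (string columns are treated as
    categorical factors by the formula interface); ``group`` and
    ``subgroup`` define the two-level random-intercept hierarchy, with
    ``nesting`` choosing which factor is outer.
    """

    outcome: str
    fixed_terms: tuple[str, ...] = ()
    group: str = "focal"  # lineage identifier column
    subgroup: str | None = "bio_rep"  # biological replicate column
    nesting: str = "replicate_in_lineage"  # or "lineage_in_replicate"
    reml: bool = False

    def __post_init__(self) -> None:
        if self.nesting not in ("replicate_in_lineage", "lineage_in_replicate"):
            raise ValueError(f"unknown nesting {self.nesting!r}")

    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class FitResult:
    """Converged (or flagged) mixed-model fit."""

    loglik: float
    n_obs: int
    k_params: int
    params: pd.Series
    bse: pd.Series
    converged: bool
    singular: bool
    reml: bool
    spec: ModelSpec
    random_variances: dict[str, float] = field(default_factory=dict)
    conf_int: pd.DataFrame | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def aicc_value(self) -> float:
        return aicc(self.loglik, self.k_params, self.n_obs)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _degenerate_fit(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Closed-form fallback when the outcome has (near-)zero variance.

    All slopes are zero and the Gaussian log-likelihood is evaluated
    with the residual variance floored, keeping it finite.
    """
    y = data[spec.outcome].to_numpy(dtype=float)
    n = len(y)
    resid_var = max(float(np.var(y)), 1e-12)
    loglik = -0.5 * n * (np.log(2 * np.pi * resid_var) + 1.0)
    names = ["Intercept"] + list(spec.fixed_terms)
    params = pd.Series([float(np.mean(y))] + [0.0] * len(spec.fixed_terms), index=names)
    bse = pd.Series([0.0] * len(names), index=names)
    return FitResult(
        loglik=loglik,
        n_obs=n,
        k_params=len(names) + 1,
        params=params,
        bse=bse,
        converged=True,
        singular=True,
        reml=spec.reml,
        spec=spec,
        random_variances={},
    )


def fit_growth_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one linear mixed model described by `spec`.

    The random structure is a random intercept per biological-replicate
    cell (the crossing of ``group`` and ``subgroup``); its variance is
    estimated by profile likelihood, which is exact at the zero-variance
    boundary. A boundary estimate is reported via the ``singular`` flag,
    never silently dropped.
    """
    data = data.reset_index(drop=True).copy()

    def _term_col(term: str) -> str:
        m = re.fullmatch(r"C\((\w+)\)", term)
        return m.group(1) if m else term

    needed = {spec.outcome, spec.group} | {
        _term_col(t)
        for t in spec.fixed_terms
        if re.fullmatch(r"C\(\w+\)|[A-Za-z_]\w*", t)
    }
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise KeyError(f"data lacks required columns: {missing}")
    if float(np.std(data[spec.outcome].to_numpy(dtype=float))) < 1e-12:
        return _degenerate_fit(data, spec)

    if spec.nesting == "replicate_in_lineage":
        cols = [spec.group] + ([spec.subgroup] if spec.subgroup else [])
    else:
        if spec.subgroup is None:
            raise ValueError("lineage_in_replicate nesting needs a subgroup column")
        cols = [spec.subgroup, spec.group]
    if data[spec.group].nunique() < 2:
        raise ValueError(f"need >= 2 groups in {spec.group!r}")
    # random intercept per innermost replicate cell; with a single random
    # level the two nesting directions produce identical fits
    groups = data[cols].astype(str).agg("/".join, axis=1)

    # The random structure is a single random intercept, so the
    # profiled likelihood depends on one scalar: theta, the ratio of the
    # random-intercept variance to the residual variance. For ML the
    # profiled log-likelihood has a closed form (block-diagonal marginal
    # covariance), which is maximized by a bounded scalar search — exact
    # and stable at the zero-variance boundary, where generic gradient
    # optimizers routinely fail on a singular Hessian. Fixed effects and
    # their covariance follow by GLS at the optimum. The same profile
    # evaluated through the fitted model object is used for REML.
    formula = spec.formula()
    model = smf.mixedlm(formula, data, groups=groups, re_formula="1")

    X = np.asarray(model.exog, dtype=float)
    y = np.asarray(model.endog, dtype=float)
    n, p = X.shape
    codes, _ = pd.factorize(groups)
    order = np.argsort(codes, kind="stable")
    Xs, ys = X[order], y[order]
    cs = codes[order]
    starts = np.r_[0, 1 + np.flatnonzero(np.diff(cs))]
    ng = np.diff(np.r_[starts, len(cs)])
    sum_x = np.add.reduceat(Xs, starts, axis=0)
    sum_y = np.add.reduceat(ys, starts)
    xtx = Xs.T @ Xs
    xty = Xs.T @ ys

    def gls(theta: float):
        """GLS solution and profiled quantities at variance ratio theta."""
        w = theta / (1.0 + ng * theta)
        xtvix = xtx - sum_x.T @ (w[:, None] * sum_x)
        xtviy = xty - sum_x.T @ (w * sum_y)
        beta = np.linalg.solve(xtvix, xtviy)
        resid = ys - Xs @ beta
        sum_r = np.add.reduceat(resid, starts)
        quad = resid @ resid - float(w @ (sum_r**2))
        return beta, quad, xtvix

    def ml_llf(theta: float) -> float:
        _, quad, _ = gls(theta)
        logdet_v = float(np.log1p(ng * theta).sum())
        # a perfect fit (quad -> 0) has unbounded likelihood; floor it
        quad = max(quad, 1e-300)
        return -0.5 * (n * np.log(2 * np.pi * quad / n) + n + logdet_v)

    if spec.reml:
        # REML llf through statsmodels' own evaluation, so reported
        # values follow its convention; attributes below are normally
        # initialized inside MixedLM.fit()
        model.reml = True
        model._cov_sing = 0
        model.cov_pen = None
        model.fe_pen = None

        def llf_fn(theta: float) -> float:
            par = MixedLMParams.from_components(cov_re=np.array([[max(theta, 1e-8)]]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll = model.loglike(par, profile_fe=True)
            return float(ll) if np.isfinite(ll) else -np.inf
    else:
        llf_fn = ml_llf

    opt = optimize.minimize_scalar(
        lambda lt: -llf_fn(np.exp(lt)),
        bounds=(np.log(1e-10), 10.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    llf, theta = -float(opt.fun), float(np.exp(opt.x))
    llf_boundary = llf_fn(0.0 if not spec.reml else 1e-10)
    if llf_boundary >= llf - 1e-10:
        llf, theta = float(llf_boundary), 0.0

    beta, quad, xtvix = gls(theta)
    sigma2 = quad / (n - p) if spec.reml else quad / n
    cov_beta = sigma2 * np.linalg.inv(xtvix)

    names = list(model.exog_names)
    fe = pd.Series(beta, index=names)
    bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
    z = stats.norm.ppf(0.975)
    ci = pd.DataFrame({0: fe - z * bse, 1: fe + z * bse}, index=names)
    re_var = theta * sigma2
    return FitResult(
        loglik=llf,
        n_obs=n,
        k_params=p + 2,  # fixed effects + random-intercept var + residual var
        params=fe,
        bse=bse,
        converged=True,
        singular=re_var <= _SINGULAR_TOL,
        reml=spec.reml,
        spec=spec,
        random_variances={"/".join(cols): re_var},
        conf_int=ci,
    )


def lrt_fixed_effect(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed-effect structures.

    Returns (chi2, delta_df, p). Both fits must be maximum-likelihood
    and converged; a log-likelihood decrease beyond tolerance signals a
    failed fit and raises.
    """
    if full.reml or reduced.reml:
        raise ValueError("LRT requires maximum-likelihood (reml=False) fits")
    if not (full.converged and reduced.converged):
        raise ValueError("LRT refuses non-converged fits")
    if full.n_obs != reduced.n_obs:
        raise ValueError("LRT requires fits on the same data")
    delta_df = full.k_params - reduced.k_params
    if delta_df < 0:
        raise ValueError("models are not nested (full must have more parameters)")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -1e-8:
        raise ValueError(
            f"log-likelihood decreased under the full model (chi2={chi2:.3g}): refit"
        )
    chi2 = max(chi2, 0.0)
    # identical models: zero statistic on zero degrees of freedom
    p = 1.0 if delta_df == 0 else float(stats.chi2.sf(chi2, delta_df))
    return chi2, delta_df, p


def lineage_effect_test(
    growth: pd.DataFrame,
    outcome: str = "mu",
    lineage_col: str = "focal",
    subgroup: str | None = "bio_rep",
    nesting: str = "replicate_in_lineage",
) -> dict:
    """LRT for a lineage effect on absolute growth rates.

    Fits the model with and without lineage as a fixed categorical
    factor (both by ML, same random structure) and returns the test
    along with both fits.
    """
    full_spec = ModelSpec(
        outcome=outcome,
        fixed_terms=(f"C({lineage_col})",),
        group=lineage_col,
        subgroup=subgroup,
        nesting=nesting,
    )
    reduced_spec = replace(full_spec, fixed_terms=())
    full = fit_growth_model(growth, full_spec)
    reduced = fit_growth_model(growth, reduced_spec)
    chi2, ddf, p = lrt_fixed_effect(full, reduced)
    return {
        "chi2": chi2,
        "delta_df": ddf,
        "p": p,
        "full": full,
        "reduced": reduced,
    }


def fit_reactiveness_model(
    data: pd.DataFrame,
    predictor: str = "surplus_pct",
    outcome: str = "response",
    lineage_col: str = "focal",
    subgroup: str | None = "bio_rep",
) -> pd.DataFrame:
    """Per-scenario reactiveness models selected by AICc.

    For every scenario in `data`, fits the outcome against the carbon-
    allocation predictor and against an intercept-only alternative
    (same random structure, ML), and keeps the model with the smallest
    AICc. Scenarios with fewer than three lineages are skipped with a
    log entry. Returns a tidy table with one row per scenario.
    """
    rows = []
    for scenario, sub in data.groupby("scenario", sort=True):
        if sub[lineage_col].nunique() < 3:
            logger.warning(
                "scenario %s has < 3 lineages: reactiveness model skipped",
                scenario,
            )
            continue
        spec_full = ModelSpec(
            outcome=outcome,
            fixed_terms=(predictor,),
            group=lineage_col,
            subgroup=subgroup,
        )
        spec_null = replace(spec_full, fixed_terms=())
        full = fit_growth_model(sub, spec_full)
        null = fit_growth_model(sub, spec_null)
        best_label, best = min(
            [("with_predictor", full), ("intercept_only", null)],
            key=lambda kv: kv[1].aicc_value,
        )
        slope = full.params.get(predictor, np.nan)
        slope_se = full.bse.get(predictor, np.nan)
        ci = (
            full.conf_int.loc[predictor]
            if full.conf_int is not None and predictor in full.conf_int.index
            else (np.nan, np.nan)
        )
        rows.append(
            {
                "scenario": scenario,
                "n_obs": full.n_obs,
                "slope": float(slope),
                "slope_se": float(slope_se),
                "slope_ci_low": float(ci[0]),
                "slope_ci_high": float(ci[1]),
                "aicc_with_predictor": full.aicc_value,
                "aicc_intercept_only": null.aicc_value,
                "best_model": best_label,
                "best_aicc": best.aicc_value,
                "singular": full.singular,
            }
        )
    return pd.DataFrame(rows)
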