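"""Regression-to-the-mean null model for mono- vs mixed-culture growth.

If monoculture and mixed-culture growth rates are drawn independently
from the *same* distribution — i.e. with no interaction whatsoever —
the ratio mu_mixed/mu_mono plotted against mu_mono is L-shaped: the
numerator is independent of the denominator, so slow monoculture growers
show large apparent "responses" and fast growers small ones. The module
quantifies that shape (Spearman rank correlation, quantile-binned mean
responses, and a c/mu curve fit) so it can be compared with observed
response patterns.

Defaults draw from a normal distribution truncated to the plausible
growth range 0.45-1.1 day^-1, with mean at the midpoint (0.775) and
s.d. = range/6 (~0.1083), so essentially all probability mass of the
untruncated normal already lies inside the range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .profiles import MU_RANGE
from .response import compute_response


@dataclass(frozen=True)
class NullModelConfig:
    mu_min: float = MU_RANGE[0]
    mu_max: float = MU_RANGE[1]
    n_draws: int = 1000
    seed: int = 0
    dist_mean: float | None = None  # default: midpoint of [mu_min, mu_max]
    dist_sd: float | None = None  # default: (mu_max - mu_min) / 6

    def __post_init__(self) -> None:
        if not self.mu_min < self.mu_max:
            raise ValueError("mu_min must be < mu_max")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.dist_mean is None:
            object.__setattr__(
                self, "dist_mean", 0.5 * (self.mu_min + self.mu_max)
            )
        if self.dist_sd is None:
            object.__setattr__(self, "dist_sd", (self.mu_max - self.mu_min) / 6.0)
        if self.dist_sd < 0:
            raise ValueError("dist_sd must be >= 0")

    def distribution(self) -> stats.rv_continuous:
        """The truncated normal both growth rates are drawn from."""
        if self.dist_sd == 0:
            raise ValueError("point-mass config has no continuous distribution")
        a = (self.mu_min - self.dist_mean) / self.dist_sd
        b = (self.mu_max - self.dist_mean) / self.dist_sd
        return stats.truncnorm(a, b, loc=self.dist_mean, scale=self.dist_sd)


@dataclass
class NullModelResult:
    """Paired draws and summary statistics of the no-interaction null."""

    draws: pd.DataFrame  # mu_mono, mu_mixed, response
    spearman_rho: float
    mean_response: float
    degenerate: bool = False  # point-mass config: rho undefined, reported 0
    config: NullModelConfig = field(default_factory=NullModelConfig)


def simulate_null(config: NullModelConfig) -> NullModelResult:
    """Draw independent (mu_mono, mu_mixed) pairs and their responses."""
    rng = np.random.default_rng(config.seed)
    if config.dist_sd == 0:
        mono = np.full(config.n_draws, config.dist_mean)
        mixed = mono.copy()
    else:
        dist = config.distribution()
        mono = dist.rvs(size=config.n_draws, random_state=rng)
        mixed = dist.rvs(size=config.n_draws, random_state=rng)
    response = mixed / mono
    draws = pd.DataFrame(
        {"mu_mono": mono, "mu_mixed": mixed, "response": response}
    )
    if config.dist_sd == 0 or config.n_draws < 2:
        rho, degenerate = 0.0, True
    else:
        rho = float(stats.spearmanr(mono, response).statistic)
        degenerate = False
    return NullModelResult(
        draws=draws,
        spearman_rho=rho,
        mean_response=float(response.mean()),
        degenerate=degenerate,
        config=config,
    )


def binned_null_expectation(
    result: NullModelResult, n_bins: int = 10
) -> pd.DataFrame:
    """Mean response per quantile bin of mu_mono.

    Each bin's mean response approximates E[mu_mixed]/midpoint(bin); the
    deviation from that prediction is reported per bin. Empty bins give
    null rows. ``n_bins = 1`` reduces to the overall mean response.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    draws = result.draws
    if n_bins == 1:
        return pd.DataFrame(
            {
                "bin": [0],
                "mu_mono_mid": [draws["mu_mono"].mean()],
                "mean_response": [draws["response"].mean()],
                "n": [len(draws)],
                "expected_response": [np.nan],
                "deviation": [np.nan],
            }
        )
    cats, edges = pd.qcut(
        draws["mu_mono"], q=n_bins, retbins=True, labels=False, duplicates="drop"
    )
    e_mixed = float(draws["mu_mixed"].mean())
    rows = []
    for i in range(len(edges) - 1):
        sel = draws.loc[cats == i]
        mid = 0.5 * (edges[i] + edges[i + 1])
        if len(sel) == 0:
            rows.append(
                dict(bin=i, mu_mono_mid=mid, mean_response=np.nan, n=0,
                     expected_response=np.nan, deviation=np.nan)
            )
            continue
        mean_resp = float(sel["response"].mean())
        expected = e_mixed / mid
        rows.append(
            dict(
                bin=i,
                mu_mono_mid=mid,
                mean_response=mean_resp,
                n=len(sel),
                expected_response=expected,
                deviation=mean_resp - expected,
            )
        )
    return pd.DataFrame(rows)


def fit_inverse_curve(binned: pd.DataFrame) -> float:
    """Least-squares fit of c/mu to the binned mean responses.

    Under the no-interaction null the fitted c estimates E[mu_mixed].
    """
    ok = binned.dropna(subset=["mean_response"])
    x = ok["mu_mono_mid"].to_numpy()
    y = ok["mean_response"].to_numpy()
    if len(x) < 1:
        raise ValueError("no populated bins to fit")

    def model(mu, c):
        return c / mu

    popt, _ = optimize.curve_fit(model, x, y, p0=[float(np.mean(x * y))])
    return float(popt[0])
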