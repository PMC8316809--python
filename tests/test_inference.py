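"""Mixed-model fits, likelihood-ratio tests and AICc selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picosocial import (
    ModelSpec,
    aicc,
    fit_growth_model,
    fit_reactiveness_model,
    lineage_effect_test,
    lrt_fixed_effect,
)


def _anova_frame(seed=77, n_lineages=4, n_bio=3, n_tech=3,
                 effect=0.05, bio_sd=0.04, resid_sd=0.03, mean=0.6):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lineages):
        for b in range(n_bio):
            u = rng.normal(0, bio_sd)
            for _ in range(n_tech):
                rows.append(
                    {"focal": f"L{i + 1}", "bio_rep": b + 1,
                     "mu": mean + effect * i + u + rng.normal(0, resid_sd)}
                )
    return pd.DataFrame(rows)


FULL_SPEC = ModelSpec(outcome="mu", fixed_terms=("C(focal)",),
                      group="focal", subgroup="bio_rep")
NULL_SPEC = ModelSpec(outcome="mu", group="focal", subgroup="bio_rep")


class TestAicc:
    def test_hand_arithmetic(self):
        # aic = 26; correction 2*3*4/16 = 1.5
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_zero_parameters_reduce_to_aic(self):
        assert aicc(-10.0, 0, 20) == pytest.approx(20.0)

    def test_large_n_limit_approaches_aic(self):
        assert aicc(-10.0, 3, 10**7) == pytest.approx(26.0, abs=1e-5)

    def test_undefined_for_small_samples(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        loglik=st.floats(-1e4, 1e4),
        k=st.integers(0, 20),
        n=st.integers(25, 10_000),
    )
    def test_algebraic_definition(self, loglik, k, n):
        aic = -2 * loglik + 2 * k
        assert aicc(loglik, k, n) == pytest.approx(
            aic + 2 * k * (k + 1) / (n - k - 1)
        )
        assert aicc(loglik, k, n) >= aic


class TestMixedModelFit:
    def test_matches_lme4_reference_fit(self):
        """ML log-likelihoods and fixed effects frozen from an lme4 fit
        (lmer, mu ~ focal + (1 | lineage:replicate), REML = FALSE) on the
        identically seeded dataset."""
        df = _anova_frame(seed=77)
        full = fit_growth_model(df, FULL_SPEC)
        null = fit_growth_model(df, NULL_SPEC)
        assert full.loglik == pytest.approx(61.5103166087, abs=1e-6)
        assert null.loglik == pytest.approx(55.7131751052, abs=1e-6)
        np.testing.assert_allclose(
            full.params.to_numpy(),
            [0.59590732, 0.02211248, 0.09475204, 0.13665389],
            atol=1e-6,
        )
        assert list(full.random_variances.values())[0] == pytest.approx(
            0.001477917, abs=1e-7
        )

    def test_slope_recovery_with_zero_random_variance(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.uniform(0, 10, n)
        df = pd.DataFrame(
            {
                "focal": np.repeat([f"L{i}" for i in range(10)], n // 10),
                "bio_rep": np.tile([1, 2, 3, 4, 5], n // 5),
                "x": x,
                "y": 1.0 + 0.5 * x + rng.normal(0, 0.3, n),
            }
        )
        fit = fit_growth_model(
            df, ModelSpec(outcome="y", fixed_terms=("x",),
                          group="focal", subgroup="bio_rep")
        )
        slope, se = fit.params["x"], fit.bse["x"]
        assert abs(slope - 0.5) < 2 * se

    def test_constant_outcome_gives_finite_loglik_and_zero_slope(self):
        df = _anova_frame()
        df["mu"] = 0.7
        fit = fit_growth_model(df, FULL_SPEC)
        assert np.isfinite(fit.loglik)
        assert np.allclose(fit.params.to_numpy()[1:], 0.0)

    def test_balanced_two_group_difference_recovered(self):
        rng = np.random.default_rng(5)
        d = 0.3
        df = pd.DataFrame(
            {
                "focal": np.repeat(["A", "B"], 60),
                "bio_rep": np.tile([1, 2, 3], 40),
                "mu": np.concatenate(
                    [rng.normal(0.5, 0.02, 60), rng.normal(0.5 + d, 0.02, 60)]
                ),
            }
        )
        fit = fit_growth_model(df, FULL_SPEC)
        # closed-form OLS limit: coefficient equals the group-mean gap
        assert fit.params.iloc[1] == pytest.approx(d, abs=0.02)

    def test_singular_random_variance_is_flagged(self):
        rng = np.random.default_rng(2)
        df = _anova_frame(bio_sd=0.0, seed=2)
        df["mu"] = 0.7 + 0.05 * rng.standard_normal(len(df))
        fit = fit_growth_model(df, NULL_SPEC)
        assert fit.converged
        assert isinstance(fit.singular, (bool, np.bool_))

    def test_nesting_directions_give_identical_loglik(self):
        df = _anova_frame(seed=13)
        a = fit_growth_model(df, FULL_SPEC)
        b = fit_growth_model(
            df,
            ModelSpec(outcome="mu", fixed_terms=("C(focal)",), group="focal",
                      subgroup="bio_rep", nesting="lineage_in_replicate"),
        )
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_missing_column_raises(self):
        df = _anova_frame()
        with pytest.raises(KeyError):
            fit_growth_model(df, ModelSpec(outcome="nope", group="focal"))


class TestLrt:
    def test_identical_models_give_zero_statistic(self):
        df = _anova_frame()
        full = fit_growth_model(df, FULL_SPEC)
        pseudo = fit_growth_model(
            df, ModelSpec(outcome="mu", fixed_terms=("C(focal)", "1"),
                          group="focal", subgroup="bio_rep")
        )
        chi2, ddf, p = lrt_fixed_effect(pseudo, full)
        assert chi2 == pytest.approx(0.0, abs=1e-6)

    def test_lineage_effect_detected(self):
        out = lineage_effect_test(_anova_frame(effect=0.08))
        assert out["delta_df"] == 3  # four lineages -> three contrasts
        assert out["p"] < 0.01

    def test_refuses_reml_fits(self):
        df = _anova_frame()
        full = fit_growth_model(
            df, ModelSpec(outcome="mu", fixed_terms=("C(focal)",),
                          group="focal", subgroup="bio_rep", reml=True)
        )
        null = fit_growth_model(df, NULL_SPEC)
        with pytest.raises(ValueError, match="maximum-likelihood"):
            lrt_fixed_effect(full, null)

    def test_rejects_non_nested_order(self):
        df = _anova_frame()
        full = fit_growth_model(df, FULL_SPEC)
        null = fit_growth_model(df, NULL_SPEC)
        with pytest.raises(ValueError, match="nested"):
            lrt_fixed_effect(null, full)

    def test_chi2_invariant_to_affine_outcome_rescaling(self):
        df = _anova_frame(seed=21)
        chi2_a = lineage_effect_test(df)["chi2"]
        df2 = df.assign(mu=3.0 * df["mu"] + 10.0)
        chi2_b = lineage_effect_test(df2)["chi2"]
        assert chi2_a == pytest.approx(chi2_b, rel=1e-6)


class TestReactivenessModel:
    def _joined(self, slope, noise, seed=0, n_lineages=6):
        rng = np.random.default_rng(seed)
        rows = []
        for scen in ("thincert", "spike"):
            for i in range(n_lineages):
                s = rng.uniform(-20, 100)
                for b in (1, 2, 3):
                    sb = s + rng.normal(0, 10)
                    for _ in range(3):
                        rows.append(
                            {"scenario": scen, "focal": f"L{i + 1}",
                             "bio_rep": b, "surplus_pct": sb,
                             "response": 1.0 + slope * sb
                             + (rng.normal(0, noise) if noise else 0.0)}
                        )
        return pd.DataFrame(rows)

    def test_exact_linear_relation_recovered_without_noise(self):
        fits = fit_reactiveness_model(self._joined(slope=0.004, noise=0.0))
        assert np.allclose(fits["slope"], 0.004, rtol=1e-6)
        assert (fits["best_model"] == "with_predictor").all()

    def test_small_scenarios_skipped(self, caplog):
        df = self._joined(slope=0.004, noise=0.01, n_lineages=2)
        fits = fit_reactiveness_model(df)
        assert fits.empty

    def test_noise_only_prefers_intercept_model_often(self):
        prefer = []
        for seed in range(20):
            fits = fit_reactiveness_model(
                self._joined(slope=0.0, noise=0.05, seed=seed)
            )
            prefer.extend((fits["best_model"] == "intercept_only").tolist())
        assert np.mean(prefer) > 0.5
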