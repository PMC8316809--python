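"""Generator behaviour: growth curves, layout combinatorics, noise, events."""

import itertools

import numpy as np
import pandas as pd
import pytest

from picosocial import (
    CountSeries,
    ExperimentDesign,
    LineageProfile,
    counts_to_series,
    estimate_growth_table,
    calibrated_profiles,
    simulate_events,
    simulate_experiment,
)
from picosocial.io import FLOAT_FORMAT
from picosocial.profiles import MU_RANGE, regression_to_range_multiplier


def _mono_design(profile, **kwargs):
    defaults = dict(
        lineages=(profile,), scenarios=("monoculture",), n_bio=1, n_tech=1, seed=0
    )
    defaults.update(kwargs)
    return ExperimentDesign(**defaults)


class TestGrowthCurves:
    def test_closed_form_exponential_reaches_expected_density(
        self, single_lineage_profile
    ):
        """mu = ln(1000)/7 from 100 cells/ml reaches 1e5 cells/ml at day 7."""
        sim = simulate_experiment(
            _mono_design(single_lineage_profile, duration_days=7)
        )
        final = sim.counts.loc[sim.counts["day"] == 7, "density"].iloc[0]
        # oracle: direct evaluation of N * exp(mu * t)
        expected = 100.0 * np.exp(single_lineage_profile.mu_mono * 7)
        assert final == pytest.approx(expected, rel=1e-12)
        assert final == pytest.approx(1e5, rel=1e-12)

    def test_inoculum_is_exact_without_noise(self, noise_free_sim):
        day0 = noise_free_sim.counts.query("day == 0")
        assert (day0["density"] == 100.0).all()

    def test_unit_reactiveness_reproduces_monoculture_series(self):
        profiles = tuple(
            calibrated_profiles("ambient", cv_bio=0.0, cv_tech=0.0,
                                gamma={"thincert": 0.0, "spike": 0.0})
        )
        design = ExperimentDesign(
            lineages=profiles, scenarios=("monoculture", "thincert", "spike"),
            n_bio=1, n_tech=1, seed=5,
        )
        counts = simulate_experiment(design).counts
        mono = counts.query("scenario == 'monoculture'")
        for scen in ("thincert", "spike"):
            treat = counts.query("scenario == @scen")
            for focal, grp in treat.groupby("focal"):
                ref = mono.query("focal == @focal").sort_values("day")
                for _, well in grp.groupby("well_id"):
                    np.testing.assert_allclose(
                        well.sort_values("day")["density"].to_numpy(),
                        ref["density"].to_numpy(),
                    )

    def test_multi_transfer_series_reset_to_inoculum(self, noise_free_sim):
        direct = noise_free_sim.counts.query(
            "scenario == 'direct' and population == 'focal'"
        )
        one_well = direct[direct["well_id"] == direct["well_id"].iloc[0]]
        second = one_well.query("transfer == 2").sort_values("day")
        assert second["day"].iloc[0] == 7
        assert second["density"].iloc[0] == pytest.approx(100.0)


class TestLayout:
    def test_full_factorial_well_counts(self):
        """Oracle: explicit enumeration of the ordered-pair layout."""
        profiles = tuple(calibrated_profiles("ambient"))
        design = ExperimentDesign(
            lineages=profiles, n_bio=3, n_tech=3,
            scenario_durations={"direct": 14}, seed=0,
        )
        counts = simulate_experiment(design).counts
        wells = counts.groupby("scenario")["well_id"].nunique()

        ids = [p.lineage_id for p in profiles]
        paired = list(itertools.product(ids, ids))  # ordered, incl. self
        assert wells["thincert"] == len(paired) * 9
        assert wells["spike"] == len(paired) * 9
        assert wells["monoculture"] == len(ids) * 9
        # direct co-culture always pairs with the designated GFP lineage
        assert wells["direct"] == len(ids) * 9
        direct = counts.query("scenario == 'direct'")
        assert set(direct["partner"]) == {"GFP-Oth95"}
        assert set(direct["population"]) == {"focal", "gfp"}

    def test_self_pairs_present_as_controls(self, noise_free_sim):
        thincert = noise_free_sim.counts.query("scenario == 'thincert'")
        self_pairs = thincert[thincert["focal"] == thincert["partner"]]
        assert self_pairs["focal"].nunique() == 6

    def test_mu_ceiling_rejects_implausible_designs(self):
        fast = LineageProfile(
            lineage_id="HOT", env="ambient", mu_mono=2.0,
            reactiveness={"spike": 2.0},
        )
        slow = LineageProfile(lineage_id="SLO", env="ambient", mu_mono=0.5)
        with pytest.raises(ValueError, match="ceiling"):
            ExperimentDesign(
                lineages=(fast, slow), scenarios=("monoculture", "spike"),
                seed=0,
            )

    def test_unknown_scenario_rejected(self, single_lineage_profile):
        with pytest.raises(ValueError, match="scenario"):
            ExperimentDesign(
                lineages=(single_lineage_profile,),
                scenarios=("chemostat",),
                seed=0,
            )

    def test_non_positive_duration_rejected(self, single_lineage_profile):
        with pytest.raises(ValueError, match="duration"):
            _mono_design(single_lineage_profile, duration_days=0)


class TestNoiseModel:
    def test_round_trip_growth_equals_mu_eff_without_noise(
        self, noise_free_sim, noise_free_growth
    ):
        design = noise_free_sim.design
        profiles = {p.lineage_id: p for p in design.lineages}
        focal = noise_free_growth.query("population == 'focal'")
        for _, row in focal.iterrows():
            prof = profiles[row["focal"]]
            mu_eff = prof.mu_mono * prof.reactiveness_for(
                row["scenario"], row["partner"]
            )
            assert row["mu"] == pytest.approx(mu_eff, rel=1e-12)

    def test_log_density_residuals_unbiased(self):
        profile = LineageProfile(
            lineage_id="L1", env="ambient", mu_mono=0.8,
            cv_bio=0.0, cv_tech=0.2,
        )
        design = _mono_design(profile, n_bio=1, n_tech=400, seed=11)
        counts = simulate_experiment(design).counts
        resid = np.log(counts["density"]) - (
            np.log(design.inoculum) + profile.mu_mono * counts["day"]
        )
        # median-unbiased multiplicative noise: mean log-residual -> 0
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(len(resid))

    def test_bio_deviate_shared_within_replicate(self):
        profile = LineageProfile(
            lineage_id="L1", env="ambient", mu_mono=0.8,
            cv_bio=0.3, cv_tech=0.0,
        )
        design = ExperimentDesign(
            lineages=(profile,), scenarios=("monoculture",),
            n_bio=2, n_tech=3, seed=7,
        )
        g = estimate_growth_table(simulate_experiment(design).counts)
        per_bio = g.groupby("bio_rep")["mu"].agg(["std", "mean"])
        assert (per_bio["std"] < 1e-12).all()  # tech reps identical
        assert per_bio["mean"].std() > 0  # bio reps differ

    def test_reproducible_csv_bytes(self, tmp_path, single_lineage_profile):
        design = _mono_design(single_lineage_profile, n_tech=3, seed=99)
        out = []
        for name in ("a.csv", "b.csv"):
            counts = simulate_experiment(design).counts
            path = tmp_path / name
            counts.to_csv(path, index=False, float_format=FLOAT_FORMAT)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_calibrated_preset_growth_range(self):
        mus = [p.mu_mono for p in calibrated_profiles("ambient")]
        assert min(mus) >= MU_RANGE[0] - 1e-12
        assert max(mus) <= MU_RANGE[1] + 1e-12

    def test_regression_to_range_direction(self):
        lo = regression_to_range_multiplier(0.45, 0.5)
        hi = regression_to_range_multiplier(1.1, 0.5)
        assert lo > 1 > hi  # slow growers speed up, fast growers slow down
        assert regression_to_range_multiplier(0.775, 0.5) == pytest.approx(1.0)


class TestEvents:
    @pytest.fixture()
    def series(self):
        return CountSeries(
            well_id="W1", focal="L1", partner=None, scenario="monoculture",
            env="ambient", bio_rep=1, tech_rep=1,
            times=np.array([0.0, 7.0]), densities=np.array([100.0, 1e5]),
        )

    def test_zero_debris_gives_only_cells(self, series):
        ev = simulate_events(series, debris_fraction=0.0, gfp_fraction=0.1,
                             rng=1)
        assert set(ev["event_class"]) <= {"cell", "gfp_cell"}

    def test_debris_count_matches_binomial_draw(self, series):
        ev = simulate_events(series, debris_fraction=0.2, n_events=1000, rng=3)
        n_debris = (ev["event_class"] == "debris").sum()
        # oracle: recount against an identically seeded binomial draw
        expected = np.random.default_rng(3).binomial(1000, 0.2)
        assert len(ev) == 1000
        assert n_debris == expected

    def test_gfp_green_channel_is_bimodal_across_gate(self, series):
        ev = simulate_events(series, debris_fraction=0.0, gfp_fraction=0.5,
                             n_events=4000, rng=5)
        gfp = ev.loc[ev["event_class"] == "gfp_cell", "green"]
        dim = ev.loc[ev["event_class"] == "cell", "green"]
        # the two hidden subpopulations straddle the default green gate
        assert np.quantile(gfp, 0.01) > 100.0 > np.quantile(dim, 0.99)

    def test_expected_count_tracks_density_times_volume(self, series):
        ev = simulate_events(series, debris_fraction=0.0, sample_volume=0.05,
                             rng=8)
        lam = 1e5 * 0.05
        assert abs(len(ev) - lam) < 5 * np.sqrt(lam)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_fractions_rejected(self, series, bad):
        with pytest.raises(ValueError):
            simulate_events(series, debris_fraction=bad)
        with pytest.raises(ValueError):
            simulate_events(series, gfp_fraction=bad)

    def test_counts_to_series_round_trip(self, noise_free_sim):
        series = counts_to_series(noise_free_sim.counts)
        n_wells = noise_free_sim.counts.groupby(
            ["well_id", "population"]
        ).ngroups
        assert len(series) == n_wells
        s = series[0]
        assert np.all(np.diff(s.times) > 0)
        assert np.all(s.densities > 0)
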