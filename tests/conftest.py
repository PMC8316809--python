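import numpy as np
import pytest

from picosocial import (
    ExperimentDesign,
    LineageProfile,
    estimate_growth_table,
    gfp_partner_profile,
    calibrated_profiles,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def noise_free_profiles():
    """Six calibrated ambient lineages with all noise switched off."""
    return tuple(calibrated_profiles("ambient", cv_bio=0.0, cv_tech=0.0))


@pytest.fixture(scope="session")
def noise_free_sim(noise_free_profiles):
    """Deterministic four-scenario experiment, one replicate each."""
    design = ExperimentDesign(
        lineages=noise_free_profiles,
        n_bio=1,
        n_tech=1,
        gfp_partner=gfp_partner_profile("ambient", cv_bio=0.0, cv_tech=0.0),
        scenario_durations={"direct": 14},
        seed=123,
    )
    return simulate_experiment(design)


@pytest.fixture(scope="session")
def noise_free_growth(noise_free_sim):
    return estimate_growth_table(noise_free_sim.counts)


@pytest.fixture(scope="session")
def calibrated_sim():
    """Noisy ambient experiment at the full replicate structure."""
    design = ExperimentDesign(
        lineages=tuple(calibrated_profiles("ambient")),
        scenario_durations={"direct": 14},
        seed=42,
    )
    return simulate_experiment(design)


@pytest.fixture()
def single_lineage_profile():
    return LineageProfile(
        lineage_id="LX",
        env="ambient",
        mu_mono=float(np.log(1000) / 7),
        cv_bio=0.0,
        cv_tech=0.0,
    )
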