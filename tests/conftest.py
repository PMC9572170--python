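import numpy as np
import pytest

from relapsekit import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort_config():
    return syn.CohortConfig(
        n_controls=2, n_patients=2, days_per_subject=3, prodrome_days=1,
        relapses=[syn.RelapseSpec(0, 2, 1, "moderate", anomaly_magnitude=1.5)],
        seed=4,
    )


@pytest.fixture(scope="session")
def one_day_bundle():
    """One simulated subject-day (artifact-free) shared across tests."""
    cfg = syn.CohortConfig(n_controls=1, n_patients=0, days_per_subject=1,
                           artifact_rates=syn.ArtifactRates(0.0, 0.0, 0.0),
                           seed=7)
    profile = syn.make_profiles(cfg)[0]
    return cfg, profile, syn.simulate_subject_day(profile, cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
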