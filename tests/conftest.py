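import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoloop import preprocess, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One full simulated cohort under the study conditions (seed 0)."""
    return simulate.simulate_cohort(simulate.SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-pair cohort with record emission, for record-level checks."""
    return simulate.simulate_cohort(simulate.SimConfig(seed=11, n_pairs=4))


@pytest.fixture(scope="session")
def small_daily_via_records(small_cohort):
    """Daily summaries recomputed from the emitted tidy records."""
    obs, _ = preprocess.sanitize_rt(small_cohort.observations)
    obs, _ = preprocess.dedupe_bolus_transmissions(obs, transmission_col=None)
    return preprocess.aggregate(
        obs, small_cohort.feed, small_cohort.lw, trial_start=simulate.TRIAL_START
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
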