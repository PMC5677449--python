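import pytest

from spiraltis import SimulationConfig, score_cohort, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A small, fast cohort: short trials, coarse sampling, 5 subjects."""
    return SimulationConfig(
        n_healthy=2,
        n_early=1,
        n_intermediate=1,
        n_advanced=1,
        seed=42,
        trial_duration_s=4.0,
        sample_interval_ms=25.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_scored(tiny_cohort):
    return score_cohort(tiny_cohort)
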