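import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120929)


@pytest.fixture(scope="session")
def small_experiment():
    """A 20 kb three-line experiment with planted mutations and shared
    ancestral differences, deep enough that the focal filters pass."""
    from malines import SimulationConfig, simulate_experiment

    cfg = SimulationConfig(
        seed=3,
        genome_length=20_000,
        true_nuclear_rate=2e-7,
        shared_diff_count=5,
        mean_coverage=(15.0,),
        per_read_error=0.002,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_mask(small_experiment):
    from malines import SelfMapParams, self_map_coverage

    return self_map_coverage(small_experiment.genome, SelfMapParams())
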