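import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from trapme.synthetic import SimulationConfig, simulate_dataset  # noqa: E402


@pytest.fixture(scope="session")
def small_dataset():
    """10 subjects/group, 5 features, one detectable association (F0001 x NO2)."""
    cfg = SimulationConfig(n_per_group=10, n_features=5, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def uni_dataset():
    """Single-feature, single-pollutant dataset with unit exposure/error variance."""
    cfg = SimulationConfig(
        n_per_group=20, n_features=1, pollutants=("NO2",),
        Sigma_Z=np.eye(1), error_cov=1.0,
        beta_expo=np.array([[1.0]]), seed=7,
    )
    return simulate_dataset(cfg)
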