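import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iwsdesign import CostSpec, CovarianceSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_cov() -> CovarianceSpec:
    """Consultation-time example: stress-score variances and rho = 0.3."""
    return CovarianceSpec(variances=(100.0, 125.0, 150.0), correlations=(0.3, 0.3, 0.3))


@pytest.fixture(scope="session")
def example_costs() -> CostSpec:
    """Consultation-time example costs: overhead 500, budget 100,000."""
    return CostSpec(overhead=500.0, per_condition=(0.0, 423.6, 635.4), budget=100_000.0)


@pytest.fixture(scope="session")
def example_D(example_cov) -> np.ndarray:
    return example_cov.matrix()


@pytest.fixture(scope="session")
def benchmark_cov() -> CovarianceSpec:
    """Equal-variance benchmark covariance with rho = 0.5."""
    return CovarianceSpec(variances=(1.0, 1.0, 1.0), correlations=(0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def benchmark_costs() -> CostSpec:
    return CostSpec(overhead=100.0, per_condition=(10.0, 20.0, 20.0), budget=50_000.0)
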