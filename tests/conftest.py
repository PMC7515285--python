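import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synfac import InputStats, SynapseParams

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def fig2_params() -> SynapseParams:
    """The canonical reliable-synapse parameter point (p1=0.5, q1=0.05)."""
    return SynapseParams(p1=0.5, q1=0.05, pmax=1.0, qmax=0.2, u=0.5, v=0.5)


@pytest.fixture
def fig2_stats() -> InputStats:
    return InputStats(alpha=0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_valid_params(rng: np.random.Generator, u=None, v=None) -> SynapseParams:
    """Uniformly random synapse parameters respecting p1<=pmax, q1<=qmax."""
    p1, pmax = np.sort(rng.random(2))
    q1, qmax = np.sort(rng.random(2))
    return SynapseParams(
        p1=p1, q1=q1, pmax=pmax, qmax=qmax,
        u=rng.random() if u is None else u,
        v=rng.random() if v is None else v,
    )
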