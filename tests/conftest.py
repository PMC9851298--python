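import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import deltarank as dr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_gem() -> dr.GeneExpressionMatrix:
    """4 genes x 3 cells with ties and zeros in known places."""
    values = np.array(
        [
            [5.0, 0.0, 2.0],
            [1.0, 0.0, 2.0],
            [0.0, 3.0, 2.0],
            [3.0, 7.0, 9.0],
        ]
    )
    return dr.GeneExpressionMatrix(values, ["g1", "g2", "g3", "g4"], ["c1", "c2", "c3"])


@pytest.fixture
def tiny_net() -> dr.BackgroundNetwork:
    return dr.BackgroundNetwork([("g1", "g4"), ("g3", "g1"), ("g2", "g3")])


@pytest.fixture(scope="session")
def sim_default() -> dr.SimulatedData:
    """Default synthetic scenario, shared across tests (read-only)."""
    return dr.simulate_gem(dr.SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def drm_default(sim_default) -> dr.DeltaRankMatrix:
    return dr.build_drm(sim_default.gem, sim_default.network)


def random_gem(rng: np.random.Generator, m: int, n: int) -> dr.GeneExpressionMatrix:
    values = rng.lognormal(0, 1, size=(m, n))
    values[rng.random((m, n)) < 0.2] = 0.0
    return dr.GeneExpressionMatrix(
        values, [f"g{i}" for i in range(m)], [f"c{j}" for j in range(n)]
    )
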