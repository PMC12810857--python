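import numpy as np
import pytest

from trigame import BASELINE, GameParameters, StrategyState
from trigame.experiments import sample_parameters


@pytest.fixture(scope="session")
def baseline() -> GameParameters:
    return BASELINE


@pytest.fixture(scope="session")
def e6_variant(baseline) -> GameParameters:
    """Baseline with weak reputational damage and penalty: the
    participate/defect/supervise corner E6 becomes the unique ESS."""
    return baseline.replace(bm=10, theta=0.3)


@pytest.fixture(scope="session")
def random_param_sets() -> list[GameParameters]:
    """A reusable pool of 500 random valid parameter sets (fixed seed)."""
    return sample_parameters("any", n=500, seed=20240601)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)


def random_states(rng: np.random.Generator, n: int, margin: float = 0.0) -> list[StrategyState]:
    lo, hi = margin, 1.0 - margin
    return [StrategyState(*row) for row in rng.uniform(lo, hi, size=(n, 3))]
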