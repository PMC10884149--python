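import numpy as np
import pytest

from snlc.model import LociPartition, Structure3D, contacts_from_structure
from snlc.simulate import SimulationConfig, brownian_pair, make_dataset


@pytest.fixture(scope="session")
def phase1_start():
    """Session-wide cached phase-1 start system (one monodromy run)."""
    from snlc.polysolve import get_phase1

    return get_phase1()


@pytest.fixture()
def small_structure():
    """Seeded 10-locus Brownian pair."""
    return brownian_pair(SimulationConfig(n=10, seed=42))


@pytest.fixture()
def small_dataset():
    """Noiseless labelled dataset, n=12, half ambiguous."""
    return make_dataset(SimulationConfig(n=12, ambiguous_fraction=0.5, seed=7))


def random_structure(rng: np.random.Generator, n: int,
                     separation: float = 5.0) -> Structure3D:
    x = rng.standard_normal((n, 3))
    y = rng.standard_normal((n, 3)) + np.array([separation, 0.0, 0.0])
    return Structure3D(x, y)
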