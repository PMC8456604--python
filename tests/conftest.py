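import numpy as np
import pytest

from tcrgamma import build_reference_db, simulate_dataset
from tcrgamma.simulate import SimulationConfig


@pytest.fixture(scope="session")
def db():
    return build_reference_db()


@pytest.fixture(scope="session")
def small_dataset(db):
    """500 zero-error read pairs with truth, shared across tests."""
    cfg = SimulationConfig(n_sequences=500, seed=42)
    return cfg, simulate_dataset(cfg, db)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
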