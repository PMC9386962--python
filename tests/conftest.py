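import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from altiscan import SimulationConfig, simulate_two_pop_dataset


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     alphabet: str = "ACGT") -> list[str]:
    """Random rectangular alignment used by the oracle-equivalence tests."""
    return ["".join(rng.choice(list(alphabet), size=length)) for _ in range(n)]


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 40-gene simulated dataset shared across I/O-level tests."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(seed=7, n_genes=40)
    paths = simulate_two_pop_dataset(cfg, out)
    return cfg, paths
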