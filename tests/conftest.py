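import numpy as np
import pytest

from tailcap import simulate


@pytest.fixture(scope="session")
def pore():
    return simulate.make_pore_model(seed=0)


@pytest.fixture(scope="session")
def standards():
    return {r.name: r for r in simulate.standards_registry()}


@pytest.fixture(scope="session")
def annotation():
    return simulate.simulate_annotation(n_genes=8, seed=11)


def child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
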