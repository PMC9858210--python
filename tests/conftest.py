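import numpy as np
import pytest

from markovagents import Kernel


def deterministic_kernel(mapping: dict, n: int) -> Kernel:
    """0/1 kernel sending state a to mapping[a] (1-based)."""
    m = np.zeros((n, n))
    for a, b in mapping.items():
        m[a - 1, b - 1] = 1.0
    labels = tuple(range(1, n + 1))
    return Kernel(labels, labels, m)


@pytest.fixture
def det_kernel():
    return deterministic_kernel


@pytest.fixture
def chain9():
    """Nine-state deterministic chain with cycles (158), (2), (34), (6), (79)."""
    return deterministic_kernel(
        {1: 5, 5: 8, 8: 1, 2: 2, 3: 4, 4: 3, 6: 6, 7: 9, 9: 7}, 9
    )


@pytest.fixture
def chain9_transient2():
    """Same chain with state 2 made transient (2 -> 1)."""
    return deterministic_kernel(
        {1: 5, 5: 8, 8: 1, 2: 1, 3: 4, 4: 3, 6: 6, 7: 9, 9: 7}, 9
    )


@pytest.fixture
def identity2():
    return deterministic_kernel({1: 1, 2: 2}, 2)


@pytest.fixture
def not2():
    return deterministic_kernel({1: 2, 2: 1}, 2)
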