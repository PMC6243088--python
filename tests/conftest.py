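import numpy as np
import pytest

from conneval import ContingencyTable, LabelVolume, generate_scene


@pytest.fixture
def toy_table():
    """Reference 1 split between test segments; a worked example used throughout:
    S = [10,10,10,10,20,20,21,21], G = [1,1,1,1,2,2,2,2] on a 2x2x2 grid."""
    return ContingencyTable({(10, 1): 4, (20, 2): 2, (21, 2): 2})


@pytest.fixture
def toy_volumes():
    G = LabelVolume(np.array([1, 1, 1, 1, 2, 2, 2, 2]).reshape(2, 2, 2))
    S = LabelVolume(np.array([10, 10, 10, 10, 20, 20, 21, 21]).reshape(2, 2, 2))
    return S, G


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene((32, 32, 32), n_segments=20, n_connections=200, seed=7)


def random_volume(rng, shape, n_labels, p_background=0.2):
    """Random label volume with background, for oracle comparisons."""
    data = rng.integers(1, n_labels + 1, size=shape)
    data[rng.random(shape) < p_background] = 0
    return LabelVolume(data)


def random_table(rng, n_s=6, n_g=5, max_count=20):
    counts = {}
    for s in range(1, n_s + 1):
        for g in range(1, n_g + 1):
            if rng.random() < 0.5:
                c = int(rng.integers(1, max_count))
                counts[(s * 10, g)] = c
    if not counts:
        counts[(10, 1)] = 1
    return ContingencyTable(counts)
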