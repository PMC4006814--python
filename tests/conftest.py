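import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pathconcord import GeneSet, GeneSetCollection

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def random_collection(rng, n_sets=20, n_genes=100, size_range=(2, 12)):
    genes = np.array([f"G{i:03d}" for i in range(n_genes)], dtype=object)
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(GeneSet(f"S{i:03d}", f"desc {i}", frozenset(members)))
    return GeneSetCollection(sets)


@pytest.fixture
def small_collection(rng):
    return random_collection(rng)
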