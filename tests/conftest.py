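import numpy as np
import pytest

from ldsplit import bench
from ldsplit.hapio import HaplotypePanel


def make_random_panel(rng, n, L, missing_rate=0.0, unit="kb"):
    """Random panel; every site is guaranteed polymorphic."""
    alleles = (rng.random((n, L)) < rng.uniform(0.2, 0.8, size=L)).astype(np.int8)
    for j in range(L):
        if not (alleles[:, j] == 0).any():
            alleles[rng.integers(n), j] = 0
        if not (alleles[:, j] == 1).any():
            alleles[rng.integers(n), j] = 1
    if missing_rate > 0:
        mask = rng.random((n, L)) < missing_rate
        alleles[mask] = -1
    positions = np.sort(rng.uniform(0, 100, size=L))
    while np.any(np.diff(positions) <= 0):
        positions = np.sort(rng.uniform(0, 100, size=L))
    return HaplotypePanel(alleles=alleles, positions=positions, unit=unit)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_panel(rng):
    return make_random_panel(rng, 8, 6)


@pytest.fixture(scope="session")
def power_results():
    """Shared scan of ten causal desk datasets (used by several
    end-to-end assertions; expensive, so computed once)."""
    return bench.power_experiment(
        n_populations=5, subsets_per_pop=2, n_perm=99, seed=0
    )
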