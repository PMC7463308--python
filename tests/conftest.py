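import numpy as np
import pytest

from relictgen.genotype_io import MISSING, PopulationMap, SNPMatrix


def make_matrix(geno, sample_prefix="s", locus_prefix="L", radlocus_ids=None,
                positions=None):
    geno = np.asarray(geno, dtype=np.int8)
    n, L = geno.shape
    return SNPMatrix(
        geno,
        [f"{sample_prefix}{i}" for i in range(n)],
        [f"{locus_prefix}{j}" for j in range(L)],
        radlocus_ids,
        positions,
    )


def make_popmap(n_samples, pop_sizes, groups=None, sample_prefix="s"):
    """Assign the first pop_sizes[0] samples to pop0, etc."""
    assert sum(pop_sizes) == n_samples
    s2p = {}
    i = 0
    for k, size in enumerate(pop_sizes):
        for _ in range(size):
            s2p[f"{sample_prefix}{i}"] = f"pop{k}"
            i += 1
    if groups is None:
        groups = {f"pop{k}": "G" for k in range(len(pop_sizes))}
    coords = {f"pop{k}": (float(k), float(2 * k)) for k in range(len(pop_sizes))}
    return PopulationMap(s2p, groups, coords)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    geno = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
    return make_matrix(geno)


@pytest.fixture
def small_popmap():
    return make_popmap(12, [4, 4, 4],
                       {"pop0": "A", "pop1": "A", "pop2": "B"})
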