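import numpy as np
import pytest

from ssrpop import GenotypeMatrix, SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic panel: 45 individuals x 21 loci, seed 2022."""
    return simulate_population(SimulationConfig())


@pytest.fixture(scope="session")
def clean_sim():
    """Single unstructured population with no clones/sibs/outgroup/missing."""
    cfg = SimulationConfig(
        n_individuals=50, k_true=1, f_st=0.0, n_clone_pairs=0,
        n_sib_pairs=0, outgroup=False, missing_rate=0.0, seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture
def toy_two_locus():
    """Hand-checkable 3-individual, 2-locus matrix.

    Locus A carries 2 alleles overall, locus B carries 3, so the weighted
    index uses weights (2/5, 3/5).  Pair (0, 1) shares one allele copy at
    A (11 vs 12) and two at B (12 vs 12).
    """
    calls = np.array(
        [
            [[1, 1], [1, 2]],
            [[1, 2], [1, 2]],
            [[2, 2], [3, 3]],
        ]
    )
    return GenotypeMatrix(["i0", "i1", "i2"], ["A", "B"], calls)


def two_population_matrix(n_per_pop=10, n_fixed=4, n_shared=17, seed=0):
    """Two populations with `n_fixed` fixed allele differences and
    `n_shared` loci polymorphic in both (same frequencies)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_pop
    L = n_fixed + n_shared
    calls = np.zeros((n, L, 2), dtype=np.int64)
    for j in range(n_fixed):
        calls[:n_per_pop, j] = 1
        calls[n_per_pop:, j] = 2
    for j in range(n_fixed, L):
        p = rng.uniform(0.3, 0.7)
        draws = (rng.random((n, 2)) < p).astype(np.int64) + 1
        calls[:, j] = np.sort(draws, axis=1)
    inds = [f"a{i}" for i in range(n_per_pop)] + [f"b{i}" for i in range(n_per_pop)]
    return GenotypeMatrix(inds, [f"L{j}" for j in range(L)], calls)


@pytest.fixture(scope="session")
def two_pop():
    return two_population_matrix()
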