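import itertools

import numpy as np
import pytest

from ssrpop import (
    GenotypeMatrix,
    SimulationConfig,
    simulate_population,
    analyze_distance,
    cophenetic_correlation,
    mojena_cut,
    pairwise_distance_matrix,
    select_index_by_cophenetic,
    smouse_peakall_distance,
    unweighted_similarity,
    upgma,
    weighted_similarity,
)
from ssrpop.distance import (
    IncomparablePairError,
    cophenetic_matrix,
    shared_allele_score,
    to_newick,
)


# --------------------------------------------------------------- oracles
def upgma_oracle(d):
    """Naive average linkage: repeatedly merge the pair of clusters with
    the smallest mean leaf-to-leaf distance.  Returns the implied
    cophenetic matrix and sorted fusion heights."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or avg < best[0]:
                best = (avg, a, b)
        h, a, b = best
        heights.append(h)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph, sorted(heights)


def smouse_peakall_oracle(g1, g2):
    """Case table of the codominant squared distance for one locus."""
    s1, s2 = set(g1), set(g2)
    hom1, hom2 = len(s1) == 1, len(s2) == 1
    shared = shared_allele_score(g1, g2)
    if tuple(sorted(g1)) == tuple(sorted(g2)):
        return 0
    if hom1 and hom2:
        return 4                       # opposite homozygotes
    if hom1 != hom2:
        return 1 if shared else 3      # hom vs het
    return 1 if shared == 1 else 2     # het vs het


def random_distance_matrix(rng, n):
    d = rng.uniform(0.01, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


# ----------------------------------------------------------- pair scores
class TestSharedAlleleScore:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 1), (1, 1), 2),
        ((1, 2), (1, 2), 2),
        ((1, 2), (1, 1), 1),
        ((1, 2), (1, 3), 1),
        ((1, 1), (2, 2), 0),
        ((1, 2), (3, 4), 0),
    ])
    def test_multiset_intersection(self, a, b, expected):
        assert shared_allele_score(a, b) == expected


class TestSimilarityIndices:
    def test_identical_individuals_have_unit_similarity(self, toy_two_locus):
        g = toy_two_locus
        s, _ = weighted_similarity(g, 1, 1)
        assert s == pytest.approx(1.0)
        assert unweighted_similarity(g, 1, 1) == pytest.approx(1.0)

    def test_disjoint_individuals_have_zero_similarity(self):
        g = GenotypeMatrix(
            ["a", "b"], ["L1", "L2"],
            [[[1, 1], [1, 2]], [[2, 2], [3, 4]]],
        )
        s, common = weighted_similarity(g, "a", "b")
        assert s == 0.0 and common == 0

    def test_hand_worked_weighted_toy(self, toy_two_locus):
        """Locus weights (0.4, 0.6); scores (1/2, 1) -> S = 0.8, D = 0.2."""
        s, common = weighted_similarity(toy_two_locus, "i0", "i1")
        assert s == pytest.approx(0.8)
        assert common == 3
        assert unweighted_similarity(toy_two_locus, "i0", "i1") == pytest.approx(0.75)
        d = pairwise_distance_matrix(toy_two_locus, "weighted")
        assert d[0, 1] == pytest.approx(0.2)

    def test_weighted_equals_unweighted_for_equal_allele_counts(self):
        rng = np.random.default_rng(0)
        calls = np.sort(rng.integers(1, 3, size=(6, 4, 2)), axis=2)
        calls[0, :, 0] = 1
        calls[0, :, 1] = 2  # ensure both alleles observed at every locus
        g = GenotypeMatrix([f"i{k}" for k in range(6)],
                           [f"L{k}" for k in range(4)], calls)
        for i, j in itertools.combinations(range(6), 2):
            s, _ = weighted_similarity(g, i, j)
            assert s == pytest.approx(unweighted_similarity(g, i, j))

    def test_smouse_peakall_against_case_table(self):
        """Implementation agrees with the exhaustive genotype-pair table."""
        genos = [tuple(sorted(p)) for p in
                 itertools.combinations_with_replacement(range(1, 5), 2)]
        for g1, g2 in itertools.product(genos, repeat=2):
            g = GenotypeMatrix(["a", "b"], ["L"], [[g1], [g2]])
            assert smouse_peakall_distance(g, "a", "b") == pytest.approx(
                smouse_peakall_oracle(g1, g2)
            ), (g1, g2)

    def test_no_common_typed_locus_raises(self):
        g = GenotypeMatrix(
            ["a", "b"], ["L1", "L2"],
            [[[1, 1], [0, 0]], [[0, 0], [2, 2]]],
        )
        with pytest.raises(IncomparablePairError):
            weighted_similarity(g, "a", "b")

    def test_missing_loci_renormalize_weights(self):
        # same pair, one locus masked for b: weights renormalize over typed
        g = GenotypeMatrix(
            ["a", "b", "c"], ["A", "B"],
            [[[1, 1], [1, 2]], [[1, 2], [0, 0]], [[2, 2], [3, 3]]],
        )
        s, _ = weighted_similarity(g, "a", "b")
        assert s == pytest.approx(0.5)  # only locus A (score 1/2) counts

    def test_matrix_symmetry_zero_diagonal(self, default_sim):
        g, _ = default_sim
        for index in ("weighted", "unweighted", "smouse-peakall"):
            d = pairwise_distance_matrix(g, index)
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            if index != "smouse-peakall":
                assert d.min() >= -1e-12 and d.max() <= 1 + 1e-12


# ------------------------------------------------------------------ UPGMA
class TestUpgma:
    def test_two_leaves_merge_at_their_distance(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        z = upgma(d)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.3)

    def test_three_leaf_hand_case(self):
        d = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [0.4, 0.4, 0.0]])
        z = upgma(d)
        assert z[0, 2] == pytest.approx(0.1)
        assert z[1, 2] == pytest.approx(0.4)

    def test_ultrametric_input_is_fixed_point(self):
        # build an ultrametric matrix from a known tree
        d = np.array([
            [0.0, 0.2, 0.6, 0.6],
            [0.2, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.4],
            [0.6, 0.6, 0.4, 0.0],
        ])
        z = upgma(d)
        np.testing.assert_allclose(cophenetic_matrix(z), d)
        assert cophenetic_correlation(d, z) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_random_battery(self):
        """200 random matrices with n <= 6: cophenetic matrices agree."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 7))
            d = random_distance_matrix(rng, n)
            z = upgma(d)
            coph_oracle, heights_oracle = upgma_oracle(d)
            np.testing.assert_allclose(cophenetic_matrix(z), coph_oracle,
                                       rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(sorted(z[:, 2]), heights_oracle,
                                       rtol=1e-10, atol=1e-12)

    def test_fusion_heights_nondecreasing(self, default_sim):
        g, _ = default_sim
        z = upgma(pairwise_distance_matrix(g, "weighted"))
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            upgma(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            upgma(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestCopheneticCorrelation:
    def test_perturbed_matrix_below_one(self):
        rng = np.random.default_rng(1)
        d = np.array([
            [0.0, 0.2, 0.6, 0.6],
            [0.2, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.4],
            [0.6, 0.6, 0.4, 0.0],
        ])
        d[0, 2] = d[2, 0] = 0.75
        assert cophenetic_correlation(d, upgma(d)) < 1.0

    def test_agrees_with_pairwise_list_computation(self):
        rng = np.random.default_rng(2)
        d = random_distance_matrix(rng, 4)
        z = upgma(d)
        coph = cophenetic_matrix(z)
        iu = np.triu_indices(4, k=1)
        expected = np.corrcoef(d[iu], coph[iu])[0, 1]
        assert cophenetic_correlation(d, z) == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        d = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
        with pytest.raises(ValueError, match="zero variance"):
            cophenetic_correlation(d, upgma(d))


class TestMojenaCut:
    def make_linkage(self, heights):
        # chain of merges over 5 leaves with the given fusion heights
        return np.array([
            [0, 1, heights[0], 2],
            [2, 3, heights[1], 2],
            [5, 4, heights[2], 3],
            [6, 7, heights[3], 5],
        ])

    def test_hand_worked_threshold(self):
        """Heights (1,1,1,10), k=1.25: mean 3.25, sd 4.5, cut 8.875 -> 2."""
        z = self.make_linkage([1, 1, 1, 10])
        groups = mojena_cut(z, 1.25)
        assert groups.max() == 2

    def test_no_height_above_threshold_single_group(self):
        z = self.make_linkage([1.0, 1.1, 1.2, 1.3])
        assert mojena_cut(z, 3.0).max() == 1

    def test_every_height_above_threshold_all_singletons(self):
        z = self.make_linkage([1, 1, 1, 10])
        # negative k pushes the threshold below the smallest height
        assert mojena_cut(z, -10.0).max() == 5

    def test_equal_heights_warns_single_group(self):
        z = self.make_linkage([1, 1, 1, 1])
        with pytest.warns(UserWarning):
            groups = mojena_cut(z)
        assert groups.max() == 1

    def test_recovers_separated_clusters(self):
        """F_ST >= 0.3: the cut finds >= K_true groups and each multi-member
        group is dominated by one true cluster."""
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                n_individuals=45, f_st=0.35, n_clone_pairs=0, n_sib_pairs=0,
                outgroup=False, missing_rate=0.0, seed=seed,
            )
            g, truth = simulate_population(cfg)
            res = analyze_distance(g, "weighted")
            assert res.n_groups() >= 3
            pure = 0
            for gid in range(1, res.n_groups() + 1):
                members = truth.cluster_labels[res.groups == gid]
                _, counts = np.unique(members, return_counts=True)
                pure += counts.max()
            assert pure / g.n_individuals >= 0.9


class TestIndexSelection:
    def test_returns_table_over_all_indices(self, default_sim):
        g, _ = default_sim
        best, table = select_index_by_cophenetic(g)
        assert set(table) == {"weighted", "unweighted", "smouse-peakall"}
        assert best.r_c == max(table.values())

    def test_tie_prefers_weighted(self, monkeypatch):
        import ssrpop.distance as dist

        g, _ = simulate_population(SimulationConfig(
            n_individuals=10, n_clone_pairs=0, n_sib_pairs=0,
            outgroup=False, seed=3,
        ))
        monkeypatch.setattr(
            dist, "cophenetic_correlation", lambda d, z: 0.9
        )
        best, table = dist.select_index_by_cophenetic(g)
        assert best.index == "weighted"

    def test_minimum_three_individuals(self):
        g = GenotypeMatrix(["a", "b"], ["L"], [[[1, 1]], [[1, 2]]])
        with pytest.raises(ValueError):
            select_index_by_cophenetic(g)


def test_outgroup_merges_last(default_sim):
    """The private-allele outgroup is the last leaf to join the tree."""
    g, truth = default_sim
    z = upgma(pairwise_distance_matrix(g, "weighted"))
    last = z[-1]
    assert truth.outgroup_index in (int(last[0]), int(last[1]))


def test_newick_export_contains_all_labels(default_sim):
    g, _ = default_sim
    z = upgma(pairwise_distance_matrix(g, "weighted"))
    nwk = to_newick(z, g.individuals)
    assert nwk.endswith(";")
    for name in g.individuals:
        assert name in nwk
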