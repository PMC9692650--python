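"""Pairwise dissimilarity indices, UPGMA clustering and the Mojena cut.

Three codominant indices are provided for a pair of diploid individuals:

weighted similarity
    ``S = sum_j p_j * c_j`` over loci typed in both individuals, where
    ``p_j = a_j / A`` weights locus ``j`` by its allele count ``a_j``
    relative to the panel total ``A`` (renormalised over the typed loci),
    and ``c_j`` is the shared-allele score scaled to [0, 1]: 0, 1/2 or 1
    for 0, 1 or 2 shared allele copies (multiset intersection).
    Dissimilarity is ``D = 1 - S``.

unweighted similarity
    the plain mean of the shared-allele scores over typed loci.

Smouse-Peakall squared distance
    the codominant genotype metric summed over loci: per locus 0 for
    identical genotypes, 1 for hom vs het or het vs het sharing one
    allele, 2 for heterozygotes sharing none, 3 for hom vs het sharing
    none, 4 for opposite homozygotes.

Clustering uses UPGMA (average linkage); the dendrogram is cut with
Mojena's stopping rule: undo every fusion whose height exceeds
``mean(heights) + k * sd(heights)`` (sample sd, default k = 1.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genotypes import GenotypeMatrix, NoDataError

__all__ = [
    "DistanceResult",
    "shared_allele_score",
    "weighted_similarity",
    "unweighted_similarity",
    "smouse_peakall_distance",
    "pairwise_distance_matrix",
    "upgma",
    "cophenetic_correlation",
    "mojena_cut",
    "select_index_by_cophenetic",
    "to_newick",
    "INDEX_ORDER",
]

INDEX_ORDER = ("weighted", "unweighted", "smouse-peakall")

MOJENA_K_DEFAULT = 1.25


class IncomparablePairError(NoDataError):
    """Two individuals share no typed locus."""


# ------------------------------------------------------------- pair scores
def shared_allele_score(call_a, call_b) -> int:
    """Number of shared allele copies between two diploid calls (0, 1, 2).

    Multiset intersection: AB vs AA shares 1 copy, AB vs AB shares 2.
    """
    a1, a2 = call_a
    b1, b2 = call_b
    shared = 0
    b = [b1, b2]
    for a in (a1, a2):
        if a in b:
            b.remove(a)
            shared += 1
    return shared


def _common_typed(g: GenotypeMatrix, i: int, i2: int) -> np.ndarray:
    typed = g.typed_mask()
    both = typed[i] & typed[i2]
    if not both.any():
        raise IncomparablePairError(
            f"individuals {g.individuals[i]!r} and {g.individuals[i2]!r} "
            "share no typed locus"
        )
    return both


def weighted_similarity(g: GenotypeMatrix, i, i2):
    """Allele-count-weighted similarity S in [0, 1].

    Returns ``(S, total_common)`` where ``total_common`` is the raw count
    of shared allele copies summed over the loci typed in both.
    """
    i, i2 = g.individual_index(i), g.individual_index(i2)
    both = _common_typed(g, i, i2)
    a_j = np.array([g.n_alleles(j) for j in range(g.n_loci)], dtype=float)
    weights = a_j * both
    weights = weights / weights.sum()
    s = 0.0
    total_common = 0
    for j in np.flatnonzero(both):
        c = shared_allele_score(g.calls[i, j], g.calls[i2, j])
        total_common += c
        s += weights[j] * (c / 2.0)
    return float(s), int(total_common)


def unweighted_similarity(g: GenotypeMatrix, i, i2) -> float:
    """Mean shared-allele score over loci typed in both individuals."""
    i, i2 = g.individual_index(i), g.individual_index(i2)
    both = _common_typed(g, i, i2)
    scores = [
        shared_allele_score(g.calls[i, j], g.calls[i2, j]) / 2.0
        for j in np.flatnonzero(both)
    ]
    return float(np.mean(scores))


def smouse_peakall_distance(g: GenotypeMatrix, i, i2) -> float:
    """Smouse-Peakall squared genotype distance summed over typed loci.

    Computed as half the squared Euclidean distance between the per-locus
    allele-count vectors (2 for a homozygous allele, 1 for each
    heterozygous allele).
    """
    i, i2 = g.individual_index(i), g.individual_index(i2)
    both = _common_typed(g, i, i2)
    total = 0.0
    for j in np.flatnonzero(both):
        a1, a2 = g.calls[i, j]
        b1, b2 = g.calls[i2, j]
        alleles = {int(a1), int(a2), int(b1), int(b2)}
        ya = {a: 0 for a in alleles}
        yb = {a: 0 for a in alleles}
        ya[a1] += 1
        ya[a2] += 1
        yb[b1] += 1
        yb[b2] += 1
        total += 0.5 * sum((ya[a] - yb[a]) ** 2 for a in alleles)
    return float(total)


# ------------------------------------------------------- distance matrices
def pairwise_distance_matrix(g: GenotypeMatrix, index: str = "weighted") -> np.ndarray:
    """Symmetric pairwise dissimilarity matrix under the chosen index.

    For the similarity indices the entry is ``D = 1 - S``; for
    ``smouse-peakall`` it is the squared distance itself.
    """
    n = g.n_individuals
    d = np.zeros((n, n))
    for i in range(n):
        for i2 in range(i + 1, n):
            if index == "weighted":
                s, _ = weighted_similarity(g, i, i2)
                dij = 1.0 - s
            elif index == "unweighted":
                dij = 1.0 - unweighted_similarity(g, i, i2)
            elif index == "smouse-peakall":
                dij = smouse_peakall_distance(g, i, i2)
            else:
                raise ValueError(f"unknown index {index!r}")
            d[i, i2] = d[i2, i] = dij
    return d


# ---------------------------------------------------------------- UPGMA
def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("diagonal must be zero")
    return d


def upgma(d: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) merge list in scipy linkage form.

    Each row is ``(cluster_a, cluster_b, fusion_height, size)``; a pair of
    leaves at distance ``d`` fuses at height ``d``.  Heights are
    non-decreasing in merge order.
    """
    d = _check_square(d)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def cophenetic_matrix(linkage: np.ndarray) -> np.ndarray:
    return squareform(hierarchy.cophenet(linkage))


def cophenetic_correlation(d: np.ndarray, linkage: np.ndarray) -> float:
    """Pearson correlation between D and the dendrogram's cophenetic
    distances, over the n(n-1)/2 pairs."""
    d = _check_square(d)
    orig = squareform(d, checks=False)
    coph = hierarchy.cophenet(linkage)
    if np.std(orig) == 0 or np.std(coph) == 0:
        raise ValueError("cophenetic correlation undefined (zero variance)")
    return float(np.corrcoef(orig, coph)[0, 1])


def mojena_cut(linkage: np.ndarray, k: float = MOJENA_K_DEFAULT) -> np.ndarray:
    """Flat groups from Mojena's stopping rule.

    The threshold is ``mean(h) + k * sd(h)`` over the fusion heights
    ``h`` (sample standard deviation); every fusion above the threshold
    is undone.  Returns integer group labels (1-based) for the leaves.
    """
    heights = linkage[:, 2]
    if len(heights) < 1:
        raise ValueError("need at least one merge")
    sd = float(np.std(heights, ddof=1)) if len(heights) > 1 else 0.0
    if sd == 0.0:
        import warnings

        warnings.warn("all fusion heights equal; returning a single group")
        n = linkage.shape[0] + 1
        return np.ones(n, dtype=int)
    threshold = float(np.mean(heights)) + k * sd
    return hierarchy.fcluster(linkage, t=threshold, criterion="distance")


@dataclass
class DistanceResult:
    """Distance analysis bundle for one index."""

    index: str
    d: np.ndarray
    linkage: np.ndarray
    cophenetic: np.ndarray
    r_c: float
    groups: np.ndarray
    individuals: list

    def n_groups(self) -> int:
        return int(self.groups.max())


def analyze_distance(
    g: GenotypeMatrix, index: str = "weighted", mojena_k: float = MOJENA_K_DEFAULT
) -> DistanceResult:
    d = pairwise_distance_matrix(g, index)
    z = upgma(d)
    return DistanceResult(
        index=index,
        d=d,
        linkage=z,
        cophenetic=cophenetic_matrix(z),
        r_c=cophenetic_correlation(d, z),
        groups=mojena_cut(z, mojena_k),
        individuals=list(g.individuals),
    )


def select_index_by_cophenetic(g: GenotypeMatrix, indices=INDEX_ORDER,
                               mojena_k: float = MOJENA_K_DEFAULT):
    """Run UPGMA under each index and keep the one with the highest
    cophenetic correlation (ties resolved by the fixed order
    weighted, unweighted, smouse-peakall).

    Returns ``(best DistanceResult, {index: r_c})``.
    """
    if g.n_individuals < 3:
        raise ValueError("index selection needs at least 3 individuals")
    results = {idx: analyze_distance(g, idx, mojena_k) for idx in indices}
    table = {idx: results[idx].r_c for idx in indices}
    best = max(indices, key=lambda idx: table[idx])  # max is stable: first wins ties
    return results[best], table


def to_newick(linkage: np.ndarray, labels) -> str:
    """Newick string (with branch lengths) for a linkage dendrogram."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, list(labels))
    return str(tree).strip()
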