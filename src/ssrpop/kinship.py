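"""Pairwise Loiselle kinship coefficients.

The Loiselle estimator measures co-ancestry of two individuals relative to
the sample allele frequencies.  With ``p_ila`` the frequency of allele
``a`` at locus ``l`` within individual ``i`` (0, 1/2 or 1 for a diploid),
``pbar_la`` the sample frequency, and ``n_l`` the number of typed
individuals at ``l``:

    F_ij = [ sum_l sum_a (p_ila - pbar_la)(p_jla - pbar_la)
             + sum_l sum_a pbar_la (1 - pbar_la) / (n_l - 1) ]
           / sum_l sum_a pbar_la (1 - pbar_la)

The second numerator term is the small-sample bias correction.  Numerators
and denominators are summed over loci before dividing (a single multilocus
ratio, which weights each locus by its polymorphism); per-locus averaging
is available behind a flag.  Sums run over the loci typed in both members
of the pair.  Reference frequencies are those of the full sample, including
the pair itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, NoDataError

__all__ = ["KinshipMatrix", "loiselle_kinship", "kinship_matrix", "kinship_histogram",
           "DEFAULT_BINS", "PAPER_BIN_LABELS"]

# contiguous half-open bins mirroring the customary reporting intervals
DEFAULT_BINS = (-np.inf, 0.0, 0.1, 0.3, 0.5, np.inf)
PAPER_BIN_LABELS = ("< 0", "0 to 0.09", "0.1 to 0.3", "0.3 to 0.5", "> 0.5")


@dataclass
class KinshipMatrix:
    """Symmetric matrix of pairwise Loiselle coefficients (diagonal NaN)."""

    values: np.ndarray
    individuals: list

    def pair(self, i, j) -> float:
        return float(self.values[i, j])

    def upper_triangle(self) -> np.ndarray:
        n = self.values.shape[0]
        iu = np.triu_indices(n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals,
                            columns=self.individuals)


def _locus_terms(g: GenotypeMatrix):
    """Per-locus quantities reused by every pair.

    Returns, per locus: allele codes, sample frequencies, per-individual
    allele dosage matrix (n x n_alleles, rows NaN when untyped), n_typed,
    and the denominator/correction scalars.
    """
    typed = g.typed_mask()
    out = []
    for j in range(g.n_loci):
        af = g.allele_frequencies(j)
        alleles = af.alleles
        idx = {a: k for k, a in enumerate(alleles)}
        n = g.n_individuals
        dose = np.full((n, len(alleles)), np.nan)
        for i in range(n):
            if not typed[i, j]:
                continue
            dose[i] = 0.0
            a, b = g.calls[i, j]
            dose[i, idx[a]] += 0.5
            dose[i, idx[b]] += 0.5
        n_typed = int(typed[:, j].sum())
        denom = float(np.sum(af.freqs * (1.0 - af.freqs)))
        corr = denom / (n_typed - 1) if n_typed > 1 else 0.0
        out.append((af.freqs, dose, denom, corr))
    return out, typed


def loiselle_kinship(g: GenotypeMatrix, i, i2, per_locus_average: bool = False,
                     correction: bool = True) -> float:
    """Loiselle kinship coefficient for one pair of individuals.

    ``correction=False`` drops the small-sample bias term from the
    numerator.
    """
    i, i2 = g.individual_index(i), g.individual_index(i2)
    terms, typed = _locus_terms(g)
    return _pair_kinship(terms, typed, i, i2, per_locus_average, correction)


def _pair_kinship(terms, typed, i, i2, per_locus_average: bool,
                  correction: bool = True) -> float:
    num_sum = den_sum = 0.0
    ratios = []
    any_locus = False
    for j, (freqs, dose, denom, corr) in enumerate(terms):
        if not (typed[i, j] and typed[i2, j]):
            continue
        if denom == 0.0:
            continue  # monomorphic locus carries no information
        any_locus = True
        num = float(np.sum((dose[i] - freqs) * (dose[i2] - freqs)))
        if correction:
            num += corr
        if per_locus_average:
            ratios.append(num / denom)
        else:
            num_sum += num
            den_sum += denom
    if not any_locus:
        if not np.any(typed[i] & typed[i2]):
            raise NoDataError("pair shares no typed locus")
        raise NoDataError("all shared loci are monomorphic; kinship undefined")
    if per_locus_average:
        return float(np.mean(ratios))
    return num_sum / den_sum


def kinship_matrix(g: GenotypeMatrix, per_locus_average: bool = False,
                   correction: bool = True) -> KinshipMatrix:
    """Full symmetric pairwise Loiselle kinship matrix (diagonal NaN)."""
    terms, typed = _locus_terms(g)
    n = g.n_individuals
    k = np.full((n, n), np.nan)
    for i in range(n):
        for i2 in range(i + 1, n):
            v = _pair_kinship(terms, typed, i, i2, per_locus_average, correction)
            k[i, i2] = k[i2, i] = v
    return KinshipMatrix(values=k, individuals=list(g.individuals))


def kinship_histogram(k: KinshipMatrix, bins=DEFAULT_BINS) -> pd.DataFrame:
    """Fraction of the n(n-1)/2 pairwise estimates per kinship bin.

    Bins are half-open ``[lo, hi)`` and must be non-overlapping and
    increasing.
    """
    edges = np.asarray(bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    vals = k.upper_triangle()
    counts, _ = np.histogram(vals, bins=edges)
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    return pd.DataFrame(
        {"bin": labels, "count": counts, "fraction": counts / len(vals)}
    )
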