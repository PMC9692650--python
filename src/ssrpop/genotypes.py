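"""Diploid codominant genotype matrices with numeric allele coding.

Genotypes at an SSR (microsatellite) locus are unordered pairs of allele
calls.  Following the usual practice for codominant data, raw allele labels
(typically fragment sizes in bp) are converted to small integer codes
``1..NA`` per locus, so a three-allele locus has homozygotes ``11``, ``22``,
``33`` and heterozygotes ``12``, ``13``, ``23``.  Code ``0`` is the missing
sentinel; a genotype is either fully typed or fully missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AlleleFrequencies",
    "MalformedGenotypeError",
    "UnknownAlleleError",
    "NoDataError",
    "encode_numeric",
]


class MalformedGenotypeError(ValueError):
    """A raw call does not consist of exactly two allele labels."""


class UnknownAlleleError(KeyError):
    """An allele label cannot be mapped at its locus."""


class NoDataError(ValueError):
    """A locus (or pair of individuals) has no usable calls."""


@dataclass
class AlleleFrequencies:
    """Relative allele frequencies at one locus, over non-missing copies.

    ``alleles`` holds the sorted distinct numeric allele codes observed at
    the locus; ``freqs[i]`` is the relative frequency of ``alleles[i]``.
    ``n_copies`` is the number of allele copies counted (2 per typed
    diploid individual).
    """

    locus: str
    alleles: np.ndarray
    freqs: np.ndarray
    n_copies: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.freqs < 0):
            raise ValueError("negative allele frequency")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")


class GenotypeMatrix:
    """Individuals x loci table of diploid codominant genotype calls.

    Parameters
    ----------
    individuals, loci : sequences of unique identifiers.
    calls : int array, shape (n_individuals, n_loci, 2)
        Numeric allele codes (>=1), or ``0`` for missing.  Pairs are stored
        order-normalised (smaller code first).  Half-missing pairs are
        promoted to fully missing with a warning.
    allele_labels : optional mapping ``locus -> list of original labels``
        such that code ``k`` at that locus decodes to ``labels[k-1]``.
    """

    ploidy = 2

    def __init__(self, individuals, loci, calls, allele_labels=None):
        self.individuals = list(individuals)
        self.loci = list(loci)
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual identifiers")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus identifiers")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        if np.any(calls < 0):
            raise ValueError("allele codes must be >= 0 (0 = missing)")
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            warnings.warn(
                f"{int(half.sum())} half-missing call(s) promoted to fully missing",
                stacklevel=2,
            )
            calls[half] = MISSING
        self.calls = np.sort(calls, axis=2)
        self.allele_labels = dict(allele_labels) if allele_labels else {}

    # -- basic geometry ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus) -> int:
        if isinstance(locus, (int, np.integer)):
            return int(locus)
        return self.loci.index(locus)

    def individual_index(self, ind) -> int:
        if isinstance(ind, (int, np.integer)):
            return int(ind)
        return self.individuals.index(ind)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the genotype call is non-missing."""
        return self.calls[:, :, 0] != MISSING

    # -- allele bookkeeping -----------------------------------------------
    def observed_alleles(self, locus) -> np.ndarray:
        """Sorted distinct allele codes observed at `locus`."""
        j = self.locus_index(locus)
        col = self.calls[:, j, :]
        vals = np.unique(col[col != MISSING])
        return vals

    def n_alleles(self, locus) -> int:
        """NA: the number of distinct alleles observed at `locus`."""
        return len(self.observed_alleles(locus))

    def allele_frequencies(self, locus) -> AlleleFrequencies:
        """Sample allele frequencies at `locus` over non-missing copies.

        A homozygote contributes two copies of its allele, a heterozygote
        one copy of each.
        """
        j = self.locus_index(locus)
        col = self.calls[:, j, :]
        copies = col[col != MISSING]
        if copies.size == 0:
            raise NoDataError(f"locus {self.loci[j]!r} has no non-missing calls")
        alleles, counts = np.unique(copies, return_counts=True)
        return AlleleFrequencies(
            locus=self.loci[j],
            alleles=alleles,
            freqs=counts / copies.size,
            n_copies=int(copies.size),
        )

    # -- views ------------------------------------------------------------
    def decode(self, individual, locus):
        """Original allele labels for one call (None if missing)."""
        i = self.individual_index(individual)
        j = self.locus_index(locus)
        a, b = self.calls[i, j]
        if a == MISSING:
            return None
        labels = self.allele_labels.get(self.loci[j])
        if labels is None:
            return (int(a), int(b))
        return (labels[a - 1], labels[b - 1])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x "
            f"{self.n_loci} loci)"
        )


def encode_numeric(individuals, loci, raw_calls) -> GenotypeMatrix:
    """Convert raw allele labels to per-locus numeric codes.

    ``raw_calls[i][j]`` is a pair of hashable allele labels (e.g. fragment
    sizes) for individual ``i`` at locus ``j``, or ``None``/empty for a
    missing call.  Codes are assigned 1..n per locus by first appearance in
    file order, and the label table is kept on the result for round-trip
    decoding.
    """
    individuals = list(individuals)
    loci = list(loci)
    n, L = len(individuals), len(loci)
    calls = np.zeros((n, L, 2), dtype=np.int64)
    tables: dict[str, list] = {locus: [] for locus in loci}

    def code(locus, label):
        table = tables[locus]
        try:
            return table.index(label) + 1
        except ValueError:
            table.append(label)
            return len(table)

    for i in range(n):
        row = raw_calls[i]
        if len(row) != L:
            raise MalformedGenotypeError(
                f"individual {individuals[i]!r} has {len(row)} calls, expected {L}"
            )
        for j, call in enumerate(row):
            if call is None or len(call) == 0:
                continue
            if len(call) != 2:
                raise MalformedGenotypeError(
                    f"call {call!r} at ({individuals[i]!r}, {loci[j]!r}) "
                    "does not have exactly two allele labels"
                )
            a, b = (code(loci[j], lab) for lab in call)
            calls[i, j] = sorted((a, b))
    return GenotypeMatrix(individuals, loci, calls, allele_labels=tables)
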