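"""Readers and writers for the two standard codominant exchange formats.

GenAlEx codominant CSV
    Three header rows (counts, title, column names with two columns per
    locus), then one row per individual: sample id, population, and the two
    numeric allele codes for each locus.  Missing alleles are ``0``.

STRUCTURE text
    Whitespace-delimited, two rows per individual (one allele copy per
    row), one column per locus after the sample id.  Missing alleles are
    ``-9``.  An optional first row carries the locus names.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FormatError",
    "read_genalex",
    "write_genalex",
    "read_structure",
    "write_structure",
    "read_genotypes",
    "write_genotypes",
]

STRUCTURE_MISSING = -9


class FormatError(ValueError):
    """A genotype file violates its format's layout."""


# ---------------------------------------------------------------- GenAlEx
def write_genalex(g: GenotypeMatrix, path, title: str = "ssrpop export",
                  populations=None) -> None:
    """Write `g` as a GenAlEx codominant CSV (0 = missing)."""
    path = Path(path)
    pops = list(populations) if populations is not None else ["pop1"] * g.n_individuals
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([g.n_loci, g.n_individuals, 1, g.n_individuals])
        w.writerow([title])
        header = ["Sample", "Pop"]
        for locus in g.loci:
            header.extend([locus, ""])
        w.writerow(header)
        for i, ind in enumerate(g.individuals):
            row = [ind, pops[i]]
            for j in range(g.n_loci):
                a, b = g.calls[i, j]
                row.extend([int(a), int(b)])
            w.writerow(row)


def read_genalex(path) -> GenotypeMatrix:
    """Read a GenAlEx codominant CSV into a :class:`GenotypeMatrix`."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise FormatError(f"{path}: expected 3 header rows plus data")
    try:
        n_loci = int(rows[0][0])
        n_samples = int(rows[0][1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed count header: {rows[0]}") from exc
    header = rows[2]
    loci = [header[2 + 2 * j] for j in range(n_loci)]
    data_rows = [r for r in rows[3:] if any(cell.strip() for cell in r)]
    if len(data_rows) != n_samples:
        raise FormatError(
            f"{path}: header declares {n_samples} samples, found {len(data_rows)}"
        )
    individuals = []
    calls = np.zeros((n_samples, n_loci, 2), dtype=np.int64)
    for i, row in enumerate(data_rows):
        if len(row) < 2 + 2 * n_loci:
            raise FormatError(
                f"{path}: row {i + 4} has {len(row)} columns, "
                f"expected {2 + 2 * n_loci}"
            )
        individuals.append(row[0])
        for j in range(n_loci):
            try:
                a = int(row[2 + 2 * j])
                b = int(row[3 + 2 * j])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer allele code in row {i + 4}"
                ) from exc
            calls[i, j] = (a, b)
    return GenotypeMatrix(individuals, loci, calls)


# -------------------------------------------------------------- STRUCTURE
def write_structure(g: GenotypeMatrix, path, header: bool = True) -> None:
    """Write `g` in STRUCTURE two-rows-per-individual format (-9 = missing)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write("\t".join(g.loci) + "\n")
        for i, ind in enumerate(g.individuals):
            for copy in range(2):
                vals = []
                for j in range(g.n_loci):
                    a = int(g.calls[i, j, copy])
                    vals.append(str(STRUCTURE_MISSING if a == MISSING else a))
                fh.write("\t".join([str(ind)] + vals) + "\n")


def read_structure(path) -> GenotypeMatrix:
    """Read a STRUCTURE two-rows-per-individual file."""
    path = Path(path)
    lines = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    # A header row (locus names only) has one fewer column than data rows
    # and non-integer second field.
    loci = None
    first = lines[0]
    if len(first) >= 1 and not _is_int(first[-1]):
        loci = first
        lines = lines[1:]
    if len(lines) % 2 != 0:
        raise FormatError(f"{path}: odd number of genotype rows")
    n_cols = len(lines[0])
    n_loci = n_cols - 1
    if loci is None:
        loci = [f"locus{j + 1}" for j in range(n_loci)]
    elif len(loci) != n_loci:
        raise FormatError(
            f"{path}: header names {len(loci)} loci but rows carry {n_loci}"
        )
    n = len(lines) // 2
    individuals = []
    calls = np.zeros((n, n_loci, 2), dtype=np.int64)
    for i in range(n):
        r1, r2 = lines[2 * i], lines[2 * i + 1]
        if len(r1) != n_cols or len(r2) != n_cols:
            raise FormatError(f"{path}: inconsistent column count near row {2 * i + 1}")
        if r1[0] != r2[0]:
            raise FormatError(
                f"{path}: row pair for individual {i + 1} has mismatched ids "
                f"({r1[0]!r} vs {r2[0]!r})"
            )
        individuals.append(r1[0])
        for j in range(n_loci):
            a, b = int(r1[1 + j]), int(r2[1 + j])
            a = MISSING if a == STRUCTURE_MISSING else a
            b = MISSING if b == STRUCTURE_MISSING else b
            calls[i, j] = (a, b)
    return GenotypeMatrix(individuals, loci, calls)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


# ------------------------------------------------------------- dispatch
_READERS = {"genalex": read_genalex, "structure": read_structure}
_WRITERS = {"genalex": write_genalex, "structure": write_structure}


def read_genotypes(path, fmt: str) -> GenotypeMatrix:
    try:
        return _READERS[fmt](path)
    except KeyError:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_READERS)}")


def write_genotypes(g: GenotypeMatrix, path, fmt: str) -> None:
    try:
        _WRITERS[fmt](g, path)
    except KeyError:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_WRITERS)}")
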