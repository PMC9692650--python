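"""Per-locus diversity parameters for codominant markers.

For each locus with sample allele frequencies ``p_k``:

* ``NA`` — number of distinct alleles observed;
* ``Ho`` — fraction of typed individuals that are heterozygous;
* ``He`` — Hardy-Weinberg expected heterozygosity, ``1 - sum(p_k^2)``;
* ``I``  — Shannon information index, ``-sum(p_k ln p_k)`` (nats);
* ``F``  — fixation index ``(He - Ho)/He = 1 - Ho/He`` (undefined for a
  monomorphic locus).

Loci are classed as highly informative (I > 0.5), moderately informative
(0.25 <= I <= 0.5) or uninformative (I < 0.25), the customary
informativeness thresholds for marker panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, NoDataError

__all__ = [
    "LocusStats",
    "locus_stats",
    "all_locus_stats",
    "classify_informativeness",
    "summarize_loci",
    "biallelic_freq_from_he",
    "shannon_index",
    "expected_heterozygosity",
]

HIGH, MODERATE, UNINFORMATIVE = "high", "moderate", "uninformative"


@dataclass
class LocusStats:
    locus: str
    na: int
    i: float
    ho: float
    he: float
    f: float | None          # None when He == 0 (monomorphic)
    n_typed: int
    informativeness: str


def expected_heterozygosity(freqs: np.ndarray) -> float:
    return float(1.0 - np.sum(np.asarray(freqs) ** 2))


def shannon_index(freqs: np.ndarray) -> float:
    p = np.asarray(freqs, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def classify_informativeness(i: float) -> str:
    """Informativeness class of a locus from its Shannon index.

    Ties at exactly 0.25 and 0.5 fall in the moderate class.
    """
    if i < 0:
        raise ValueError("information index cannot be negative")
    if i > 0.5:
        return HIGH
    if i >= 0.25:
        return MODERATE
    return UNINFORMATIVE


def locus_stats(g: GenotypeMatrix, locus) -> LocusStats:
    """Compute NA, I, Ho, He and F for one locus."""
    j = g.locus_index(locus)
    af = g.allele_frequencies(j)      # raises NoDataError if all missing
    col = g.calls[:, j, :]
    typed = col[:, 0] != 0
    n_typed = int(typed.sum())
    het = col[typed, 0] != col[typed, 1]
    ho = float(het.mean()) if n_typed else 0.0
    he = expected_heterozygosity(af.freqs)
    i = shannon_index(af.freqs)
    f = (he - ho) / he if he > 0 else None
    return LocusStats(
        locus=g.loci[j],
        na=len(af.alleles),
        i=i,
        ho=ho,
        he=he,
        f=f,
        n_typed=n_typed,
        informativeness=classify_informativeness(i),
    )


def all_locus_stats(g: GenotypeMatrix) -> list[LocusStats]:
    return [locus_stats(g, j) for j in range(g.n_loci)]


def summarize_loci(stats: list[LocusStats]) -> dict:
    """Panel-level summary: unweighted means, totals and counts.

    The mean fixation index averages only loci where F is defined
    (polymorphic loci); monomorphic loci are excluded rather than
    counted as zero.
    """
    if not stats:
        raise ValueError("need at least one locus")
    na = np.array([s.na for s in stats], dtype=float)
    i = np.array([s.i for s in stats])
    ho = np.array([s.ho for s in stats])
    he = np.array([s.he for s in stats])
    f_defined = [s.f for s in stats if s.f is not None]
    return {
        "n_loci": len(stats),
        "total_alleles": int(na.sum()),
        "mean_na": float(na.mean()),
        "mean_i": float(i.mean()),
        "mean_ho": float(ho.mean()),
        "mean_he": float(he.mean()),
        "mean_f": float(np.mean(f_defined)) if f_defined else None,
        "n_high_informative": sum(s.i > 0.5 for s in stats),
        "n_ho_gt_he": sum(s.ho > s.he for s in stats),
        "n_f_negative": sum(s.f is not None and s.f < 0 for s in stats),
        "min_na": int(na.min()),
        "max_na": int(na.max()),
    }


def stats_table(stats: list[LocusStats]) -> pd.DataFrame:
    """Per-locus statistics as a DataFrame with a trailing MEAN row."""
    df = pd.DataFrame(
        {
            "locus": [s.locus for s in stats],
            "na": [s.na for s in stats],
            "i": [s.i for s in stats],
            "ho": [s.ho for s in stats],
            "he": [s.he for s in stats],
            "f": [s.f for s in stats],
            "n_typed": [s.n_typed for s in stats],
            "class": [s.informativeness for s in stats],
        }
    )
    summ = summarize_loci(stats)
    mean_row = pd.DataFrame(
        {
            "locus": ["MEAN"],
            "na": [summ["mean_na"]],
            "i": [summ["mean_i"]],
            "ho": [summ["mean_ho"]],
            "he": [summ["mean_he"]],
            "f": [summ["mean_f"]],
            "n_typed": [np.nan],
            "class": [""],
        }
    )
    return pd.concat([df, mean_row], ignore_index=True)


def biallelic_freq_from_he(he: float) -> tuple[float, float]:
    """Invert He = 2p(1-p) for a biallelic locus; returns (p, q), p >= 0.5.

    Useful as an internal-consistency oracle linking a locus's He to the
    Shannon index it implies when only two alleles segregate.
    """
    if not (0.0 < he <= 0.5):
        raise ValueError("biallelic He must lie in (0, 0.5]")
    disc = math.sqrt(1.0 - 2.0 * he)
    p = 0.5 * (1.0 + disc)
    return p, 1.0 - p
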