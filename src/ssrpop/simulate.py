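"""Synthetic diploid SSR genotype populations.

The generator emulates the structure of a clonal coffee germplasm panel:
a few dozen conspecific genotypes carrying 2-5 alleles per locus, excess
heterozygosity (population-mean fixation index near zero), a handful of
clone/full-sib pairs, a few latent ancestry clusters, and one outgroup
individual from a different species that carries private alleles.

Cluster allele frequencies follow the Balding-Nichols F-model: ancestral
frequencies ``p`` are drawn from a symmetric Dirichlet and each cluster's
frequencies from ``Dirichlet(p * (1 - F_ST) / F_ST)``, so F_ST controls
divergence.  Within a cluster, genotypes depart from Hardy-Weinberg
proportions according to F_IS: ``P(hom k) = p_k^2 + F_IS * p_k * (1 - p_k)``
with heterozygote probabilities reduced correspondingly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["SimulationConfig", "ConfigError", "simulate_population", "make_fixture_tables"]

# Per-locus allele-count weights emulating the published 21-locus coffee
# panel (9 loci with 2 alleles, 7 with 3, 3 with 4, 2 with 5; mean 2.90).
_ALLELE_COUNT_WEIGHTS = {2: 9, 3: 7, 4: 3, 5: 2}


class ConfigError(ValueError):
    """An impossible simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population.

    Defaults mirror the study conditions the generator emulates: 45
    individuals (44 conspecific + 1 outgroup), 21 loci with 2-5 alleles,
    three latent ancestry clusters, no inbreeding, a couple of clone and
    sib pairs, and a 2% missing-call rate.
    """

    n_individuals: int = 45
    n_loci: int = 21
    alleles_min: int = 2
    alleles_max: int = 5
    k_true: int = 3
    f_st: float = 0.15
    f_is: float = 0.0
    n_clone_pairs: int = 2
    n_sib_pairs: int = 3
    outgroup: bool = True
    missing_rate: float = 0.02
    seed: int = 2022
    allele_count_weights: dict | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ConfigError("need at least 2 individuals")
        if self.alleles_min < 2 or self.alleles_max < self.alleles_min:
            raise ConfigError("allele range must satisfy 2 <= min <= max")
        if not (0.0 <= self.f_st < 1.0):
            raise ConfigError("f_st must be in [0, 1)")
        if not (-1.0 < self.f_is < 1.0):
            raise ConfigError("f_is must be in (-1, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.k_true < 1:
            raise ConfigError("k_true must be >= 1")
        n_core = self.n_individuals - (1 if self.outgroup else 0)
        if n_core < 1:
            raise ConfigError("no conspecific individuals left")
        if 2 * self.n_clone_pairs + 2 * self.n_sib_pairs > n_core:
            raise ConfigError(
                "clone/sib pairs require more individuals than available"
            )


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated dataset."""

    cluster_labels: np.ndarray          # -1 for the outgroup
    ancestral_freqs: list               # per locus, ancestral allele freqs
    cluster_freqs: list                 # per locus, (K, n_alleles) array
    clone_pairs: list                   # (i, j) index pairs, j copies i
    sib_pairs: list                     # (i, j) full-sib index pairs
    outgroup_index: int | None

    def to_dict(self) -> dict:
        return {
            "cluster_labels": self.cluster_labels.tolist(),
            "ancestral_freqs": [p.tolist() for p in self.ancestral_freqs],
            "cluster_freqs": [p.tolist() for p in self.cluster_freqs],
            "clone_pairs": [list(p) for p in self.clone_pairs],
            "sib_pairs": [list(p) for p in self.sib_pairs],
            "outgroup_index": self.outgroup_index,
        }


def _genotype_probs(p: np.ndarray, f_is: float) -> np.ndarray:
    """Genotype probability matrix under an F_IS departure from HWE.

    Returns an (n_alleles, n_alleles) upper-triangular matrix with
    P(kk) on the diagonal and P(km), k<m, above it.  For negative F_IS
    beyond the feasible range, homozygote probabilities are clipped at 0
    and the matrix renormalised.
    """
    n = len(p)
    probs = np.zeros((n, n))
    diag = p**2 + f_is * p * (1.0 - p)
    np.fill_diagonal(probs, np.clip(diag, 0.0, None))
    for k in range(n):
        for m in range(k + 1, n):
            probs[k, m] = max(2.0 * p[k] * p[m] * (1.0 - f_is), 0.0)
    total = probs.sum()
    if total <= 0:
        raise ConfigError("degenerate genotype distribution")
    return probs / total


def _draw_genotype(rng, p: np.ndarray, f_is: float) -> tuple[int, int]:
    """Draw one diploid genotype (1-based allele codes) at frequencies p."""
    if f_is == 0.0:
        a, b = rng.choice(len(p), size=2, p=p) + 1
    elif f_is > 0.0:
        a = rng.choice(len(p), p=p) + 1
        b = a if rng.random() < f_is else int(rng.choice(len(p), p=p)) + 1
    else:
        probs = _genotype_probs(p, f_is)
        flat = rng.choice(probs.size, p=probs.ravel())
        a, b = divmod(flat, probs.shape[1])
        a, b = a + 1, b + 1
    return (min(a, b), max(a, b))


def _mendelian_child(rng, parent1, parent2) -> tuple[int, int]:
    a = parent1[rng.integers(2)]
    b = parent2[rng.integers(2)]
    return (min(a, b), max(a, b))


def simulate_population(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Simulate a diploid codominant genotype matrix plus its ground truth.

    Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    L = cfg.n_loci
    K = cfg.k_true
    outgroup_idx = n - 1 if cfg.outgroup else None
    n_core = n - (1 if cfg.outgroup else 0)

    # per-locus allele counts
    weights = cfg.allele_count_weights or {
        a: _ALLELE_COUNT_WEIGHTS.get(a, 1)
        for a in range(cfg.alleles_min, cfg.alleles_max + 1)
    }
    sizes = np.array(sorted(weights))
    wvec = np.array([weights[s] for s in sizes], dtype=float)
    n_alleles = rng.choice(sizes, size=L, p=wvec / wvec.sum())

    ancestral, cluster_freqs = [], []
    for j in range(L):
        # require two common alleles per locus so each locus stays
        # polymorphic at panel-scale sample sizes; rarer extra alleles
        # are allowed, as in real SSR panels
        p_anc = rng.dirichlet(np.ones(n_alleles[j]))
        while np.sort(p_anc)[-2] < 0.08:
            p_anc = rng.dirichlet(np.ones(n_alleles[j]))
        ancestral.append(p_anc)
        if cfg.f_st > 0.0:
            conc = p_anc * (1.0 - cfg.f_st) / cfg.f_st
            pk = np.vstack([rng.dirichlet(np.clip(conc, 1e-6, None)) for _ in range(K)])
        else:
            pk = np.tile(p_anc, (K, 1))
        cluster_freqs.append(pk)

    labels = np.full(n, -1, dtype=np.int64)
    labels[:n_core] = np.arange(n_core) % K
    rng.shuffle(labels[:n_core])

    calls = np.zeros((n, L, 2), dtype=np.int64)
    for i in range(n_core):
        k = labels[i]
        for j in range(L):
            calls[i, j] = _draw_genotype(rng, cluster_freqs[j][k], cfg.f_is)

    # clone pairs: the second member becomes an exact copy of the first
    core = list(rng.permutation(n_core))
    clone_pairs, sib_pairs = [], []
    for _ in range(cfg.n_clone_pairs):
        i, j = int(core.pop()), int(core.pop())
        calls[j] = calls[i]
        labels[j] = labels[i]
        clone_pairs.append((min(i, j), max(i, j)))
    # sib pairs: Mendelian full siblings of two simulated cluster parents
    for _ in range(cfg.n_sib_pairs):
        i, j = int(core.pop()), int(core.pop())
        k = labels[i]
        labels[j] = k
        for jl in range(L):
            par1 = _draw_genotype(rng, cluster_freqs[jl][k], cfg.f_is)
            par2 = _draw_genotype(rng, cluster_freqs[jl][k], cfg.f_is)
            calls[i, jl] = _mendelian_child(rng, par1, par2)
            calls[j, jl] = _mendelian_child(rng, par1, par2)
        sib_pairs.append((min(i, j), max(i, j)))

    # outgroup: homozygous for a private allele at ~half the loci
    if outgroup_idx is not None:
        for j in range(L):
            if rng.random() < 0.5:
                private = n_alleles[j] + 1
                calls[outgroup_idx, j] = (private, private)
            else:
                calls[outgroup_idx, j] = _draw_genotype(rng, ancestral[j], 0.0)

    if cfg.missing_rate > 0.0:
        mask = rng.random((n, L)) < cfg.missing_rate
        # keep every locus typed somewhere
        for j in range(L):
            if mask[:, j].all():
                mask[rng.integers(n), j] = False
        calls[mask] = MISSING

    individuals = [f"G{i + 1:02d}" for i in range(n)]
    if outgroup_idx is not None:
        individuals[outgroup_idx] = "Outgroup"
    loci = [f"SSR{j + 1:02d}" for j in range(L)]
    g = GenotypeMatrix(individuals, loci, calls)
    truth = SimulationTruth(
        cluster_labels=labels,
        ancestral_freqs=ancestral,
        cluster_freqs=cluster_freqs,
        clone_pairs=clone_pairs,
        sib_pairs=sib_pairs,
        outgroup_index=outgroup_idx,
    )
    return g, truth


def make_fixture_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged coffee-panel metadata tables.

    Returns a dict with:

    ``genotypes``
        the 45 sample numbers and genotype names of the panel;
    ``yield``
        per-genotype mean yield (liter/bag) and productivity (bag/ha),
        with the UPGMA group reported for the panel (missing where no
        field data exist);
    ``locus_stats``
        the published per-locus diversity values (NA, I, Ho, He, F) for
        the 21-locus panel, used as a cross-check fixture.
    """
    base = importlib.resources.files("ssrpop") / "data"
    return {
        "genotypes": pd.read_csv(base / "coffee_panel_genotypes.csv"),
        "yield": pd.read_csv(base / "coffee_panel_yield.csv"),
        "locus_stats": pd.read_csv(base / "coffee_panel_locus_stats.csv"),
    }
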