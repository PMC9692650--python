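"""End-to-end orchestration: simulate/read -> diversity -> distance ->
kinship -> admixture, with a combined report.

A run is driven by a :class:`PipelineConfig` (loadable from YAML).  Every
artifact is a TSV/newick/JSON file in the output directory, stamped with
the config hash and seeds so reruns are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.special import comb

from . import admixture, distance, diversity, kinship
from .genotypes import GenotypeMatrix
from .io import read_genotypes, write_genalex, write_structure
from .simulate import SimulationConfig, simulate_population

__all__ = ["PipelineConfig", "SimulateSection", "run_pipeline",
           "cross_tabulate_groups", "adjusted_rand_index"]


class SimulateSection(BaseModel):
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

    def to_config(self) -> SimulationConfig:
        return SimulationConfig(**self.model_dump())


class StageToggles(BaseModel):
    diversity: bool = True
    distance: bool = True
    kinship: bool = True
    structure: bool = True


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-round-trippable)."""

    input_path: str | None = None
    input_format: str = "genalex"
    simulate: SimulateSection | None = Field(default_factory=SimulateSection)
    stages: StageToggles = Field(default_factory=StageToggles)
    distance_index: str = "auto"          # weighted|unweighted|smouse-peakall|auto
    mojena_k: float = 1.25
    kinship_bins: list[float] = Field(
        default_factory=lambda: [-np.inf, 0.0, 0.1, 0.3, 0.5, np.inf]
    )
    k_min: int = 1
    k_max: int = 6
    n_replicates: int = 10
    burn_in: int = 2000
    n_iter: int = 10000
    adherence_threshold: float = 0.70
    rep_run_rule: str = "highest"
    seed: int = 2022
    out_dir: str = "ssrpop_out"

    @model_validator(mode="after")
    def _check(self):
        if self.input_path is None and self.simulate is None:
            raise ValueError("provide either input_path or a simulate section")
        if self.input_format not in ("genalex", "structure"):
            raise ValueError("input_format must be genalex or structure")
        if self.distance_index not in ("auto",) + distance.INDEX_ORDER:
            raise ValueError(f"unknown distance index {self.distance_index!r}")
        if self.rep_run_rule not in ("highest", "lowest"):
            raise ValueError("rep_run_rule must be 'highest' or 'lowest'")
        if not (0.0 < self.adherence_threshold <= 1.0):
            raise ValueError("adherence_threshold must be in (0, 1]")
        return self

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self) -> str:
        data = self.model_dump()
        data["kinship_bins"] = [
            None if not np.isfinite(b) else float(b) for b in data["kinship_bins"]
        ]
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text)
        if "kinship_bins" in (data or {}):
            bins = data["kinship_bins"]
            fixed = []
            for pos, b in enumerate(bins):
                if b is None:
                    fixed.append(-np.inf if pos == 0 else np.inf)
                else:
                    fixed.append(float(b))
            data["kinship_bins"] = fixed
        return cls(**(data or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    a = pd.Categorical(list(map(str, labels_a)))
    b = pd.Categorical(list(map(str, labels_b)))
    ct = pd.crosstab(a, b).to_numpy()
    n = ct.sum()
    sum_cells = comb(ct, 2).sum()
    sum_rows = comb(ct.sum(axis=1), 2).sum()
    sum_cols = comb(ct.sum(axis=0), 2).sum()
    expected = sum_rows * sum_cols / comb(n, 2)
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0 if sum_cells == max_index else 0.0
    return float((sum_cells - expected) / (max_index - expected))


def cross_tabulate_groups(upgma_groups, admixture_labels, individuals=None):
    """Contingency table of UPGMA groups vs admixture clusters.

    Returns ``(table, adjusted_rand)``.  Both label sequences must cover
    the same individuals in the same order.
    """
    if len(upgma_groups) != len(admixture_labels):
        raise ValueError(
            f"partition sizes differ: {len(upgma_groups)} vs {len(admixture_labels)}"
        )
    idx = individuals if individuals is not None else range(len(upgma_groups))
    df = pd.DataFrame(
        {"upgma": list(upgma_groups), "bayes": list(admixture_labels)}, index=list(idx)
    )
    table = pd.crosstab(df["upgma"], df["bayes"])
    return table, adjusted_rand_index(upgma_groups, admixture_labels)


def _tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and write the report bundle.

    Returns a dict with the in-memory results keyed by stage; artifacts
    land under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    bundle: dict = {"config": cfg, "stamp": stamp}
    report: list[str] = [
        "# ssrpop pipeline report",
        "",
        f"config hash: `{stamp['config_hash']}`  |  seed: {cfg.seed}",
        "",
    ]
    caught: list[str] = []

    # ---- input ----------------------------------------------------------
    if cfg.input_path is not None:
        g = read_genotypes(cfg.input_path, cfg.input_format)
        report.append(f"Input: `{cfg.input_path}` ({cfg.input_format}), "
                      f"{g.n_individuals} individuals x {g.n_loci} loci.")
    else:
        sim_cfg = cfg.simulate.to_config()
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            g, truth = simulate_population(sim_cfg)
        caught += [str(w.message) for w in wlist]
        write_genalex(g, out / "genotypes_genalex.csv")
        write_structure(g, out / "genotypes_structure.txt")
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
        bundle["truth"] = truth
        report.append(
            f"Simulated population (seed {sim_cfg.seed}): {g.n_individuals} "
            f"individuals x {g.n_loci} loci, K_true={sim_cfg.k_true}, "
            f"F_ST={sim_cfg.f_st}, F_IS={sim_cfg.f_is}."
        )
    bundle["genotypes"] = g
    (out / "run_stamp.json").write_text(json.dumps(stamp, indent=1))
    (out / "config.yaml").write_text(cfg.to_yaml())

    # ---- diversity ------------------------------------------------------
    if cfg.stages.diversity:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            stats = diversity.all_locus_stats(g)
        caught += [str(w.message) for w in wlist]
        table = diversity.stats_table(stats)
        _tsv(table, out / "diversity.tsv")
        summ = diversity.summarize_loci(stats)
        bundle["diversity"] = {"stats": stats, "summary": summ}
        report += [
            "", "## Diversity", "",
            f"{summ['n_loci']} loci, {summ['total_alleles']} alleles "
            f"(NA {summ['min_na']}-{summ['max_na']}, mean {summ['mean_na']:.3f}).",
            f"Mean I={summ['mean_i']:.3f}, Ho={summ['mean_ho']:.3f}, "
            f"He={summ['mean_he']:.3f}, F={summ['mean_f']:.3f}."
            if summ["mean_f"] is not None else
            f"Mean I={summ['mean_i']:.3f} (F undefined everywhere).",
            f"{summ['n_high_informative']} loci highly informative (I > 0.5); "
            f"{summ['n_f_negative']} loci with F < 0.",
        ]

    # ---- distance / clustering -----------------------------------------
    if cfg.stages.distance:
        if cfg.distance_index == "auto":
            dres, r_c_table = distance.select_index_by_cophenetic(
                g, mojena_k=cfg.mojena_k
            )
            _tsv(
                pd.DataFrame(
                    {"index": list(r_c_table), "r_c": list(r_c_table.values())}
                ),
                out / "cophenetic_selection.tsv",
            )
        else:
            dres = distance.analyze_distance(g, cfg.distance_index, cfg.mojena_k)
        bundle["distance"] = dres
        _tsv(
            pd.DataFrame(dres.d, index=g.individuals, columns=g.individuals),
            out / "distance_matrix.tsv", index=True,
        )
        (out / "tree.nwk").write_text(
            distance.to_newick(dres.linkage, g.individuals) + "\n"
        )
        _tsv(
            pd.DataFrame({"individual": g.individuals, "group": dres.groups}),
            out / "upgma_groups.tsv",
        )
        report += [
            "", "## Distance / UPGMA", "",
            f"Index: {dres.index}; cophenetic correlation r_c = {dres.r_c:.3f}.",
            f"Mojena cut (k={cfg.mojena_k}) yields {dres.n_groups()} groups.",
        ]

    # ---- kinship --------------------------------------------------------
    if cfg.stages.kinship:
        km = kinship.kinship_matrix(g)
        hist = kinship.kinship_histogram(km, bins=tuple(cfg.kinship_bins))
        bundle["kinship"] = {"matrix": km, "histogram": hist}
        _tsv(km.to_frame(), out / "kinship_matrix.tsv", index=True)
        _tsv(hist, out / "kinship_histogram.tsv")
        top = hist.iloc[-2:]["fraction"].sum()
        report += [
            "", "## Kinship", "",
            f"Mean pairwise Loiselle kinship {np.nanmean(km.upper_triangle()):.4f}; "
            f"{top:.1%} of pairs at 0.3 or above.",
        ]

    # ---- admixture ------------------------------------------------------
    if cfg.stages.structure:
        camp = admixture.run_campaign(
            g,
            k_range=range(cfg.k_min, cfg.k_max + 1),
            n_replicates=cfg.n_replicates,
            burn_in=cfg.burn_in,
            n_iter=cfg.n_iter,
            seed=cfg.seed,
            rep_run_rule=cfg.rep_run_rule,
        )
        bundle["admixture"] = camp
        _tsv(camp.evanno, out / "evanno.tsv")
        rep = camp.representative
        _tsv(rep.q_frame(), out / f"q_K{camp.selected_k}.tsv", index=True)
        labels = camp.assign_groups(cfg.adherence_threshold)
        _tsv(
            pd.DataFrame({"individual": g.individuals, "cluster": labels}),
            out / "admixture_assignments.tsv",
        )
        try:
            ax = rep.plot_q(threshold=cfg.adherence_threshold)
            ax.figure.savefig(out / "q_barplot.png", dpi=150,
                              bbox_inches="tight")
            import matplotlib.pyplot as plt

            plt.close(ax.figure)
        except Exception as exc:          # plotting must never sink a run
            caught.append(f"Q plot failed: {exc}")
        n_admixed = sum(1 for x in labels if x == admixture.ADMIXED)
        report += [
            "", "## Bayesian admixture", "",
            f"Evanno Δk selects K = {camp.selected_k} "
            f"({cfg.n_replicates} replicates, K {cfg.k_min}..{cfg.k_max}, "
            f"{cfg.n_iter} sweeps, burn-in {cfg.burn_in}).",
            f"{n_admixed} individual(s) below the "
            f"{cfg.adherence_threshold:.0%} adherence threshold (admixed).",
        ]

    # ---- cross-tabulation ----------------------------------------------
    if cfg.stages.distance and cfg.stages.structure:
        table, ari = cross_tabulate_groups(
            bundle["distance"].groups, labels, g.individuals
        )
        bundle["cross_tab"] = {"table": table, "ari": ari}
        _tsv(table.reset_index(), out / "groups_vs_clusters.tsv")
        report += [
            "", "## UPGMA groups vs Bayesian clusters", "",
            f"Adjusted Rand index: {ari:.3f}.", "",
            table.to_string(),
        ]

    if caught:
        report += ["", "## Warnings", ""] + [f"- {m}" for m in sorted(set(caught))]
    (out / "report.md").write_text("\n".join(report) + "\n")
    bundle["report_path"] = out / "report.md"
    return bundle
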