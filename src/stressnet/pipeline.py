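"""Pipeline orchestration: staged execution with on-disk artifacts.

The full procedure — per-study differential-expression selection,
cross-study intersection, pooled quantile discretization, condition
appending, ensemble structure learning, grouped arc weighting, final arc
selection, and Markov-blanket / community analysis — runs as a chain of
stages. Every stage reads its inputs from, and writes its artifact into, a
run directory, so each is independently invokable (the CLI exposes one
subcommand per stage) and the whole chain is reproducible from the master
seed. A JSON manifest records the configuration, its hash, derived seeds,
and every ambiguity resolution actually applied (significance cutoff,
consensus combination rule, tie handling).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as snio
from ._seeds import derive_seed
from .datasets import CONDITION_VAR
from .consensus import group_and_weight, run_ensemble, select_arcs
from .deselect import filter_low_counts, fit_moderated_t, intersect_gene_lists, log_cpm, top_genes
from .discretize import append_condition, build_discrete_dataset
from .errors import ConfigError, StageError, StressnetError
from .network_analysis import condition_community, girvan_newman, markov_blanket
from .structure import SearchConfig
from .synthetic import TwoStudyDesign, simulate_two_study_counts

log = logging.getLogger(__name__)

STAGES = ["simulate", "deselect", "discretize", "learn", "consensus", "analyze"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, JSON-serializable.

    Defaults mirror the study-scale procedure where stated (3 expression
    bins, top 100 networks, arc threshold at half the group size) at sizes
    a desk run can afford.
    """

    # synthetic input (used when no input paths are given)
    n_genes: int = 2000
    n_de_genes: int = 20
    n_samples_per_group: tuple = ((12, 13), (12, 13))
    log2_fold_change: float = 4.0
    nb_dispersion: float = 0.05
    # deselect
    min_cpm: float = 0.5
    min_samples: int = 2
    prior_count: float = 0.5
    alpha: float = 0.05
    max_n: int | None = None
    # discretize
    n_bins: int = 3
    # search
    n_proposals: int = 100_000
    top_n: int = 100
    ess: float = 1.0
    initial_temperature: float = 1e4
    cooling_factor: float = 0.9
    # shorter cooling levels than the search default so a scaled 1e5-proposal
    # run ends cold (a study-scale run is cold long before it finishes)
    proposals_per_level: int = 1000
    reanneal_after: int = 5000
    max_parents: int | None = None
    # ensemble
    n_runs: int = 50
    group_size: int = 5
    threshold: float | None = None  # default: group_size / 2
    rule: str = "mean"
    min_groups: int | None = None
    majority_fraction: float = 0.5
    # analysis
    target: str = CONDITION_VAR
    # seeds / inputs
    master_seed: int = 0
    input_counts: tuple | None = None  # ((counts, sidecar), (counts, sidecar))

    def search_config(self, seed: int = 0) -> SearchConfig:
        return SearchConfig(
            n_proposals=self.n_proposals,
            top_n=self.top_n,
            ess=self.ess,
            initial_temperature=self.initial_temperature,
            cooling_factor=self.cooling_factor,
            proposals_per_level=self.proposals_per_level,
            reanneal_after=self.reanneal_after,
            max_parents=self.max_parents,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "n_samples_per_group" in d:
            d["n_samples_per_group"] = tuple(tuple(g) for g in d["n_samples_per_group"])
        if d.get("input_counts") is not None:
            d["input_counts"] = tuple(tuple(p) for p in d["input_counts"])
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            d = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(cfg: PipelineConfig, outdir: Path):
            try:
                return fn(cfg, Path(outdir))
            except StressnetError:
                raise
            except Exception as e:  # surface with the stage name
                raise StageError(name, str(e)) from e
        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    """Generate the two synthetic studies (skipped when inputs are given)."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = derive_seed(cfg.master_seed, "simulate")
    genes = TwoStudyDesign(n_genes=cfg.n_genes).gene_ids()
    design = TwoStudyDesign(
        n_genes=cfg.n_genes,
        n_samples_per_group=cfg.n_samples_per_group,
        de_gene_ids=frozenset(genes[: cfg.n_de_genes]),
        log2_fold_change=cfg.log2_fold_change,
        nb_dispersion=cfg.nb_dispersion,
        seed=seed,
    )
    a, b, truth = simulate_two_study_counts(design)
    snio.write_count_matrix(a, outdir / "study0_counts.tsv", outdir / "study0_samples.tsv")
    snio.write_count_matrix(b, outdir / "study1_counts.tsv", outdir / "study1_samples.tsv")
    snio.write_gene_list(sorted(truth), outdir / "truth_genes.txt")
    return {"artifacts": ["study0_counts.tsv", "study0_samples.tsv",
                          "study1_counts.tsv", "study1_samples.tsv", "truth_genes.txt"],
            "seed": seed}


def _load_studies(cfg: PipelineConfig, outdir: Path):
    if cfg.input_counts is not None:
        return [snio.read_count_matrix(c, s) for c, s in cfg.input_counts]
    return [
        snio.read_count_matrix(outdir / f"study{i}_counts.tsv", outdir / f"study{i}_samples.tsv")
        for i in (0, 1)
    ]


@_stage("deselect")
def stage_deselect(cfg: PipelineConfig, outdir: Path) -> dict:
    """Per-study DE statistics, top-gene lists, and their intersection."""
    studies = _load_studies(cfg, outdir)
    lists = []
    for i, cm in enumerate(studies):
        filt = filter_low_counts(cm, cfg.min_cpm, cfg.min_samples)
        logmat = log_cpm(filt, cfg.prior_count)
        stats = fit_moderated_t(logmat, filt.condition.to_numpy())
        stats.to_csv(outdir / f"stats_study{i}.tsv", sep="\t", index_label="gene")
        genes = top_genes(stats, cfg.alpha, cfg.max_n)
        snio.write_gene_list(genes, outdir / f"genes_study{i}.txt")
        lists.append(genes)
        log.info("study %d: %d genes at BH alpha=%g", i, len(genes), cfg.alpha)
    shared = intersect_gene_lists(lists[0], lists[1])
    snio.write_gene_list(shared, outdir / "shared_genes.txt")
    log.info("shared genes: %d (alpha=%g, max_n=%s)", len(shared), cfg.alpha, cfg.max_n)
    return {
        "artifacts": [f"stats_study{i}.tsv" for i in (0, 1)]
        + [f"genes_study{i}.txt" for i in (0, 1)] + ["shared_genes.txt"],
        "n_shared": len(shared),
        "alpha": cfg.alpha,
    }


@_stage("discretize")
def stage_discretize(cfg: PipelineConfig, outdir: Path) -> dict:
    """Pooled tertile discretization of the shared genes plus condition."""
    studies = _load_studies(cfg, outdir)
    shared = snio.read_gene_list(outdir / "shared_genes.txt")
    if len(shared) < 1:
        raise StageError("discretize", "no shared genes to discretize")
    logmats, conds = [], []
    for cm in studies:
        filt = filter_low_counts(cm, cfg.min_cpm, cfg.min_samples)
        logmats.append(log_cpm(filt, cfg.prior_count))
        conds.append(filt.condition)
    ds = build_discrete_dataset(logmats, shared, cfg.n_bins)
    labels = pd.concat(conds).reindex(ds.data.columns)
    ds = append_condition(ds, labels.to_numpy())
    snio.write_discrete_dataset(ds, outdir / "discrete.tsv", outdir / "discrete.json")
    return {"artifacts": ["discrete.tsv", "discrete.json"],
            "n_variables": len(ds.variables), "n_samples": ds.n_samples}


@_stage("learn")
def stage_learn(cfg: PipelineConfig, outdir: Path) -> dict:
    """Ensemble of annealed searches, one consensus network per run."""
    ds = snio.read_discrete_dataset(outdir / "discrete.tsv", outdir / "discrete.json")
    seed = derive_seed(cfg.master_seed, "learn")
    nets = run_ensemble(
        ds, cfg.search_config(), cfg.n_runs, seed, cfg.majority_fraction
    )
    rows = [
        {"run": i, "parent": u, "child": v, "confidence": d["confidence"]}
        for i, g in enumerate(nets)
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["run", "parent", "child", "confidence"]).to_csv(
        outdir / "ensemble_networks.tsv", sep="\t", index=False
    )
    return {"artifacts": ["ensemble_networks.tsv"], "seed": seed, "n_runs": cfg.n_runs}


@_stage("consensus")
def stage_consensus(cfg: PipelineConfig, outdir: Path) -> dict:
    """Group the ensemble, weight arcs, select the final network."""
    import networkx as nx

    ds = snio.read_discrete_dataset(outdir / "discrete.tsv", outdir / "discrete.json")
    df = pd.read_csv(outdir / "ensemble_networks.tsv", sep="\t")
    nets = []
    for i in range(cfg.n_runs):
        g = nx.DiGraph()
        g.add_nodes_from(ds.variables)
        for _, r in df[df["run"] == i].iterrows():
            g.add_edge(str(r["parent"]), str(r["child"]))
        nets.append(g)
    matrices = group_and_weight(nets, cfg.group_size)
    snio.write_weight_matrices(matrices, outdir / "weight_matrices.tsv")
    thr = cfg.threshold if cfg.threshold is not None else cfg.group_size / 2
    final = select_arcs(matrices, thr, variables=ds.variables,
                        rule=cfg.rule, min_groups=cfg.min_groups)
    snio.write_final_network(
        final, outdir / "final_network.tsv", outdir / "final_network.graphml",
        outdir / "isolated_nodes.txt",
    )
    log.info("consensus rule=%s threshold=%g: %d arcs, %d isolated",
             cfg.rule, thr, final.graph.number_of_edges(), len(final.isolated))
    return {
        "artifacts": ["weight_matrices.tsv", "final_network.tsv",
                      "final_network.graphml", "isolated_nodes.txt"],
        "rule": cfg.rule, "threshold": thr,
        "n_arcs": final.graph.number_of_edges(),
        "isolated": final.isolated,
    }


@_stage("analyze")
def stage_analyze(cfg: PipelineConfig, outdir: Path) -> dict:
    """Markov blanket of the condition and community structure."""
    ds = snio.read_discrete_dataset(outdir / "discrete.tsv", outdir / "discrete.json")
    final = snio.read_final_network(
        outdir / "final_network.tsv", outdir / "isolated_nodes.txt",
        variables=ds.variables,
    )
    g = final.graph
    if cfg.target in g:
        mb = markov_blanket(g, cfg.target)
        blanket = {
            "target": cfg.target,
            "parents": sorted(mb.parents),
            "children": sorted(mb.children),
            "spouses": sorted(mb.spouses),
            "blanket": sorted(mb.blanket),
        }
    else:
        blanket = {"target": cfg.target, "parents": [], "children": [],
                   "spouses": [], "blanket": [], "note": "target isolated"}
    if g.number_of_nodes() > 0:
        part = girvan_newman(g.to_undirected())
        membership = {n: int(c) for n, c in part.membership.items()}
        community = (
            sorted(condition_community(part, cfg.target)) if cfg.target in membership else []
        )
        q = part.modularity
        ncomm = part.n_communities
        dendro = [list(e) for e in part.removal_sequence]
    else:
        membership, community, q, ncomm, dendro = {}, [], 0.0, 0, []
    result = {
        "markov_blanket": blanket,
        "communities": {"membership": membership, "n_communities": ncomm,
                        "modularity": q, "removal_sequence": dendro},
        "condition_community": community,
    }
    (outdir / "analysis.json").write_text(json.dumps(result, indent=1))
    blanket_set = set(blanket["blanket"])
    rows = [
        {"node": n, "community": membership.get(n, -1), "in_blanket": int(n in blanket_set)}
        for n in final.variables
    ]
    pd.DataFrame(rows, columns=["node", "community", "in_blanket"]).to_csv(
        outdir / "node_annotation.tsv", sep="\t", index=False
    )
    return {"artifacts": ["analysis.json", "node_annotation.tsv"],
            "n_communities": ncomm, "modularity": q,
            "blanket_size": len(blanket["blanket"])}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "deselect": stage_deselect,
    "discretize": stage_discretize,
    "learn": stage_learn,
    "consensus": stage_consensus,
    "analyze": stage_analyze,
}


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage in order and write a manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES)
    if cfg.input_counts is not None:
        stages.remove("simulate")
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    for name in stages:
        manifest["stages"][name] = STAGE_FUNCS[name](cfg, outdir)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=list))
    return manifest
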