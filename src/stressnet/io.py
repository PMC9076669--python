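"""Plain-text serialization: TSV / JSON / GraphML round-trips.

Count matrices travel as a TSV (first column gene id, header row sample
ids) plus a sidecar TSV mapping sample id to condition label and study id.
Discrete datasets are a TSV of integer codes plus a JSON header (arities,
state labels, cutpoints). Networks are edge-list TSVs and GraphML.
Malformed files raise :class:`~stressnet.errors.DataError` with the
offending id and line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .consensus import ArcWeightMatrix, FinalNetwork
from .datasets import CountMatrix, DiscreteDataset
from .errors import DataError
from .synthetic import GroundTruthBN

import numpy as np


# ---------------------------------------------------------------- counts

def write_count_matrix(cm: CountMatrix, counts_path, sidecar_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    side = pd.DataFrame(
        {
            "sample": cm.samples,
            "condition": cm.condition.to_numpy(),
            "study": cm.study.to_numpy() if cm.study is not None else "",
        }
    )
    side.to_csv(sidecar_path, sep="\t", index=False)


def read_count_matrix(counts_path, sidecar_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    gene_col = df.columns[0]
    dup = df[gene_col].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(
            f"{counts_path}: duplicate gene id '{df[gene_col].iloc[i]}' at line {i + 2}"
        )
    df = df.set_index(gene_col)
    df.index.name = None
    side = pd.read_csv(sidecar_path, sep="\t", dtype={"sample": str})
    for col in ("sample", "condition"):
        if col not in side.columns:
            raise DataError(f"{sidecar_path}: missing column '{col}'")
    dup = side["sample"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(
            f"{sidecar_path}: duplicate sample id '{side['sample'].iloc[i]}' at line {i + 2}"
        )
    bad = ~side["condition"].isin([0, 1])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(
            f"{sidecar_path}: unknown condition label "
            f"'{side['condition'].iloc[i]}' at line {i + 2}"
        )
    cond = pd.Series(side["condition"].to_numpy(), index=side["sample"])
    study = (
        pd.Series(side["study"].to_numpy(), index=side["sample"])
        if "study" in side.columns
        else None
    )
    missing = [s for s in df.columns if s not in cond.index]
    if missing:
        raise DataError(f"{sidecar_path}: no condition for samples {missing}")
    return CountMatrix(df, cond, study)


# ------------------------------------------------------------- discrete

def write_discrete_dataset(ds: DiscreteDataset, tsv_path, json_path) -> None:
    ds.data.to_csv(tsv_path, sep="\t", index_label="variable")
    header = {
        "arities": ds.arities,
        "labels": ds.labels,
        "cutpoints": ds.cutpoints,
    }
    Path(json_path).write_text(json.dumps(header, indent=1))


def read_discrete_dataset(tsv_path, json_path) -> DiscreteDataset:
    df = pd.read_csv(tsv_path, sep="\t", dtype={0: str})
    var_col = df.columns[0]
    dup = df[var_col].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(
            f"{tsv_path}: duplicate variable '{df[var_col].iloc[i]}' at line {i + 2}"
        )
    df = df.set_index(var_col)
    df.index.name = None
    header = json.loads(Path(json_path).read_text())
    return DiscreteDataset(
        data=df.astype(np.int64),
        arities={k: int(v) for k, v in header["arities"].items()},
        labels=header["labels"],
        cutpoints=header.get("cutpoints", {}),
    )


# ------------------------------------------------------------- networks

def write_edge_list(graph: nx.DiGraph, path, weight_attr: str | None = None) -> None:
    rows = []
    for u, v, d in sorted(graph.edges(data=True)):
        row = {"parent": u, "child": v}
        if weight_attr is not None:
            row[weight_attr] = d.get(weight_attr, "")
        rows.append(row)
    cols = ["parent", "child"] + ([weight_attr] if weight_attr else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_edge_list(path, weight_attr: str | None = None) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for i, row in df.iterrows():
        u, v = str(row["parent"]), str(row["child"])
        if g.has_edge(u, v):
            raise DataError(f"{path}: duplicate arc {u}->{v} at line {i + 2}")
        attrs = {}
        if weight_attr is not None and weight_attr in df.columns:
            attrs[weight_attr] = float(row[weight_attr])
        g.add_edge(u, v, **attrs)
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_final_network(fn: FinalNetwork, edge_path, graphml_path, isolated_path) -> None:
    write_edge_list(fn.graph, edge_path, weight_attr="mean_weight")
    write_graphml(fn.graph, graphml_path)
    Path(isolated_path).write_text("".join(f"{v}\n" for v in fn.isolated))


def read_final_network(edge_path, isolated_path, variables=None) -> FinalNetwork:
    g = read_edge_list(edge_path, weight_attr="mean_weight")
    isolated = [
        line.strip()
        for line in Path(isolated_path).read_text().splitlines()
        if line.strip()
    ]
    roster = list(variables) if variables is not None else sorted(g.nodes()) + isolated
    return FinalNetwork(graph=g, variables=roster, isolated=isolated)


# ------------------------------------------------------- weight matrices

def write_weight_matrices(matrices: list[ArcWeightMatrix], path) -> None:
    rows = [
        {"group": m.group_id, "parent": u, "child": v, "weight": w}
        for m in matrices
        for (u, v), w in sorted(m.weights.items())
    ]
    pd.DataFrame(rows, columns=["group", "parent", "child", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_weight_matrices(path) -> list[ArcWeightMatrix]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for gid, grp in df.groupby("group", sort=True):
        weights = {
            (str(r["parent"]), str(r["child"])): int(r["weight"])
            for _, r in grp.iterrows()
        }
        out.append(ArcWeightMatrix(group_id=int(gid), weights=weights))
    return out


# ------------------------------------------------------------ BN / misc

def write_ground_truth_bn(bn: GroundTruthBN, json_path, edges_path=None) -> None:
    doc = {
        "nodes": bn.nodes,
        "arities": bn.arities,
        "parents": bn.parents,
        "cpts": {v: bn.cpts[v].tolist() for v in bn.nodes},
    }
    Path(json_path).write_text(json.dumps(doc))
    if edges_path is not None:
        write_edge_list(bn.to_dag(), edges_path)


def read_ground_truth_bn(json_path) -> GroundTruthBN:
    doc = json.loads(Path(json_path).read_text())
    return GroundTruthBN(
        nodes=doc["nodes"],
        arities={k: int(v) for k, v in doc["arities"].items()},
        parents=doc["parents"],
        cpts={k: np.asarray(v, dtype=float) for k, v in doc["cpts"].items()},
    )


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
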