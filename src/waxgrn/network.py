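"""Regulatory network assembly, summary, export and planted-truth scoring.

An edge joins two differentially expressed genes when their Pearson
correlation passes the threshold (PCC >= 0.9 by default, inclusive), the
correlation FDR passes (q <= 0.05, inclusive), and at least one of the two
genes is a transcription factor with an enriched binding motif in the other
gene's promoter. Edges are directed TF -> partner; mutual TF-TF binding
yields two directed edges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import CoexpressionResult

__all__ = [
    "RegulatoryNetwork",
    "NetworkSummary",
    "assemble_grn",
    "summarize_network",
    "export_network",
    "import_network",
    "evaluate_recovery",
]


@dataclass
class RegulatoryNetwork:
    """Directed TF -> partner network with coexpression/binding attributes."""

    graph: nx.DiGraph
    thresholds: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d.get("pcc"), d.get("q"), d.get("mr"), d.get("motif"))
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["tf", "target", "pcc", "q", "mr", "motif"])

    def nodes_table(self) -> pd.DataFrame:
        rows = []
        for n, d in sorted(self.graph.nodes(data=True)):
            rows.append(
                (n, d.get("is_tf", False), d.get("fold_change"), d.get("fdr"),
                 d.get("mean_epidermis"), d.get("mean_other"), d.get("pathway", False))
            )
        return pd.DataFrame(
            rows,
            columns=["gene", "is_tf", "fold_change", "fdr",
                     "mean_epidermis", "mean_other", "pathway"],
        )

    def directed_edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def validate(self, de_genes: Optional[Iterable[str]] = None) -> None:
        tfs = {n for n, d in self.graph.nodes(data=True) if d.get("is_tf")}
        for u, v in self.graph.edges():
            if u not in tfs and v not in tfs:
                raise ValueError(f"edge ({u}, {v}) has no TF endpoint")
        if de_genes is not None:
            extra = set(self.graph.nodes()) - set(de_genes)
            if extra:
                raise ValueError(f"nodes outside the DE gene set: {sorted(extra)[:5]}")

    def equals(self, other: "RegulatoryNetwork", rtol: float = 1e-9) -> bool:
        if set(self.graph.nodes()) != set(other.graph.nodes()):
            return False
        if set(self.graph.edges()) != set(other.graph.edges()):
            return False
        for u, v in self.graph.edges():
            a, b = self.graph.edges[u, v], other.graph.edges[u, v]
            for key in ("pcc", "q", "mr"):
                va, vb = a.get(key), b.get(key)
                if va is None or vb is None:
                    if va != vb:
                        return False
                elif not np.isclose(float(va), float(vb), rtol=rtol, equal_nan=True):
                    return False
        return True


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    tf_connections: dict[str, int]  # per pathway gene: distinct TFs wired to it
    tf_out_degree: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "tf_connections": dict(sorted(self.tf_connections.items())),
            "tf_out_degree": dict(sorted(self.tf_out_degree.items())),
        }


def assemble_grn(
    de_genes: Iterable[str],
    coexpression: CoexpressionResult,
    binding_map: pd.DataFrame,
    tf_list: Iterable[str],
    pcc_min: float = 0.9,
    q_max: float = 0.05,
    sign: str = "positive",
    mr_max: Optional[float] = None,
    de_table: Optional[pd.DataFrame] = None,
    pathway_genes: Optional[Iterable[str]] = None,
    all_genes: Optional[Iterable[str]] = None,
) -> RegulatoryNetwork:
    """Assemble the network from DE genes, coexpression and binding evidence.

    Edge rule (boundaries inclusive): both genes differentially expressed;
    PCC >= ``pcc_min`` (or <= -pcc_min for ``sign='negative'``); correlation
    q <= ``q_max``; the TF's enriched motif present in the partner's
    promoter; optionally MR <= ``mr_max``.
    """
    de = set(de_genes)
    tfs = set(tf_list)
    if all_genes is not None:
        unknown_tfs = tfs - set(all_genes)
        if unknown_tfs:
            warnings.warn(f"unknown gene(s) in tf_list: {sorted(unknown_tfs)[:5]}")
    if not de:
        warnings.warn("empty DE gene set: returning an empty network")

    g = nx.DiGraph()
    pcc = coexpression.pcc
    q = coexpression.q
    mr = coexpression.mr

    def _passes(a: str, b: str) -> Optional[dict]:
        if a not in pcc.index or b not in pcc.index:
            return None
        r = float(pcc.loc[a, b])
        if sign == "positive" and r < pcc_min:
            return None
        if sign == "negative" and r > -pcc_min:
            return None
        qv = float(q.loc[a, b])
        if qv > q_max:
            return None
        mv = float(mr.loc[a, b]) if mr is not None else None
        if mr_max is not None and mv is not None and mv > mr_max:
            return None
        return {"pcc": r, "q": qv, "mr": mv}

    for row in binding_map.sort_values(["tf", "target"]).itertuples(index=False):
        tf, target = row.tf, row.target
        if tf not in de or target not in de or tf not in tfs:
            continue
        if not getattr(row, "enriched", True):
            continue
        attrs = _passes(tf, target)
        if attrs is None:
            continue
        attrs["motif"] = row.motif
        g.add_edge(tf, target, **attrs)

    pathway = set(pathway_genes) if pathway_genes is not None else set()
    for node in sorted(g.nodes()):
        g.nodes[node]["is_tf"] = node in tfs
        g.nodes[node]["pathway"] = node in pathway
        if de_table is not None and node in de_table.index:
            rec = de_table.loc[node]
            for key, col in (
                ("fold_change", "fold_change"),
                ("fdr", "fdr"),
                ("mean_epidermis", "mean_epidermis"),
                ("mean_other", "mean_other"),
            ):
                if col in de_table.columns:
                    g.nodes[node][key] = float(rec[col])

    net = RegulatoryNetwork(
        g,
        thresholds={"pcc_min": pcc_min, "q_max": q_max, "sign": sign, "mr_max": mr_max},
    )
    net.validate(de_genes=de if de else None)
    return net


def summarize_network(
    network: RegulatoryNetwork, pathway_gene_list: Iterable[str]
) -> NetworkSummary:
    """Node/edge counts, per-pathway-gene TF connections, per-TF out-degree."""
    g = network.graph
    tfs = {n for n, d in g.nodes(data=True) if d.get("is_tf")}
    tf_connections = {}
    for gene in sorted(set(pathway_gene_list)):
        if gene in g:
            tf_connections[gene] = len({u for u, _ in g.in_edges(gene) if u in tfs})
        else:
            tf_connections[gene] = 0
    out_degree = {tf: g.out_degree(tf) for tf in sorted(tfs) if tf in g}
    return NetworkSummary(network.n_nodes, network.n_edges, tf_connections, out_degree)


def export_network(network: RegulatoryNetwork, outdir: str | Path) -> dict[str, Path]:
    """Write edge TSV, node TSV and GraphML with deterministic ordering."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "nodes": out / "nodes.tsv",
        "graphml": out / "network.graphml",
    }
    edges = network.edges_table().sort_values(["tf", "target"])
    edges.to_csv(paths["edges"], sep="\t", index=False, float_format="%.10g")
    nodes = network.nodes_table().sort_values("gene")
    nodes.to_csv(paths["nodes"], sep="\t", index=False, float_format="%.10g")

    g = nx.DiGraph()
    for n, d in sorted(network.graph.nodes(data=True)):
        g.add_node(n, **{k: v for k, v in sorted(d.items()) if v is not None})
    for u, v, d in sorted(network.graph.edges(data=True)):
        g.add_edge(u, v, **{k: val for k, val in sorted(d.items()) if val is not None})
    nx.write_graphml(g, paths["graphml"])
    return paths


def import_network(graphml_path: str | Path) -> RegulatoryNetwork:
    g = nx.read_graphml(str(graphml_path))
    return RegulatoryNetwork(nx.DiGraph(g))


def evaluate_recovery(
    network: RegulatoryNetwork, true_edges: Iterable[tuple[str, str]]
) -> dict:
    """Precision/recall/F1 of directed TF -> target edges vs planted truth."""
    truth = set(true_edges) if not hasattr(true_edges, "true_edges") else set(true_edges.true_edges)
    predicted = network.directed_edges()
    tp = len(predicted & truth)
    empty_prediction = len(predicted) == 0
    precision = 0.0 if empty_prediction else tp / len(predicted)
    recall = tp / len(truth) if truth else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_predicted": len(predicted),
        "n_true": len(truth),
        "n_correct": tp,
        "empty_prediction": empty_prediction,
    }
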