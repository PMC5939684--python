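"""Time-indexed inverse-expression miRNA-mRNA bipartite networks.

Three networks are built: group-A miRNAs against the DE mRNAs at P15 and
at P17 (the latter capturing the ~2-day lag a miRNA needs to silence its
targets), and group-B miRNAs against the DE mRNAs at P17.  An edge
requires a predicted interaction supported by at least two algorithms, a
retina-detected target gene, and fold changes of opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocessing import DetectionCalls

__all__ = [
    "TargetPredictionTable",
    "InteractionNetwork",
    "read_prediction_table",
    "filter_min_algorithms",
    "build_inverse_network",
    "inverse_gene_set",
    "export_network",
    "read_network_tsv",
]

EDGE_COLUMNS = ["mirna_id", "gene_id", "mirna_signed_fc", "mrna_signed_fc", "algorithm_count"]


@dataclass
class TargetPredictionTable:
    """Predicted miRNA->gene pairs with their supporting algorithm labels.

    ``table`` has columns ``mirna_id``, ``gene_id`` and ``algorithms``
    (a frozenset of labels per row); (miRNA, gene) pairs are unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.duplicated(subset=["mirna_id", "gene_id"]).any():
            raise ValueError("duplicate (mirna_id, gene_id) prediction pairs")
        if self.table["algorithms"].map(len).eq(0).any():
            raise ValueError("every prediction must name at least one algorithm")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["algorithms"] = out["algorithms"].map(lambda s: ";".join(sorted(s)))
        out.to_csv(path, sep="\t", index=False)


def read_prediction_table(path) -> TargetPredictionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["algorithms"] = df["algorithms"].map(lambda s: frozenset(s.split(";")))
    return TargetPredictionTable(df)


def filter_min_algorithms(predictions: TargetPredictionTable, k: int = 2) -> TargetPredictionTable:
    """Keep predictions supported by at least ``k`` algorithms."""
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = predictions.table["algorithms"].map(len) >= k
    return TargetPredictionTable(predictions.table.loc[keep].reset_index(drop=True))


@dataclass
class InteractionNetwork:
    """Bipartite miRNA->gene edge set for one temporal network (A15/A17/B17)."""

    name: str
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.edges.columns) != EDGE_COLUMNS:
            self.edges = self.edges.reindex(columns=EDGE_COLUMNS)
        if len(self.edges):
            if (np.sign(self.edges["mirna_signed_fc"]) * np.sign(self.edges["mrna_signed_fc"]) != -1).any():
                raise ValueError("every edge must connect oppositely regulated partners")

    @property
    def mirna_nodes(self) -> set[str]:
        return set(self.edges["mirna_id"])

    @property
    def gene_nodes(self) -> set[str]:
        return set(self.edges["gene_id"])


def build_inverse_network(
    name: str,
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    predictions: TargetPredictionTable,
    detection: DetectionCalls,
) -> InteractionNetwork:
    """Intersect predictions with DE tables under the inverse-expression rule.

    ``mirna_de`` holds the filter-passing miRNAs of the network's group
    (fold change anchored at the group-defining vs-WT comparison) and
    ``mrna_de`` the filter-passing mRNAs at the network's timepoint.  An
    edge (m, g) is kept iff the pair is predicted, m and g are in their DE
    tables, g was detected in at least one array, and the fold-change
    signs are opposite.
    """
    mirna_fc = dict(zip(mirna_de["feature_id"], mirna_de["signed_fc"]))
    mrna_fc = dict(zip(mrna_de["feature_id"], mrna_de["signed_fc"]))
    detected = set(detection.calls.index[detection.calls.any(axis=1)])
    unknown = set(mrna_fc) - set(detection.calls.index)
    if unknown:
        raise ValueError(f"mRNA ids missing from detection table: {sorted(unknown)[:5]}")
    rows = []
    for m, g, algos in predictions.table.itertuples(index=False):
        if m not in mirna_fc or g not in mrna_fc or g not in detected:
            continue
        fm, fg = mirna_fc[m], mrna_fc[g]
        if np.sign(fm) * np.sign(fg) == -1:
            rows.append((m, g, fm, fg, len(algos)))
    return InteractionNetwork(name, pd.DataFrame(rows, columns=EDGE_COLUMNS))


def inverse_gene_set(networks: list[InteractionNetwork]) -> set[str]:
    """Union of inversely expressed target genes across networks."""
    out: set[str] = set()
    for net in networks:
        out |= net.gene_nodes
    return out


def _to_graph(network: InteractionNetwork) -> nx.DiGraph:
    g = nx.DiGraph(name=network.name)
    for m, gene, fm, fg, k in network.edges.itertuples(index=False):
        g.add_node(m, node_type="mirna")
        g.add_node(gene, node_type="gene")
        g.add_edge(m, gene, mirna_signed_fc=float(fm), mrna_signed_fc=float(fg), algorithm_count=int(k))
    return g


def export_network(network: InteractionNetwork, fmt: str, path) -> None:
    """Write a network as SIF (``mirna targets gene``), GraphML or TSV."""
    path = Path(path)
    if fmt == "sif":
        lines = [f"{m}\ttargets\t{g}" for m, g in zip(network.edges["mirna_id"], network.edges["gene_id"])]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(_to_graph(network), path)
    elif fmt == "tsv":
        network.edges.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}; use sif, graphml or tsv")


def read_network_tsv(name: str, path) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t")
    return InteractionNetwork(name, df)
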