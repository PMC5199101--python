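"""Gene-gene functional-interaction subnetwork over DE genes.

The induced subnetwork on the differentially expressed genes is scored with
two centrality indicators: degree (number of directly linked genes) and
betweenness centrality (fraction of all-pairs shortest paths passing through
a gene, normalized by 2/((N-1)(N-2)) on an N-node network).  Core genes are
the records at or above a betweenness threshold, both indicators reported.
Edge types and directions are metadata only; all path computations treat the
network as untyped and undirected.
"""

from __future__ import annotations

import logging
from typing import Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "build_subnetwork",
    "degree_centrality",
    "betweenness_centrality",
    "centrality_table",
    "select_core_genes",
]

logger = logging.getLogger(__name__)


def build_subnetwork(graph: nx.Graph, de_directions: Mapping[str, str]) -> nx.Graph:
    """Induced subgraph on the DE genes, keeping isolated nodes.

    ``de_directions`` maps gene symbol -> ``up``/``down``.  DE genes absent
    from the interaction graph are retained as isolated (degree 0) nodes and
    logged.  Raises if no DE gene appears in the graph at all.
    """
    de_genes = set(de_directions)
    present = de_genes & set(graph.nodes)
    if not present:
        raise ValueError(
            "no DE gene occurs in the interaction graph; check that gene "
            "symbols in the DE table and the edge file use the same namespace"
        )
    sub = graph.subgraph(present).copy()
    absent = sorted(de_genes - present)
    if absent:
        logger.info("build_subnetwork: %d DE genes absent from the graph kept isolated", len(absent))
        sub.add_nodes_from(absent)
    nx.set_node_attributes(sub, dict(de_directions), name="direction")
    return sub


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Number of distinct neighbors per gene (undirected, no self-loops)."""
    return {node: int(deg) for node, deg in graph.degree()}


def betweenness_centrality(graph: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness per gene.

    Each unordered pair (s, t) contributes the fraction of its shortest paths
    passing through the gene; unreachable pairs contribute nothing.  With
    ``normalized`` the score is divided by the number of pairs
    (N-1)(N-2)/2, mapping it into [0, 1]; otherwise raw pair sums are
    returned.
    """
    return {
        node: float(v)
        for node, v in nx.betweenness_centrality(graph, normalized=normalized).items()
    }


def centrality_table(graph: nx.Graph, normalized: bool = True) -> pd.DataFrame:
    """Per-gene centrality records: gene, style (up/down), degree, betweenness."""
    deg = degree_centrality(graph)
    btw = betweenness_centrality(graph, normalized=normalized)
    rows = [
        {
            "gene": node,
            "style": graph.nodes[node].get("direction", "unmeasured"),
            "degree": deg[node],
            "betweenness": btw[node],
        }
        for node in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["gene", "style", "degree", "betweenness"])


def select_core_genes(records: pd.DataFrame, bc_threshold: float = 0.005) -> pd.DataFrame:
    """Core genes: betweenness >= threshold (inclusive), ranked.

    Sort order: betweenness descending, ties by degree descending, then gene
    id; both indicators are kept in the output.
    """
    if records.empty:
        return records.copy()
    kept = records[records["betweenness"] >= bc_threshold].copy()
    kept = kept.sort_values(
        ["betweenness", "degree", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return kept
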