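"""Per-group lncRNA-mRNA co-expression networks and degree-difference core genes.

Within each sample group (tumor, normal) every pair of transcripts —
mRNA-lncRNA, mRNA-mRNA, lncRNA-lncRNA — is correlated (Pearson, over that
group's samples) and pairs with |r| at or above the cutoff (default 0.92)
become network edges, keeping the sign of r as an attribute.  Because the
disease can rewire co-expression without changing mean levels, core genes
are ranked by the difference of their degrees between the two group
networks.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ProbeAnnotation

__all__ = [
    "build_correlation_network",
    "degree_difference_core",
    "pair_report",
]

logger = logging.getLogger(__name__)


def build_correlation_network(
    matrix: ExpressionMatrix,
    biotype_of: dict[str, str],
    group: str,
    cutoff: float = 0.92,
) -> nx.Graph:
    """Co-expression network for one group at a |r| cutoff (inclusive).

    ``matrix`` must be gene-level (see :func:`lncnet.io.collapse_to_genes`);
    ``biotype_of`` maps gene -> biotype, and only lncRNA/mRNA features enter
    the network.  Every node carries its biotype; every edge carries ``r``
    and ``sign`` ("positive"/"negative").  Zero-variance genes within the
    group are skipped.  Edge insertion order is deterministic (sorted gene
    pairs).
    """
    samples = matrix.samples_in_group(group)
    if not samples:
        raise ValueError(f"group {group!r} absent from the matrix")
    if len(samples) < 3:
        raise ValueError(f"group {group!r} has {len(samples)} samples; need >=3")
    genes = sorted(
        g for g in matrix.probe_ids if biotype_of.get(g) in ("lncRNA", "mRNA")
    )
    net = nx.Graph(group=group, cutoff=cutoff)
    for g in genes:
        net.add_node(g, biotype=biotype_of[g])
    X = matrix.values.loc[genes, samples].to_numpy(dtype=float)
    sd = X.std(axis=1)
    alive = sd > 0
    if not alive.all():
        logger.info(
            "build_correlation_network(%s): %d zero-variance genes skipped",
            group,
            int((~alive).sum()),
        )
    idx = np.flatnonzero(alive)
    if idx.size >= 2:
        r = np.corrcoef(X[idx])
        ii, jj = np.triu_indices(idx.size, k=1)
        keep = np.abs(r[ii, jj]) >= cutoff
        for a, b, val in zip(ii[keep], jj[keep], r[ii, jj][keep]):
            u, v = genes[idx[a]], genes[idx[b]]
            net.add_edge(u, v, r=float(val), sign="positive" if val >= 0 else "negative")
    return net


def degree_difference_core(
    net_tumor: nx.Graph, net_normal: nx.Graph, top_k: int | None = None
) -> pd.DataFrame:
    """Rank genes by |degree(tumor) - degree(normal)| across the two networks.

    Genes missing from one network count as degree 0 there.  Ties break by
    tumor degree descending, then gene id.  Columns: gene, degree_tumor,
    degree_normal, degree_diff, rank.
    """
    universe = sorted(set(net_tumor.nodes) | set(net_normal.nodes))
    rows = []
    for gene in universe:
        dt = net_tumor.degree(gene) if gene in net_tumor else 0
        dn = net_normal.degree(gene) if gene in net_normal else 0
        rows.append({"gene": gene, "degree_tumor": int(dt), "degree_normal": int(dn)})
    out = pd.DataFrame(rows)
    out["degree_diff"] = out["degree_tumor"] - out["degree_normal"]
    out["_abs"] = out["degree_diff"].abs()
    out = out.sort_values(
        ["_abs", "degree_tumor", "gene"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="_abs").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out


def pair_report(net: nx.Graph, gene_list) -> pd.DataFrame:
    """Partners of the opposite biotype for each listed gene, with r and sign.

    Unknown genes are skipped with a warning.  Columns: gene, partner,
    gene_biotype, partner_biotype, r, sign — the mRNA/lncRNA pair table
    shape.
    """
    rows = []
    for gene in gene_list:
        if gene not in net:
            logger.warning("pair_report: gene %r not in network universe, skipped", gene)
            continue
        bio = net.nodes[gene].get("biotype")
        for partner in sorted(net.neighbors(gene)):
            pbio = net.nodes[partner].get("biotype")
            if pbio == bio:
                continue
            data = net.edges[gene, partner]
            rows.append(
                {
                    "gene": gene,
                    "partner": partner,
                    "gene_biotype": bio,
                    "partner_biotype": pbio,
                    "r": data["r"],
                    "sign": data["sign"],
                }
            )
    return pd.DataFrame(rows, columns=["gene", "partner", "gene_biotype", "partner_biotype", "r", "sign"])
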