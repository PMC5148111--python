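"""Extraction of regulator-centred visualization subnetworks.

The subnetwork for one group seeds on the extreme regulators (top-k
positive and negative by RIF1 and/or RIF2 z-score), pulls in their
PCIT-significant, threshold-passing partners that are DE or
differential-PIF genes, and keeps every edge of the group's edge set
among the retained nodes (optionally only regulator-incident edges).
Seed regulators with no retained partner stay in the network as isolated
nodes so "unconnected regulators" are visible, not silently dropped.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .rif import top_regulators

__all__ = ["extract_network", "network_stats"]

NODE_TYPES = ("TR", "DEG", "PIF", "DEG+PIF")


def _node_type(node: str, trs: set[str], degs: set[str], pifs: set[str]) -> str:
    if node in trs:
        return "TR"
    in_deg, in_pif = node in degs, node in pifs
    if in_deg and in_pif:
        return "DEG+PIF"
    if in_deg:
        return "DEG"
    if in_pif:
        return "PIF"
    return "DEG"  # unreachable for retained partners by construction


def extract_network(
    edges: pd.DataFrame,
    rif_table: pd.DataFrame,
    degs: set[str],
    pif_set: set[str],
    k: int = 5,
    criterion: str = "both",
    tr_only_edges: bool = False,
) -> nx.Graph:
    """Build the regulator network for one group.

    Parameters
    ----------
    edges : DataFrame
        Thresholded PCIT edge set (columns gene_a, gene_b, r, group).
    rif_table : DataFrame
        Output of :func:`rifnet.rif.score_regulators`.
    degs, pif_set : set
        DE and differential-PIF node ids (same id space as the edges).
    k : int
        Seeds per sign per criterion (top-k positive plus top-k negative).
    criterion : {"rif1", "rif2", "both"}
        Which z-score ranking(s) supply the seeds; "both" merges them.
    tr_only_edges : bool
        Keep only edges incident to a seed regulator instead of all edges
        among retained nodes.
    """
    criteria = ("rif1", "rif2") if criterion == "both" else (criterion,)
    seeds: set[str] = set()
    for crit in criteria:
        pos, neg = top_regulators(rif_table, crit, k)
        seeds.update(pos)
        seeds.update(neg)
    if not seeds:
        raise ValueError("empty seed selection: no scored regulators to seed on")

    trs = set(rif_table.index.astype(str))
    targets = degs | pif_set
    partners: set[str] = set()
    edge_rows = list(edges.itertuples(index=False))
    for row in edge_rows:
        a, b = str(row.gene_a), str(row.gene_b)
        if a in seeds and b in targets:
            partners.add(b)
        if b in seeds and a in targets:
            partners.add(a)
    retained = seeds | partners

    g = nx.Graph(criterion=criterion, k=k)
    for node in sorted(retained):
        g.add_node(node, type=_node_type(node, trs, degs, pif_set))
    for row in edge_rows:
        a, b = str(row.gene_a), str(row.gene_b)
        if a in retained and b in retained:
            if tr_only_edges and not (a in seeds or b in seeds):
                continue
            g.add_edge(a, b, weight=float(row.r), group=str(row.group))
    return g


def network_stats(graph: nx.Graph) -> dict:
    """Exact node/edge counts, per-type counts and the degree distribution."""
    type_counts: dict[str, int] = {}
    for _, data in graph.nodes(data=True):
        t = data.get("type", "?")
        type_counts[t] = type_counts.get(t, 0) + 1
    degrees = sorted((int(d) for _, d in graph.degree()), reverse=True)
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "type_counts": dict(sorted(type_counts.items())),
        "degree_distribution": degrees,
        "n_isolated": sum(1 for d in degrees if d == 0),
    }
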