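"""Interaction-network centralities and hub-gene selection.

Hub genes are network nodes whose degree, closeness and betweenness all
strictly exceed the network means, computed after removing low-degree
(< 2) nodes.  Conventions follow the Centiscape tool: closeness is the
reciprocal of the summed shortest-path distances to all reachable nodes
(not the normalised (n-1)/sum variant) and betweenness is raw, unnormalised
shortest-path betweenness with endpoints excluded, each unordered pair
counted once.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "load_network",
    "prune_min_degree",
    "centralities",
    "select_hubs",
]


def load_network(source, predicted: set[str] | None = None) -> nx.Graph:
    """Build a simple undirected graph from a two-column edge list.

    ``source`` is a TSV path or a DataFrame whose first two columns are
    node pairs.  Self-loops are dropped (with a warning reporting the
    count) and duplicate edges collapse.  ``predicted`` flags nodes added
    by an external interaction-prediction service; the flag is stored as a
    node attribute and carried through to the centrality table.
    """
    if isinstance(source, pd.DataFrame):
        edges = source
    else:
        try:
            edges = pd.read_csv(source, sep="\t", comment="#", dtype=str)
        except pd.errors.EmptyDataError:
            edges = pd.DataFrame(columns=["node_a", "node_b"])
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed edge list {source}: {exc}") from exc
    graph = nx.Graph()
    dropped = 0
    for row in edges.itertuples(index=False):
        u, v = str(row[0]).upper(), str(row[1]).upper()
        if u == v:
            dropped += 1
            continue
        graph.add_edge(u, v)
    if dropped:
        warnings.warn(f"dropped {dropped} self-loop(s) from edge list")
    if graph.number_of_edges() == 0:
        warnings.warn("edge list is empty")
    predicted = {p.upper() for p in predicted or set()}
    nx.set_node_attributes(
        graph, {n: (n in predicted) for n in graph.nodes}, "predicted"
    )
    return graph


def prune_min_degree(graph: nx.Graph, k: int = 2, iterative: bool = True) -> nx.Graph:
    """Remove nodes with degree below ``k``.

    By default removal iterates to a fixed point (removing a node can drop
    a neighbour below the threshold), which equals the graph's k-core;
    ``iterative=False`` performs a single pass over the original degrees.
    """
    pruned = graph.copy()
    if k <= 0:
        return pruned
    if iterative:
        while True:
            low = [n for n, d in pruned.degree() if d < k]
            if not low:
                break
            pruned.remove_nodes_from(low)
    else:
        pruned.remove_nodes_from([n for n, d in pruned.degree() if d < k])
    return pruned


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, closeness (1 / sum of distances) and raw betweenness.

    Distances use unit edge weights within each connected component; a
    node with no reachable neighbours has undefined closeness, reported as
    0 with a warning.  Betweenness is Brandes' algorithm, undirected and
    unnormalised, endpoints excluded.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    rows = []
    isolated = []
    for node in sorted(graph.nodes, key=str):
        dist = nx.single_source_shortest_path_length(graph, node)
        total = sum(dist.values())  # d(node, node) = 0 contributes nothing
        if total == 0:
            isolated.append(node)
            closeness = 0.0
        else:
            closeness = 1.0 / total
        rows.append(
            {
                "node": node,
                "degree": graph.degree(node),
                "closeness": closeness,
                "betweenness": betweenness[node],
                "predicted": bool(graph.nodes[node].get("predicted", False)),
            }
        )
    if isolated:
        warnings.warn(f"closeness undefined (reported 0) for isolated nodes: {isolated}")
    return pd.DataFrame(rows)


def select_hubs(records: pd.DataFrame) -> pd.DataFrame:
    """Flag hub nodes: all three centralities strictly above their means.

    Means are computed over every node in ``records`` (i.e. the
    post-pruning network) and attached as ``DataFrame.attrs['means']`` so
    writers can echo them in the output header.
    """
    records = records.copy()
    means = {
        "betweenness": float(records["betweenness"].mean()),
        "closeness": float(records["closeness"].mean()),
        "degree": float(records["degree"].mean()),
    }
    records["is_hub"] = (
        (records["betweenness"] > means["betweenness"])
        & (records["closeness"] > means["closeness"])
        & (records["degree"] > means["degree"])
    )
    records.attrs["means"] = means
    return records
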