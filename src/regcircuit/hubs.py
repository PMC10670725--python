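"""Hub identification on regulatory-circuit graphs.

Target-side hubs are ranked by maximal clique centrality (MCC): the score
of a node is the sum over maximal cliques C containing it of ``(|C|-1)!``.
On a bipartite graph every maximal clique is a single edge, so MCC reduces
to the node degree; the general scorer is kept so arbitrary graphs can be
analyzed.  Regulator-side hubs are ranked by out-degree (number of distinct
targets) with all regulators tied at the cutoff included, and their
coverage is reported as a percentage of the distinct targets in the graph.
"""

from __future__ import annotations

from math import factorial

import networkx as nx
import pandas as pd

from .integrate import RegulatoryCircuit

REGULATOR = "regulator"
TARGET = "target"


def circuit_graph(circuit: RegulatoryCircuit) -> nx.Graph:
    """Undirected bipartite graph of a circuit, nodes tagged with ``side``.

    Edge direction (regulator -> target) is implicit in the sides.
    """
    g = nx.Graph()
    for m, t in sorted(circuit.edges):
        g.add_node(m, side=REGULATOR)
        g.add_node(t, side=TARGET)
        g.add_edge(m, t)
    return g


def bipartite_graph(edges) -> nx.Graph:
    """Bipartite graph from raw (regulator, target) pairs."""
    g = nx.Graph()
    for m, t in sorted(set(edges)):
        g.add_node(m, side=REGULATOR)
        g.add_node(t, side=TARGET)
        g.add_edge(m, t)
    return g


def maximal_cliques(graph: nx.Graph) -> set[frozenset]:
    """All maximal cliques (Bron-Kerbosch with pivoting), each exactly once."""
    return {frozenset(c) for c in nx.find_cliques(graph)}


def mcc_score(graph: nx.Graph, node) -> int:
    """Sum of ``(|C|-1)!`` over maximal cliques containing ``node``.

    Isolated nodes score 0 by convention, which keeps the bipartite
    MCC = degree identity exact.
    """
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    if graph.degree(node) == 0:
        return 0
    return sum(
        factorial(len(c) - 1) for c in maximal_cliques(graph) if node in c and len(c) > 1
    )


def _mcc_scores(graph: nx.Graph) -> dict:
    scores = {v: 0 for v in graph.nodes}
    for c in maximal_cliques(graph):
        if len(c) < 2:
            continue
        w = factorial(len(c) - 1)
        for v in c:
            scores[v] += w
    return scores


def _side_nodes(graph: nx.Graph, side: str) -> list:
    return [v for v, d in graph.nodes(data=True) if d.get("side") == side]


def select_target_hubs(graph: nx.Graph, k: int = 5) -> pd.DataFrame:
    """Top-``k`` targets by MCC (descending), lexicographic tie-break on ID.

    Columns: ``hub``, ``mcc_score``, ``n_regulators``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    targets = _side_nodes(graph, TARGET)
    if not targets:
        raise ValueError("graph has no target nodes")
    scores = _mcc_scores(graph)
    ranked = sorted(targets, key=lambda v: (-scores[v], str(v)))[:k]
    return pd.DataFrame(
        {
            "hub": ranked,
            "mcc_score": [float(scores[v]) for v in ranked],
            "n_regulators": [graph.degree(v) for v in ranked],
        }
    )


def select_regulator_hubs(graph: nx.Graph, k: int = 5) -> pd.DataFrame:
    """Regulators ranked by out-degree with tie expansion at the cutoff.

    The top ``k`` are expanded to include every regulator whose out-degree
    equals the k-th value.  ``coverage_pct`` is 100 x out-degree over the
    number of distinct targets in the graph, rounded to one decimal.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    regulators = _side_nodes(graph, REGULATOR)
    if not regulators:
        raise ValueError("graph has no regulator nodes")
    n_targets = len(_side_nodes(graph, TARGET))
    ranked = sorted(regulators, key=lambda v: (-graph.degree(v), str(v)))
    if len(ranked) > k:
        cutoff = graph.degree(ranked[k - 1])
        ranked = [v for v in ranked if graph.degree(v) >= cutoff]
    return pd.DataFrame(
        {
            "hub": ranked,
            "out_degree": [graph.degree(v) for v in ranked],
            "coverage_pct": [
                round(100.0 * graph.degree(v) / n_targets, 1) for v in ranked
            ],
        }
    )


def hub_tables(circuit: RegulatoryCircuit, k: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Target and regulator hub tables for a circuit, annotated with the
    circuit type and node directions (mirrors published hub-table layout)."""
    g = circuit_graph(circuit)
    if g.number_of_nodes() == 0:
        cols_t = ["hub", "mcc_score", "n_regulators", "circuit", "direction"]
        cols_r = ["hub", "out_degree", "coverage_pct", "circuit", "direction"]
        return pd.DataFrame(columns=cols_t), pd.DataFrame(columns=cols_r)
    t = select_target_hubs(g, k=k)
    r = select_regulator_hubs(g, k=k)
    t["circuit"] = circuit.circuit_type
    t["direction"] = [circuit.gene_mrna_directions[h] for h in t["hub"]]
    r["circuit"] = circuit.circuit_type
    r["direction"] = [circuit.mirna_directions[h] for h in r["hub"]]
    return t, r
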