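"""Orthogonal minimum spanning trees and global cost efficiency.

The data-driven alternative to a fixed proportional threshold: spanning
trees are extracted one after another from the connectivity graph, each
tree's edges removed from the residual before the next extraction, so the
trees are pairwise edge-disjoint ("orthogonal").  After adding the m-th tree
to the growing union the trade-off

    J(m) = GE(m) - cost(m)

is evaluated, where cost(m) is the summed weight of the union over the
summed weight of the full graph and GE(m) is the union's weighted global
efficiency normalized by the full graph's.  The union at the argmax of J is
the selected network ("equilibrium between global efficiency and edge
removal cost").

Synchronization weights are similarities; spanning trees are computed on the
distance transform d = 1/w (d = 1 - w behind a flag), so a *minimum*
spanning tree in distance is the maximum-synchronization spanning tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from .spectral import ConnectivityMatrix
from .thresholding import DEFAULT_Q_GRID, ThresholdedGraph, quantile_threshold

__all__ = [
    "OMSTResult",
    "maximum_spanning_tree",
    "extract_orthogonal_msts",
    "match_density_threshold",
    "global_efficiency",
]


def _distance(w: float, transform: str) -> float:
    if transform == "inverse":
        return 1.0 / w
    if transform == "one_minus":
        return 1.0 - w
    raise ValueError(f"unknown distance transform {transform!r}")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_tree(
    graph: nx.Graph | ConnectivityMatrix,
    distance: str = "inverse",
) -> list[tuple]:
    """Spanning tree maximizing total synchronization weight.

    Kruskal on the distance transform with deterministic tie-breaking: edges
    of equal distance are taken in lexicographic (u, v) order.  Returns the
    N - 1 edges as (u, v) tuples; raises if the graph is disconnected.
    """
    if isinstance(graph, ConnectivityMatrix):
        graph = _full_graph(graph)
    nodes = list(graph.nodes)
    if not nx.is_connected(graph):
        raise ValueError("residual graph is disconnected; cannot span all nodes")
    edges = sorted(
        (
            (_distance(d["weight"], distance),) + tuple(sorted((u, v), key=str))
            for u, v, d in graph.edges(data=True)
        ),
    )
    uf = _UnionFind(nodes)
    tree = []
    for _, u, v in edges:
        if uf.union(u, v):
            tree.append((u, v))
            if len(tree) == len(nodes) - 1:
                break
    return tree


def _full_graph(m: ConnectivityMatrix) -> nx.Graph:
    """Weighted graph of all strictly positive edges."""
    g = nx.Graph()
    g.add_nodes_from(m.node_labels)
    iu, ju = np.triu_indices(m.n_nodes, k=1)
    for i, j in zip(iu, ju):
        w = m.weights[i, j]
        if w > 0:
            g.add_edge(m.node_labels[i], m.node_labels[j], weight=float(w))
    return g


def global_efficiency(g: nx.Graph, nodes: list | None = None,
                      transform: str = "inverse") -> float:
    """Weighted global efficiency: mean over pairs of 1 / d_ij.

    Shortest paths use the distance transform of the edge weights; pairs
    disconnected in ``g`` contribute 0.
    """
    if nodes is None:
        nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    index = {u: i for i, u in enumerate(nodes)}
    lengths = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        dist = _distance(d["weight"], transform)
        i, j = index[u], index[v]
        lengths[i, j] = lengths[j, i] = dist
    dmat = dijkstra(lengths, directed=False, unweighted=False)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dmat[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(np.mean(inv))


@dataclass
class OMSTResult:
    """Ordered orthogonal MSTs, the selected union, and the J trace."""

    subject_id: str
    measure: str
    msts: list[list[tuple]]
    union_graph: nx.Graph
    gce_trace: list[tuple]  # (m, cost, global efficiency, J)
    selected_m: int
    density: float
    node_labels: list
    group: str = ""

    @property
    def n_trees_extracted(self) -> int:
        return len(self.msts)


def extract_orthogonal_msts(
    m: ConnectivityMatrix,
    distance: str = "inverse",
    patience: int = 3,
    max_trees: int | None = None,
) -> OMSTResult:
    """Run the orthogonal-MST extraction with the J = GE - cost selector.

    Extraction stops when the residual graph disconnects, when ``max_trees``
    trees have been extracted, or when J has not improved for ``patience``
    rounds past its running maximum (J is not guaranteed unimodal; the
    bounded lookahead keeps the procedure deterministic and finite).
    """
    full = _full_graph(m)
    if not nx.is_connected(full):
        raise ValueError(f"{m.subject_id}/{m.measure}: graph is disconnected")
    nodes = sorted(full.nodes, key=str)
    total_weight = sum(d["weight"] for _, _, d in full.edges(data=True))
    ge_full = global_efficiency(full, nodes, transform=distance)

    residual = full.copy()
    union = nx.Graph()
    union.add_nodes_from(nodes)
    msts: list[list[tuple]] = []
    trace: list[tuple] = []
    best_j = -np.inf
    best_m = 0
    limit = max_trees if max_trees is not None else full.number_of_edges()
    while len(msts) < limit:
        if residual.number_of_edges() < len(nodes) - 1 or not nx.is_connected(residual):
            break
        tree = maximum_spanning_tree(residual, distance=distance)
        msts.append(tree)
        for u, v in tree:
            union.add_edge(u, v, weight=full[u][v]["weight"])
            residual.remove_edge(u, v)
        m_idx = len(msts)
        cost = sum(d["weight"] for _, _, d in union.edges(data=True)) / total_weight
        ge = global_efficiency(union, nodes, transform=distance) / ge_full
        j = ge - cost
        trace.append((m_idx, cost, ge, j))
        if j > best_j:
            best_j, best_m = j, m_idx
        elif m_idx - best_m >= patience:
            break

    selected = nx.Graph()
    selected.add_nodes_from(nodes)
    for tree in msts[:best_m]:
        for u, v in tree:
            selected.add_edge(u, v, weight=full[u][v]["weight"])
    n = len(nodes)
    density = selected.number_of_edges() / (n * (n - 1) / 2.0)
    return OMSTResult(
        subject_id=m.subject_id,
        measure=m.measure,
        msts=msts,
        union_graph=selected,
        gce_trace=trace,
        selected_m=best_m,
        density=density,
        node_labels=nodes,
        group=m.group,
    )


def match_density_threshold(
    m: ConnectivityMatrix,
    target_density: float,
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID,
    interpolation: str = "linear",
) -> ThresholdedGraph:
    """Proportional threshold whose pre-pruning density is nearest the target.

    Scans the grid for the level whose surviving-edge fraction (before node
    or component removal) is closest to ``target_density``; ties resolve to
    the smaller q.  For all-distinct weights this is simply q = 1 - target.
    """
    if not (0.0 < target_density < 1.0):
        raise ValueError("target_density must lie in (0, 1)")
    w = np.sort(m.upper_values())
    e = w.size
    best_q, best_gap = None, np.inf
    for q in q_grid:
        thr = np.quantile(w, q, method=interpolation)
        kept = e - np.searchsorted(w, thr, side="left")
        gap = abs(kept / e - target_density)
        if gap < best_gap - 1e-15:
            best_gap, best_q = gap, q
    return quantile_threshold(m, best_q, interpolation=interpolation)
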