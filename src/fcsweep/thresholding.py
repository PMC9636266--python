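"""Proportional quantile thresholding of connectivity matrices.

The sweep applies quantile thresholds q = 0.01 ... 0.99 (step 0.01) to each
subject's own edge-weight distribution: the threshold at level q is the
q-quantile (linear interpolation, off-diagonal upper triangle only) and
edges *strictly below* it are eliminated, so ties at the threshold survive.
After pruning, isolated (degree-zero) nodes are removed and recorded; if the
remainder splits into components only the largest survives (ties broken
toward the component holding the lexicographically smallest label).

Densities are always reported against the original node count N, keeping
them comparable across subjects: ``density_pre`` counts edges surviving the
weight cut, ``density`` counts edges of the finally retained graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .spectral import ConnectivityMatrix

__all__ = [
    "ThresholdedGraph",
    "SweepResult",
    "quantile_threshold",
    "run_sweep",
    "DEFAULT_Q_GRID",
]

logger = logging.getLogger(__name__)

#: the sweep grid {0.01, 0.02, ..., 0.99}
DEFAULT_Q_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 100) / 100.0, 2))


@dataclass
class ThresholdedGraph:
    """One subject's pruned graph at one quantile level, with bookkeeping."""

    subject_id: str
    measure: str
    q: float
    graph: nx.Graph  # the retained (connected) graph
    threshold_value: float
    retained_nodes: list
    isolated_nodes: list
    dropped_component_nodes: list
    n_components_before_pruning: int
    n_nodes_original: int
    density: float  # retained edges / C(N, 2), original N
    density_pre: float  # edges surviving the weight cut / C(N, 2)
    group: str = ""

    @property
    def kept_edges(self) -> list[tuple]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    @property
    def n_isolated(self) -> int:
        return len(self.isolated_nodes)


def quantile_threshold(
    m: ConnectivityMatrix,
    q: float,
    interpolation: str = "linear",
) -> ThresholdedGraph:
    """Prune one connectivity matrix at quantile level ``q``."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie strictly inside (0, 1)")
    w = m.upper_values()
    if not np.any(w > 0):
        raise ValueError(
            f"{m.subject_id}/{m.measure}: all-zero matrix has no weight distribution"
        )
    thr = float(np.quantile(w, q, method=interpolation))

    n = m.n_nodes
    labels = list(m.node_labels)
    g = nx.Graph()
    g.add_nodes_from(labels)
    iu, ju = np.triu_indices(n, k=1)
    keep = m.weights[iu, ju] >= thr  # strictly-below edges eliminated
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(labels[i], labels[j], weight=float(m.weights[i, j]))

    e_possible = n * (n - 1) / 2.0
    density_pre = g.number_of_edges() / e_possible

    isolated = sorted((node for node in g.nodes if g.degree(node) == 0), key=str)
    g.remove_nodes_from(isolated)

    comps = list(nx.connected_components(g))
    n_comps = len(comps)
    dropped: list = []
    if n_comps > 1:
        # largest component; ties -> the one containing the smallest label
        comps.sort(key=lambda c: (-len(c), min(map(str, c))))
        keep_nodes = comps[0]
        dropped = sorted((node for c in comps[1:] for node in c), key=str)
        g = g.subgraph(keep_nodes).copy()

    density = g.number_of_edges() / e_possible
    return ThresholdedGraph(
        subject_id=m.subject_id,
        measure=m.measure,
        q=q,
        graph=g,
        threshold_value=thr,
        retained_nodes=sorted(g.nodes, key=str),
        isolated_nodes=isolated,
        dropped_component_nodes=dropped,
        n_components_before_pruning=n_comps,
        n_nodes_original=n,
        density=density,
        density_pre=density_pre,
        group=m.group,
    )


@dataclass
class SweepResult:
    """All thresholded graphs of a sweep plus their tidy summary table."""

    records: list[ThresholdedGraph] = field(default_factory=list)
    metrics: pd.DataFrame | None = None  # filled by graph_metrics.add_metrics

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": tg.subject_id,
                "group": tg.group,
                "measure": tg.measure,
                "q": tg.q,
                "threshold": tg.threshold_value,
                "density": tg.density,
                "density_pre": tg.density_pre,
                "n_nodes": tg.graph.number_of_nodes(),
                "n_edges": tg.graph.number_of_edges(),
                "n_isolated": tg.n_isolated,
                "n_dropped": len(tg.dropped_component_nodes),
                "n_components": tg.n_components_before_pruning,
            }
            for tg in self.records
        ]
        df = pd.DataFrame(rows)
        if self.metrics is not None:
            df = df.merge(self.metrics, on=["subject", "measure", "q"], how="left")
        return df

    def at(self, q: float, measure: str | None = None) -> list[ThresholdedGraph]:
        out = [tg for tg in self.records if np.isclose(tg.q, q)]
        if measure is not None:
            out = [tg for tg in out if tg.measure == measure]
        return out


def run_sweep(
    matrices: list[ConnectivityMatrix],
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID,
    interpolation: str = "linear",
) -> SweepResult:
    """Threshold every matrix at every grid level.

    Failures on a single matrix (e.g. an all-zero matrix) are logged and the
    matrix is skipped; they do not abort the sweep.
    """
    if not matrices or not len(q_grid):
        raise ValueError("matrices and q_grid must be nonempty")
    result = SweepResult()
    for m in matrices:
        try:
            for q in q_grid:
                result.records.append(quantile_threshold(m, q, interpolation))
        except ValueError as exc:
            warnings.warn(
                f"skipping {m.subject_id}/{m.measure}: {exc}", stacklevel=2
            )
            logger.warning("skipping %s/%s: %s", m.subject_id, m.measure, exc)
            result.records = [
                tg for tg in result.records
                if not (tg.subject_id == m.subject_id and tg.measure == m.measure)
            ]
    if not result.records:
        raise ValueError("no matrix survived the sweep")
    return result
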