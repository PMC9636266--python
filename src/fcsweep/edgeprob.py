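"""Cohort-level edge-probability graphs across thresholds.

For a set of subjects at one threshold level, each edge's probability is the
fraction of subjects whose *pruned* network contains it — a removed or
isolated node's incident edges count as absent, because the probability
graph describes the networks actually analyzed.  Probabilities for one
measure are then min-max scaled jointly across all supplied threshold
levels, making the cross-threshold structure of the cohort comparable (the
same representation applies to OMST-derived networks, labelled q="omst").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .omst import OMSTResult
from .thresholding import ThresholdedGraph

__all__ = [
    "EdgeProbabilityGraph",
    "edge_probabilities",
    "scale_across_thresholds",
    "edge_monotonicity",
    "probability_dispersion",
    "edgeprob_long_frame",
]


@dataclass
class EdgeProbabilityGraph:
    measure: str
    q: float | str  # quantile level, or "omst"
    node_labels: list
    prob: np.ndarray  # symmetric N x N, entries k / n_subjects
    n_subjects: int
    scaled_prob: np.ndarray | None = None


def _graph_and_labels(item) -> tuple[nx.Graph, list]:
    if isinstance(item, ThresholdedGraph):
        return item.graph, None
    if isinstance(item, OMSTResult):
        return item.union_graph, item.node_labels
    if isinstance(item, nx.Graph):
        return item, None
    raise TypeError(f"cannot extract a graph from {type(item).__name__}")


def edge_probabilities(
    graphs: list,
    node_labels: list,
    measure: str = "",
    q: float | str = np.nan,
) -> EdgeProbabilityGraph:
    """Per-edge presence fraction over subjects sharing one node label set."""
    if not graphs:
        raise ValueError("empty subject list")
    n = len(node_labels)
    index = {lab: i for i, lab in enumerate(node_labels)}
    counts = np.zeros((n, n))
    for item in graphs:
        g, _ = _graph_and_labels(item)
        for u, v in g.edges:
            if u not in index or v not in index:
                raise ValueError(f"node {u!r} or {v!r} not in the shared label set")
            i, j = index[u], index[v]
            counts[i, j] += 1
            counts[j, i] += 1
    return EdgeProbabilityGraph(
        measure=measure,
        q=q,
        node_labels=list(node_labels),
        prob=counts / len(graphs),
        n_subjects=len(graphs),
    )


def scale_across_thresholds(
    eps: list[EdgeProbabilityGraph],
) -> list[EdgeProbabilityGraph]:
    """Min-max scale probabilities to [0, 1] jointly across all levels.

    The global minimum and maximum over *all* supplied threshold levels set
    the scale, so ordering is preserved within and across levels.  If every
    probability is identical the scaled values are all 0 by convention.
    """
    if not eps:
        raise ValueError("need at least one threshold level")
    lo = min(float(ep.prob.min()) for ep in eps)
    hi = max(float(ep.prob.max()) for ep in eps)
    span = hi - lo
    for ep in eps:
        if span <= 0:
            ep.scaled_prob = np.zeros_like(ep.prob)
        else:
            ep.scaled_prob = (ep.prob - lo) / span
    return eps


def edge_monotonicity(eps: list[EdgeProbabilityGraph]) -> pd.DataFrame:
    """Per-edge report: is the probability monotone across the q levels?

    Sorting is by q; the report flags, for every upper-triangle edge, whether
    its probability trace is non-increasing, non-decreasing, or neither
    (non-monotone probability across thresholds is possible and is one of
    the phenomena worth surfacing).
    """
    numeric = [ep for ep in eps if not isinstance(ep.q, str)]
    if len(numeric) < 2:
        raise ValueError("need at least 2 numeric threshold levels")
    numeric.sort(key=lambda ep: ep.q)
    labels = numeric[0].node_labels
    stack = np.stack([ep.prob for ep in numeric])  # (n_q, N, N)
    iu, ju = np.triu_indices(len(labels), k=1)
    diffs = np.diff(stack[:, iu, ju], axis=0)
    non_inc = (diffs <= 0).all(axis=0)
    non_dec = (diffs >= 0).all(axis=0)
    return pd.DataFrame(
        {
            "i": [labels[a] for a in iu],
            "j": [labels[b] for b in ju],
            "monotone": non_inc | non_dec,
            "non_increasing": non_inc,
            "non_decreasing": non_dec,
        }
    )


def probability_dispersion(ep: EdgeProbabilityGraph) -> float:
    """SD of edge probabilities over the upper triangle.

    Low dispersion (probability spread evenly across edges) is the signature
    of OMST-derived cohorts; thresholded cohorts concentrate probability on
    a core of strong edges.
    """
    iu = np.triu_indices(len(ep.node_labels), k=1)
    return float(np.std(ep.prob[iu]))


def edgeprob_long_frame(eps: list[EdgeProbabilityGraph]) -> pd.DataFrame:
    """Long-format (i, j, q, prob, scaled_prob) table for all levels."""
    rows = []
    for ep in eps:
        labels = ep.node_labels
        iu, ju = np.triu_indices(len(labels), k=1)
        scaled = ep.scaled_prob if ep.scaled_prob is not None else np.full_like(ep.prob, np.nan)
        for a, b in zip(iu, ju):
            rows.append(
                {
                    "measure": ep.measure,
                    "q": ep.q,
                    "i": labels[a],
                    "j": labels[b],
                    "prob": ep.prob[a, b],
                    "scaled_prob": scaled[a, b],
                }
            )
    return pd.DataFrame(rows)


def save_edgeprob_matrix(ep: EdgeProbabilityGraph, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    qtag = ep.q if isinstance(ep.q, str) else f"{ep.q:.2f}"
    path = directory / f"{ep.measure}_q{qtag}.csv"
    with open(path, "w") as fh:
        fh.write(",".join(map(str, ep.node_labels)) + "\n")
        np.savetxt(fh, ep.prob, delimiter=",", fmt="%.12g")
    return path
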