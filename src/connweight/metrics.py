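"""Node-level network properties and edge-weight/distance relationships.

Edge weights are connection strengths; for any shortest-path computation the
weights are reversed into lengths as ``l = 1 / w``, so a stronger connection
is a shorter distance.  Disconnected node pairs are excluded from path-based
means (and logged) rather than treated as infinite, which keeps the
statistics finite on sparse subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra
from scipy.stats import pearsonr

from .connectome import ConnectivityMatrix, DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NodeMetricVector:
    metric: str  # "strength" | "efficiency"
    values: np.ndarray
    kind: str
    provenance: str


def node_strength(matrix: ConnectivityMatrix) -> NodeMetricVector:
    """Weighted degree: the sum of each node's incident edge weights."""
    return NodeMetricVector(
        metric="strength",
        values=matrix.values.sum(axis=1),
        kind=matrix.kind,
        provenance=matrix.provenance,
    )


def shortest_path_lengths(values: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances on inverse-weight edge lengths.

    Returns an N x N matrix with ``inf`` for unreachable pairs and 0 on the
    diagonal.
    """
    with np.errstate(divide="ignore"):
        lengths = np.where(values > 0, 1.0 / values, 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def nodal_efficiency(matrix: ConnectivityMatrix) -> NodeMetricVector:
    """Reciprocal of each node's mean shortest-path distance to the other
    nodes, with edge lengths 1/w; unreachable pairs are excluded from the
    mean and fully isolated nodes score 0."""
    d = shortest_path_lengths(matrix.values)
    n = matrix.n_nodes
    eff = np.zeros(n)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreachable = int((~np.isfinite(d) & off).sum()) // 2
    if n_unreachable:
        logger.info(
            "nodal_efficiency: %d unreachable pairs excluded from the mean",
            n_unreachable,
        )
    for i in range(n):
        reach = finite[i]
        if reach.any():
            eff[i] = 1.0 / d[i, reach].mean()
    return NodeMetricVector(
        metric="efficiency",
        values=eff,
        kind=matrix.kind,
        provenance=matrix.provenance,
    )


def edge_distance_correlation(
    matrix: ConnectivityMatrix, dist: DistanceMatrix
) -> tuple[float, float, int]:
    """Pearson correlation between log edge weight and Euclidean distance.

    Computed over upper-triangle edges with weight > 0 on a histogram-matched
    matrix (one sample per edge); the natural log is used, which leaves r
    unchanged relative to any other base.

    Returns ``(r, p, n_edges)``.
    """
    if not matrix.normalized:
        raise ValueError("edge_distance_correlation requires a histogram-matched matrix")
    if matrix.values.shape != dist.values.shape:
        raise ValueError("matrix and distance shapes differ")
    iu, ju = np.triu_indices(matrix.n_nodes, k=1)
    w = matrix.values[iu, ju]
    d = dist.values[iu, ju]
    nz = w > 0
    n_edges = int(nz.sum())
    if n_edges < 3:
        raise ValueError(f"need >= 3 nonzero edges, got {n_edges}")
    logw = np.log(w[nz])
    if np.ptp(logw) == 0 or np.ptp(d[nz]) == 0:
        raise ValueError("degenerate (constant) weights or distances")
    r, p = pearsonr(logw, d[nz])
    return float(r), float(p), n_edges
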