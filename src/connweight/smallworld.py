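"""Small-world propensity (Phi) for weighted networks.

Phi quantifies how a network's clustering and characteristic path length
jointly deviate from matched lattice and random null models:

    delta_C = clip((C_latt - C_obs) / (C_latt - C_rand), 0, 1)
    delta_L = clip((L_obs - L_rand) / (L_latt - L_rand), 0, 1)
    Phi     = 1 - sqrt((delta_C**2 + delta_L**2) / 2)

Values above 0.6 are conventionally read as small-world structure.
Clustering is the Onnela geometric-mean-of-triangle-weights coefficient with
weights scaled by the global maximum; path lengths use 1/w edge lengths.
Phi is computed on original (pre-histogram-matching) matrices, which is
asserted via the ``normalized`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import ttest_rel
from statsmodels.stats.anova import AnovaRM
import pandas as pd

from .connectome import ConnectivityMatrix
from .metrics import shortest_path_lengths

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SWPResult:
    phi: float
    delta_c: float
    delta_l: float
    c_obs: float
    c_latt: float
    c_rand: float
    l_obs: float
    l_latt: float
    l_rand: float


@dataclass(frozen=True)
class SWPGroupStats:
    f_statistic: float
    f_p_value: float
    pairwise_t: dict  # (kind_a, kind_b) -> t statistic
    p_values: dict  # (kind_a, kind_b) -> Bonferroni-corrected p (x3)


def weighted_clustering(values: np.ndarray) -> np.ndarray:
    """Per-node Onnela clustering coefficient, weights scaled by the global
    maximum: c_i = sum_{jk} (w~_ij w~_jk w~_ki)^(1/3) / (k_i (k_i - 1))."""
    w = np.asarray(values, float)
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("all-zero matrix")
    what = np.cbrt(w / wmax)
    triangles = np.einsum("ij,jk,ki->i", what, what, what)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore"):
        c = np.where(denom > 0, triangles / np.maximum(denom, 1), 0.0)
    return c


def network_statistics(matrix: ConnectivityMatrix) -> tuple[float, float]:
    """(mean weighted clustering coefficient, characteristic path length).

    L is the mean shortest-path length over reachable off-diagonal pairs on
    1/w edge lengths; disconnected pairs are excluded with a logged note.
    """
    v = matrix.values
    if not np.any(v > 0):
        raise ValueError("all-zero matrix")
    c = float(weighted_clustering(v).mean())
    d = shortest_path_lengths(v)
    off = ~np.eye(len(v), dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no reachable node pairs")
    n_excluded = int((off & ~np.isfinite(d)).sum()) // 2
    if n_excluded:
        logger.info("network_statistics: %d disconnected pairs excluded", n_excluded)
    l = float(d[finite].mean())
    return c, l


def _ring_distance(n: int) -> np.ndarray:
    idx = np.arange(n)
    diff = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(diff, n - diff)


def build_null(
    matrix: ConnectivityMatrix, kind: str, seed: int
) -> ConnectivityMatrix:
    """Null network with the same node count, edge count, and weight multiset.

    ``kind="random"``: degree-preserving double-edge-swap rewiring of the
    binary topology, with the original weights reassigned uniformly at
    random to the surviving edges.

    ``kind="lattice"``: edges re-laid on a ring so the largest weights
    occupy the smallest ring distances (a banded, lattice-like matrix).
    """
    v = matrix.values
    n = len(v)
    iu, ju = np.triu_indices(n, k=1)
    mask = v[iu, ju] > 0
    weights = np.sort(v[iu, ju][mask])[::-1]
    n_edges = len(weights)
    if n_edges < 2:
        raise ValueError("too few edges to build a null model")
    out = np.zeros((n, n))
    if kind == "lattice":
        ring = _ring_distance(n)[iu, ju]
        order = np.argsort(ring, kind="stable")[:n_edges]
        out[iu[order], ju[order]] = weights  # strongest weights nearest the ring
    elif kind == "random":
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(zip(iu[mask], ju[mask]))
        try:
            nx.double_edge_swap(
                g, nswap=5 * n_edges, max_tries=40 * n_edges, seed=seed
            )
        except nx.NetworkXException:
            # swap budget exhausted (e.g. near-complete graphs): the graph is
            # still a valid degree-preserving sample, just less randomized
            logger.info("random null: swap budget exhausted, partial rewiring")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_edges)
        for (a, b), w in zip(g.edges(), weights[perm]):
            out[a, b] = w
    else:
        raise ValueError(f"null kind must be 'lattice' or 'random', got {kind!r}")
    out += out.T
    return matrix.with_values(out, provenance=f"{matrix.provenance}:{kind}-null")


def swp(matrix: ConnectivityMatrix, n_nulls: int = 10, seed: int = 0) -> SWPResult:
    """Small-world propensity of a weighted network.

    Null-model statistics are averaged over ``n_nulls`` realizations each of
    the lattice and random nulls.  Requires an original (not
    histogram-matched) matrix.
    """
    if matrix.normalized:
        raise ValueError("swp must run on original (pre-matching) matrices")
    c_obs, l_obs = network_statistics(matrix)
    c_latt = l_latt = c_rand = l_rand = 0.0
    for k in range(n_nulls):
        cl, ll = network_statistics(build_null(matrix, "lattice", seed + k))
        cr, lr = network_statistics(build_null(matrix, "random", seed + k))
        c_latt += cl / n_nulls
        l_latt += ll / n_nulls
        c_rand += cr / n_nulls
        l_rand += lr / n_nulls
    if np.isclose(c_latt, c_rand):
        raise ValueError("degenerate clustering denominator (C_latt ~= C_rand)")
    if np.isclose(l_latt, l_rand):
        raise ValueError("degenerate path-length denominator (L_latt ~= L_rand)")
    delta_c = float(np.clip((c_latt - c_obs) / (c_latt - c_rand), 0.0, 1.0))
    delta_l = float(np.clip((l_obs - l_rand) / (l_latt - l_rand), 0.0, 1.0))
    phi = 1.0 - np.sqrt((delta_c**2 + delta_l**2) / 2.0)
    return SWPResult(
        phi=float(phi),
        delta_c=delta_c,
        delta_l=delta_l,
        c_obs=c_obs,
        c_latt=c_latt,
        c_rand=c_rand,
        l_obs=l_obs,
        l_latt=l_latt,
        l_rand=l_rand,
    )


def swp_group_stats(
    phi_by_kind: np.ndarray, kinds: tuple[str, str, str] = ("NOS", "FA", "ADD")
) -> SWPGroupStats:
    """Repeated-measures ANOVA across the three weightings, with post hoc
    paired t tests Bonferroni-corrected for the three pairs."""
    phi = np.asarray(phi_by_kind, float)
    if phi.ndim != 2 or phi.shape[1] != 3:
        raise ValueError("phi_by_kind must be subjects x 3")
    if phi.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    if not np.all(np.isfinite(phi)):
        raise ValueError("missing (non-finite) phi values")
    n = phi.shape[0]
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 3),
            "kind": np.tile(np.array(kinds), n),
            "phi": phi.ravel(),
        }
    )
    if np.ptp(phi - phi[:, :1], axis=None) == 0:
        # identical conditions up to a per-subject constant: no kind effect
        f, f_p = 0.0, 1.0
    else:
        aov = AnovaRM(long, depvar="phi", subject="subject", within=["kind"]).fit()
        f = float(aov.anova_table["F Value"].iloc[0])
        f_p = float(aov.anova_table["Pr > F"].iloc[0])
    pairwise_t, p_values = {}, {}
    for a, b in ((0, 1), (0, 2), (1, 2)):
        diff = phi[:, a] - phi[:, b]
        if np.ptp(diff) == 0 and diff[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = ttest_rel(phi[:, a], phi[:, b])
        pairwise_t[(kinds[a], kinds[b])] = float(t)
        p_values[(kinds[a], kinds[b])] = float(min(1.0, 3.0 * p))
    return SWPGroupStats(
        f_statistic=f, f_p_value=f_p, pairwise_t=pairwise_t, p_values=p_values
    )
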