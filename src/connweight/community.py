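"""Multiresolution Louvain community detection with consensus clustering.

The protocol: find the resolution (gamma) range whose Louvain partitions
have between 4 and N/4 communities, draw many partitions at log-uniformly
spaced gammas across that range, aggregate them into a co-classification
(agreement) matrix, threshold weak elements at tau, and re-cluster the
agreement matrix repeatedly until every seeded run agrees.

Community detection is intended to run on group-averaged, histogram-matched
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectome import ConnectivityMatrix


@dataclass(frozen=True)
class CommunityPartition:
    assignment: np.ndarray  # per-node community id, contiguous from 0
    gamma: float
    modularity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        ids = np.unique(a)
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("community ids must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1


@dataclass(frozen=True)
class ConsensusConfig:
    n_samples: int = 1000
    tau: float = 0.2
    min_communities: int = 4
    max_communities_fraction: float = 0.25
    seed: int = 0
    n_restarts: int = 100  # Louvain restarts per consensus iteration
    max_iter: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _to_graph(values: np.ndarray) -> nx.Graph:
    n = len(values)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    nz = values[iu, ju] > 0
    g.add_weighted_edges_from(
        zip(iu[nz].tolist(), ju[nz].tolist(), values[iu, ju][nz].tolist())
    )
    return g


def _canonical_assignment(communities, n: int) -> np.ndarray:
    """Label communities 0.. in order of their smallest member node."""
    a = np.empty(n, dtype=int)
    for cid, comm in enumerate(sorted(communities, key=min)):
        for node in comm:
            a[node] = cid
    return a


def modularity(values: np.ndarray, assignment: np.ndarray, gamma: float) -> float:
    """Weighted Newman-Girvan modularity with resolution gamma:
    Q = (1/2m) sum_ij [w_ij - gamma * s_i s_j / 2m] delta(c_i, c_j)."""
    w = np.asarray(values, float)
    two_m = w.sum()
    if two_m <= 0:
        raise ValueError("graph has no edges")
    s = w.sum(axis=1)
    same = assignment[:, None] == assignment[None, :]
    return float(((w - gamma * np.outer(s, s) / two_m) * same).sum() / two_m)


def _louvain_raw(values: np.ndarray, gamma: float, seed: int) -> np.ndarray:
    g = _to_graph(values)
    if g.number_of_edges() == 0:
        raise ValueError("empty graph: no edges to cluster")
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma, seed=int(seed)
    )
    return _canonical_assignment(comms, len(values))


def _refine_moves(
    values: np.ndarray, assignment: np.ndarray, gamma: float, seed: int
) -> np.ndarray:
    """Greedy single-node modularity moves on the flat partition until no
    move improves Q (the Louvain phase-1 sweep applied to the final
    partition, which aggregation can leave short of a local optimum)."""
    w = values
    n = len(w)
    two_m = w.sum()
    s = w.sum(axis=1)
    a = assignment.copy()
    rng = np.random.default_rng(seed)
    for _ in range(100):
        moved = False
        for i in rng.permutation(n):
            labels = np.unique(a)
            onehot = (a[:, None] == labels[None, :]).astype(float)
            w_ic = w[i] @ onehot  # strength of i into each community
            s_c = s @ onehot
            cur = int(np.searchsorted(labels, a[i]))
            s_c[cur] -= s[i]  # evaluate with i removed from its community
            gain = w_ic - gamma * s[i] * s_c / two_m
            # candidate: any existing community or a fresh singleton (gain 0)
            best = int(np.argmax(gain))
            best_gain = gain[best] - gain[cur]
            if best_gain > 1e-12:
                a[i] = labels[best]
                moved = True
            elif -gain[cur] > 1e-12:  # splitting off improves Q
                a[i] = a.max() + 1
                moved = True
        if not moved:
            # single moves exhausted: try the best pairwise label exchange
            # (escapes interleaved local optima single moves cannot leave)
            if not _best_swap(w, a, gamma, s, two_m):
                break
    # relabel contiguously by smallest member
    comms = [np.where(a == lab)[0] for lab in np.unique(a)]
    return _canonical_assignment([set(c) for c in comms], n)


def _best_swap(
    w: np.ndarray, a: np.ndarray, gamma: float, s: np.ndarray, two_m: float
) -> bool:
    """Apply the best modularity-improving exchange of two nodes' community
    labels, if any; returns whether a swap was made (mutates ``a``)."""
    labels, inv = np.unique(a, return_inverse=True)
    onehot = np.zeros((len(a), len(labels)))
    onehot[np.arange(len(a)), inv] = 1.0
    w_c = w @ onehot  # (n, C) strength of each node into each community
    s_cap = s @ onehot  # community total strengths
    # swap i (in A) and j (in B != A):
    # m*dQ = (w_iB - w_iA) + (w_jA - w_jB) - 2 w_ij
    #        + gamma * (s_i - s_j) * ((S_A - s_i) - (S_B - s_j)) / 2m
    own = w_c[np.arange(len(a)), inv]  # w into own community
    gain_i = w_c - own[:, None]  # (i, B): w_iB - w_iA
    sp = s_cap[inv] - s  # S_own - s_i per node
    delta = (
        gain_i[:, inv]  # w_iB - w_iA with B = j's community
        + gain_i[:, inv].T  # w_jA - w_jB
        - 2.0 * w
        + gamma * np.subtract.outer(s, s) * np.subtract.outer(sp, sp) / two_m
    )
    delta[inv[:, None] == inv[None, :]] = -np.inf  # same community: no swap
    best = np.unravel_index(np.argmax(delta), delta.shape)
    if delta[best] > 1e-12:
        i, j = best
        a[i], a[j] = a[j], a[i]
        return True
    return False


def louvain_partition(
    matrix: ConnectivityMatrix, gamma: float, seed: int = 0
) -> CommunityPartition:
    """One seeded Louvain run maximizing weighted modularity at resolution
    gamma, followed by a greedy single-node refinement sweep; returns the
    partition with its modularity."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    a = _louvain_raw(matrix.values, gamma, seed)
    a = _refine_moves(matrix.values, a, gamma, seed)
    q = modularity(matrix.values, a, gamma)
    return CommunityPartition(assignment=a, gamma=gamma, modularity=q)


def _count(matrix: ConnectivityMatrix, gamma: float, seed: int) -> int:
    return louvain_partition(matrix, gamma, seed).n_communities


def find_gamma_range(
    matrix: ConnectivityMatrix, config: ConsensusConfig = ConsensusConfig()
) -> tuple[float, float]:
    """Bracket the gamma range whose partitions have more than 3 and fewer
    than N/4 communities (counts in [4, ceil(N/4) - 1]).

    Geometric expansion locates brackets, bisection refines them; a single
    fixed seed makes the search deterministic.
    """
    n = matrix.n_nodes
    lo_target = config.min_communities
    hi_target = int(np.ceil(n * config.max_communities_fraction)) - 1
    if hi_target < lo_target:
        raise ValueError(
            f"no admissible community-count window for N={n}: "
            f"[{lo_target}, {hi_target}]"
        )
    seed = config.seed

    def count(g: float) -> int:
        return _count(matrix, g, seed)

    # --- smallest gamma with count >= lo_target ------------------------------
    hi = 1.0
    for _ in range(60):
        if count(hi) >= lo_target:
            break
        hi *= 2.0
    else:
        raise ValueError(f"no gamma found with >= {lo_target} communities")
    lo = hi
    for _ in range(60):
        lo /= 2.0
        if count(lo) < lo_target:
            break
    else:
        raise ValueError("community count never drops below the lower bound")
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        if count(mid) >= lo_target:
            hi = mid
        else:
            lo = mid
    gamma_min = hi

    # --- largest gamma with count <= hi_target -------------------------------
    lo2 = max(gamma_min, 1.0) if count(max(gamma_min, 1.0)) <= hi_target else gamma_min
    if count(lo2) > hi_target:
        raise ValueError("lower bracket already exceeds the community ceiling")
    hi2 = lo2
    for _ in range(60):
        hi2 *= 2.0
        if count(hi2) > hi_target:
            break
    else:
        raise ValueError("community count never exceeds the ceiling")
    for _ in range(40):
        mid = np.sqrt(lo2 * hi2)
        if count(mid) <= hi_target:
            lo2 = mid
        else:
            hi2 = mid
    gamma_max = lo2

    if not gamma_min < gamma_max:
        raise ValueError(
            f"degenerate gamma range: gamma_min={gamma_min:.4g} "
            f">= gamma_max={gamma_max:.4g}"
        )
    return float(gamma_min), float(gamma_max)


def sample_partitions(
    matrix: ConnectivityMatrix,
    gamma_min: float,
    gamma_max: float,
    config: ConsensusConfig = ConsensusConfig(),
) -> list[CommunityPartition]:
    """One Louvain partition at each of ``n_samples`` log-uniformly spaced
    gammas on [gamma_min, gamma_max], with per-sample derived seeds."""
    if not gamma_min < gamma_max and config.n_samples > 1:
        raise ValueError("gamma_min must be < gamma_max")
    if config.n_samples == 1:
        gammas = np.array([gamma_min])
    else:
        gammas = np.geomspace(gamma_min, gamma_max, config.n_samples)
    return [
        louvain_partition(matrix, float(g), seed=config.seed + 1 + i)
        for i, g in enumerate(gammas)
    ]


def agreement_matrix(partitions: list[CommunityPartition]) -> np.ndarray:
    """Co-classification matrix: A[i, j] = fraction of partitions that place
    nodes i and j in the same community (unit diagonal)."""
    if not partitions:
        raise ValueError("need >= 1 partition")
    n = len(partitions[0].assignment)
    a = np.zeros((n, n))
    for p in partitions:
        lab = p.assignment
        if len(lab) != n:
            raise ValueError("partitions cover different node sets")
        a += lab[:, None] == lab[None, :]
    return a / len(partitions)


def consensus_partition(
    partitions: list[CommunityPartition],
    config: ConsensusConfig = ConsensusConfig(),
) -> CommunityPartition:
    """Iterated consensus: agreement matrix -> tau threshold -> seeded
    Louvain restarts, repeated until all restarts return the same partition.

    Raises if the iteration has not converged after ``max_iter`` rounds.
    """
    a = agreement_matrix(partitions)
    n = len(a)
    for it in range(config.max_iter):
        b = a.copy()
        b[b < config.tau] = 0.0
        np.fill_diagonal(b, 0.0)
        if b.sum() == 0:  # thresholding removed every co-classified pair
            return CommunityPartition(
                assignment=np.arange(n), gamma=1.0, modularity=0.0
            )
        runs = [
            _louvain_raw(b, 1.0, config.seed + 1000 * (it + 1) + r)
            for r in range(config.n_restarts)
        ]
        first = runs[0]
        if all(np.array_equal(first, r) for r in runs):
            q = modularity(b, first, 1.0) if b.sum() > 0 else 0.0
            return CommunityPartition(assignment=first, gamma=1.0, modularity=q)
        a = agreement_matrix(
            [CommunityPartition(r, gamma=1.0, modularity=0.0) for r in runs]
        )
    raise RuntimeError(
        f"consensus clustering did not converge within {config.max_iter} iterations"
    )
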