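"""Weighted connectivity matrices.

Builders for the four edge weightings used throughout the pipeline —
streamline count (NOS), mean fractional anisotropy (FA), mean axon diameter
distribution index (ADD), and inter-centroid Euclidean distance (DIST) —
plus quantile-based histogram matching to the NOS distribution, group
averaging with MAD outlier exclusion, and per-node mean incident weight.

Matrices are undirected: both triangles are stored, the diagonal is zero,
and per-edge iteration uses the upper triangle (i < j).  Node ids are
0-based everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .synthetic import AtlasDefinition, StreamlineTable

WEIGHT_KINDS = ("NOS", "FA", "ADD", "DIST")

#: consistency constant relating MAD to the SD of a normal sample
MAD_SCALE = 0.6745


@dataclass(frozen=True)
class ConnectivityMatrix:
    """N x N symmetric nonnegative edge-weight matrix.

    ``normalized`` flags whether the weights have been histogram-matched to
    a reference distribution; several downstream stages require one state or
    the other and assert it.
    """

    values: np.ndarray
    kind: str
    provenance: str = "unknown"
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.kind not in WEIGHT_KINDS:
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix entries must be finite")
        if np.any(v < 0):
            raise ValueError("matrix entries must be nonnegative")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("matrix diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, **meta) -> "ConnectivityMatrix":
        return replace(self, values=values, **meta)


@dataclass(frozen=True)
class DistanceMatrix:
    """Euclidean distances between node centroids, in mm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        off = v[~np.eye(len(v), dtype=bool)]
        if len(off) and np.any(off <= 0):
            raise ValueError("off-diagonal distances must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _check_ids(table: StreamlineTable, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    i = table.rows["node_i"].to_numpy(np.int64)
    j = table.rows["node_j"].to_numpy(np.int64)
    if len(i) and (i.min() < 0 or j.min() < 0 or max(i.max(), j.max()) >= n_nodes):
        raise ValueError(f"streamline node id out of range for n_nodes={n_nodes}")
    return i, j


def build_nos(table: StreamlineTable, n_nodes: int) -> ConnectivityMatrix:
    """Streamline-count connectome: entry (i, j) is the number of streamlines
    whose endpoints are the unordered pair {i, j}."""
    i, j = _check_ids(table, n_nodes)
    m = np.zeros((n_nodes, n_nodes))
    np.add.at(m, (i, j), 1.0)
    np.add.at(m, (j, i), 1.0)
    return ConnectivityMatrix(m, kind="NOS", provenance=table.subject)


def build_mean_scalar(
    table: StreamlineTable, scalar: str, n_nodes: int
) -> ConnectivityMatrix:
    """Mean-scalar connectome: entry (i, j) is the arithmetic mean of the
    chosen per-streamline scalar (``"fa"`` or ``"add"``) over all streamlines
    with endpoints {i, j}; zero where no streamline exists."""
    if scalar not in ("fa", "add"):
        raise ValueError(f"scalar must be 'fa' or 'add', got {scalar!r}")
    i, j = _check_ids(table, n_nodes)
    x = table.rows[scalar].to_numpy(float)
    total = np.zeros((n_nodes, n_nodes))
    count = np.zeros((n_nodes, n_nodes))
    np.add.at(total, (i, j), x)
    np.add.at(count, (i, j), 1.0)
    total += total.T
    count += count.T
    with np.errstate(invalid="ignore"):
        m = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return ConnectivityMatrix(m, kind=scalar.upper(), provenance=table.subject)


def build_distance(atlas: AtlasDefinition) -> DistanceMatrix:
    """Euclidean distance between node centroids for every node pair."""
    xyz = atlas.centroids
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d)


def histogram_match(
    source: ConnectivityMatrix, reference: ConnectivityMatrix
) -> ConnectivityMatrix:
    """Quantile-map the nonzero weights of ``source`` onto the empirical
    distribution of the nonzero weights of ``reference``.

    Each nonzero source entry is ranked (ties receive their average rank) and
    replaced by the reference quantile at that rank, with linear
    interpolation between order statistics.  Mapped values below 1 are set to
    zero — mirroring the convention that a streamline-count weight below one
    is no connection — and structural zeros stay zero.
    """
    if source.values.shape != reference.values.shape:
        raise ValueError("source and reference must have the same shape")
    ref_nz = reference.values[np.triu_indices_from(reference.values, k=1)]
    ref_nz = np.sort(ref_nz[ref_nz > 0])
    if len(ref_nz) == 0:
        raise ValueError("reference matrix has no nonzero entries")

    n = source.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    src = source.values[iu, ju]
    nz = src > 0
    out = np.zeros_like(src)
    k = int(nz.sum())
    if k:
        ranks = rankdata(src[nz], method="average")
        q = (ranks - 1.0) / (k - 1.0) if k > 1 else np.full(1, 0.5)
        mapped = np.quantile(ref_nz, q, method="linear")
        mapped[mapped < 1.0] = 0.0
        out[nz] = mapped
    m = np.zeros((n, n))
    m[iu, ju] = out
    m += m.T
    return source.with_values(m, normalized=True)


def group_average(
    matrices: list[ConnectivityMatrix], mad_z_threshold: float = 3.5
) -> ConnectivityMatrix:
    """Per-edge group mean over nonzero subject values, after excluding
    outliers by modified z-score ``|x - median| * 0.6745 / MAD`` above the
    threshold.  When MAD = 0, values at the median are kept (their modified
    z is taken as 0) and values away from it are treated as infinitely
    deviant and excluded.
    """
    if len(matrices) < 2:
        raise ValueError("group_average needs at least 2 matrices")
    kind = matrices[0].kind
    shape = matrices[0].values.shape
    for m in matrices[1:]:
        if m.values.shape != shape:
            raise ValueError("matrix shape mismatch in group_average")
        if m.kind != kind:
            raise ValueError("matrix kind mismatch in group_average")

    stack = np.stack([m.values for m in matrices])  # (S, N, N)
    vals = np.where(stack > 0, stack, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        med = np.nanmedian(vals, axis=0)
        mad = np.nanmedian(np.abs(vals - med), axis=0)
        modz = MAD_SCALE * np.abs(vals - med) / mad
    keep = ~np.isnan(vals)
    with np.errstate(invalid="ignore"):
        # modz is inf where MAD = 0 and x != median, nan (kept) where 0/0
        exclude = modz > mad_z_threshold
    keep &= ~exclude
    with np.errstate(invalid="ignore"):
        summed = np.where(keep, stack, 0.0).sum(axis=0)
        counts = keep.sum(axis=0)
        out = np.where(counts > 0, summed / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(out, 0.0)
    out = (out + out.T) / 2.0
    return ConnectivityMatrix(
        out, kind=kind, provenance="group", normalized=matrices[0].normalized
    )


def node_mean_weight(matrix: ConnectivityMatrix) -> np.ndarray:
    """Per-node mean of nonzero incident edge weights; 0 for isolated nodes."""
    v = matrix.values
    nz = v > 0
    counts = nz.sum(axis=1)
    sums = v.sum(axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
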