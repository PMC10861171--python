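"""Synthetic cohort generation.

Emulates the statistical structure of a tractography-derived cohort —
distance-decaying connection counts, per-modality edge scalars with a
configurable sign of distance coupling, between-subject variability, and
cognitive composite scores with a planted linear dependence on subnetwork
block means — so that every downstream stage of the pipeline can be
exercised without access-restricted imaging data.

All distributional choices here are stand-ins: no diffusion signal, voxel
grid, or streamline geometry is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

YEO7_NETWORKS: tuple[str, ...] = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)


class ConfigError(ValueError):
    """Raised for an invalid cohort configuration."""


@dataclass(frozen=True)
class ScalarParams:
    """Latent-scale location/scale and signed distance coupling for one
    per-streamline scalar (logit scale for FA, log scale for ADD)."""

    loc: float
    scale: float
    distance_coupling: float  # latent units per mm; sign is the modelled trend

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 120
    nodes_per_hemisphere: int = 100
    network_labels: tuple[str, ...] = YEO7_NETWORKS
    streamline_budget: int = 40_000
    distance_decay: float = 0.015  # 1/mm, pair-sampling probability ~ exp(-decay*d)
    fa_params: ScalarParams = field(
        default_factory=lambda: ScalarParams(loc=-0.6, scale=0.5, distance_coupling=+0.008)
    )
    add_params: ScalarParams = field(
        default_factory=lambda: ScalarParams(loc=0.0, scale=0.3, distance_coupling=-0.004)
    )
    subject_sd: float = 0.02  # SD of log of the per-subject multiplicative factor
    node_sd: float = 0.4  # SD of per-subject regional (node-level) latent offsets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.nodes_per_hemisphere < len(self.network_labels):
            raise ConfigError(
                f"nodes_per_hemisphere ({self.nodes_per_hemisphere}) must be >= "
                f"number of networks ({len(self.network_labels)})"
            )
        if self.streamline_budget < 0:
            raise ConfigError("streamline_budget must be >= 0")
        if self.distance_decay < 0:
            raise ConfigError("distance_decay must be >= 0")
        if self.subject_sd < 0:
            raise ConfigError("subject_sd must be >= 0")
        if self.node_sd < 0:
            raise ConfigError("node_sd must be >= 0")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class AtlasDefinition:
    """Parcellation table: node id, hemisphere, functional network, centroid (mm).

    Node ids are contiguous 0..N-1.  Left-hemisphere centroids have negative
    x, right positive, and every network label is present in both hemispheres.
    """

    nodes: pd.DataFrame  # columns: node_id, hemisphere, network, x, y, z

    def __post_init__(self) -> None:
        df = self.nodes
        required = ["node_id", "hemisphere", "network", "x", "y", "z"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        n = len(df)
        ids = df["node_id"].to_numpy()
        if len(np.unique(ids)) != n:
            raise ValueError("duplicate node_id in atlas")
        if not np.array_equal(np.sort(ids), np.arange(n)):
            raise ValueError("node_id values must be contiguous 0..N-1")
        if not set(df["hemisphere"]) == {"L", "R"}:
            raise ValueError("both hemispheres must be nonempty")
        for net, grp in df.groupby("network"):
            if set(grp["hemisphere"]) != {"L", "R"}:
                raise ValueError(f"network {net!r} absent from one hemisphere")
        xyz = df[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite centroid coordinates")
        left = df["hemisphere"] == "L"
        if not (np.all(df.loc[left, "x"] < 0) and np.all(df.loc[~left, "x"] > 0)):
            raise ValueError("left-hemisphere x must be negative, right positive")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def centroids(self) -> np.ndarray:
        return (
            self.nodes.sort_values("node_id")[["x", "y", "z"]].to_numpy(float)
        )

    @property
    def hemispheres(self) -> np.ndarray:
        return self.nodes.sort_values("node_id")["hemisphere"].to_numpy()

    @property
    def networks(self) -> np.ndarray:
        return self.nodes.sort_values("node_id")["network"].to_numpy()


@dataclass(frozen=True)
class StreamlineTable:
    """Per-subject streamline records: endpoint node pair plus the
    streamline's mean FA (unitless, in (0,1)) and mean ADD (µm, > 0)."""

    rows: pd.DataFrame  # columns: node_i, node_j, fa, add
    subject: str

    def __post_init__(self) -> None:
        required = ["node_i", "node_j", "fa", "add"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise ValueError(f"streamline table missing columns: {missing}")
        if len(self.rows) and np.any(
            self.rows["node_i"].to_numpy() == self.rows["node_j"].to_numpy()
        ):
            raise ValueError("self-loop streamline (node_i == node_j)")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class PlantedEffect:
    """Linear dependence of the cognitive score on subnetwork block means.

    The composite score is normed to mean 100 / SD 15, matching the scale of
    the NIH-Toolbox total cognition composite.
    """

    block_coefficients: dict
    noise_sd: float = 0.0
    score_mean: float = 100.0
    score_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# --------------------------------------------------------------------------
# generators


def _hemisphere_centroids(
    n_nodes: int, n_networks: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place one cluster of nodes per network inside a hemisphere-sized box.

    Returns (centroids relative to the midline with positive x, network index
    per node).  Nodes of the same network share a cluster center with modest
    jitter, so same-network nodes sit nearer each other than across networks.
    """
    centers = np.column_stack(
        [
            rng.uniform(20.0, 60.0, n_networks),  # |x|, lateral offset from midline
            rng.uniform(-90.0, 60.0, n_networks),  # y, posterior-anterior
            rng.uniform(-50.0, 70.0, n_networks),  # z, inferior-superior
        ]
    )
    networks = np.arange(n_nodes) % n_networks  # round-robin assignment
    jitter = rng.normal(0.0, 8.0, (n_nodes, 3))
    xyz = centers[networks] + jitter
    xyz[:, 0] = np.abs(xyz[:, 0]) + 1.0  # keep strictly lateral of the midline
    return xyz, networks


def generate_atlas(config: CohortConfig) -> AtlasDefinition:
    """Generate a bilateral atlas with ``2 * nodes_per_hemisphere`` nodes.

    Networks are assigned round-robin within each hemisphere; the right
    hemisphere mirrors the left's cluster geometry with independent jitter.
    """
    rng = np.random.default_rng(config.seed)
    n_per_hemi = config.nodes_per_hemisphere
    labels = list(config.network_labels)
    k = len(labels)

    left_xyz, left_net = _hemisphere_centroids(n_per_hemi, k, rng)
    right_jitter = rng.normal(0.0, 8.0, (n_per_hemi, 3))
    # mirror the left cluster layout across the midline
    right_xyz = left_xyz + right_jitter
    right_xyz[:, 0] = np.abs(right_xyz[:, 0]) + 1.0

    frames = []
    for hemi, xyz, nets, offset, xsign in (
        ("L", left_xyz, left_net, 0, -1.0),
        ("R", right_xyz, left_net, n_per_hemi, +1.0),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "node_id": np.arange(n_per_hemi) + offset,
                    "hemisphere": hemi,
                    "network": [labels[i] for i in nets],
                    "x": xsign * xyz[:, 0],
                    "y": xyz[:, 1],
                    "z": xyz[:, 2],
                }
            )
        )
    return AtlasDefinition(pd.concat(frames, ignore_index=True))


def _pairwise_distances(xyz: np.ndarray) -> np.ndarray:
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def generate_streamlines(
    atlas: AtlasDefinition, config: CohortConfig, subject_index: int
) -> StreamlineTable:
    """Sample one subject's streamline table.

    Node pairs are drawn with probability proportional to
    ``exp(-distance_decay * d(i, j))``; each streamline's FA is logit-normal
    and its ADD log-normal, with latent means shifted by the signed distance
    coupling.  Between-subject variability has two parts per modality, both
    on the latent scale so each scalar keeps its support: a global
    multiplicative factor (``subject_sd``) and regional node-level offsets
    (``node_sd``) emulating subject-specific microstructure profiles — a
    streamline inherits the mean offset of its two endpoint nodes.
    """
    seed = config.seed + subject_index  # reproducible per-subject stream
    rng = np.random.default_rng(seed)
    n = atlas.n_nodes
    d = _pairwise_distances(atlas.centroids)
    iu, ju = np.triu_indices(n, k=1)
    pair_d = d[iu, ju]
    logits = -config.distance_decay * pair_d
    p = np.exp(logits - logits.max())
    p /= p.sum()

    m = config.streamline_budget
    pick = rng.choice(len(iu), size=m, p=p)
    d_row = pair_d[pick]

    # one multiplicative subject factor per modality, on the latent scale
    f_fa = rng.normal(0.0, config.subject_sd)
    f_add = rng.normal(0.0, config.subject_sd)
    # regional profile: per-node latent offsets, per modality
    u_fa = rng.normal(0.0, config.node_sd, n)
    u_add = rng.normal(0.0, config.node_sd, n)
    i_pick, j_pick = iu[pick], ju[pick]

    fa = expit(
        config.fa_params.loc
        + config.fa_params.distance_coupling * d_row
        + f_fa
        + 0.5 * (u_fa[i_pick] + u_fa[j_pick])
        + config.fa_params.scale * rng.standard_normal(m)
    )
    add = np.exp(
        config.add_params.loc
        + config.add_params.distance_coupling * d_row
        + f_add
        + 0.5 * (u_add[i_pick] + u_add[j_pick])
        + config.add_params.scale * rng.standard_normal(m)
    )
    rows = pd.DataFrame(
        {
            "node_i": iu[pick].astype(np.int64),
            "node_j": ju[pick].astype(np.int64),
            "fa": fa,
            "add": add,
        }
    )
    return StreamlineTable(rows=rows, subject=f"sub-{subject_index:04d}")


def generate_cohort(
    config: CohortConfig,
) -> tuple[AtlasDefinition, list[StreamlineTable]]:
    """One shared atlas plus ``n_subjects`` streamline tables.

    Per-subject seeds are derived deterministically from the master seed, so
    any subject's table is identical across runs and independent of how many
    subjects are generated.
    """
    atlas = generate_atlas(config)
    tables = [
        generate_streamlines(atlas, config, s) for s in range(config.n_subjects)
    ]
    return atlas, tables


def generate_scores(
    block_means: pd.DataFrame, effect: PlantedEffect, seed: int
) -> np.ndarray:
    """Cognitive composite scores with a planted linear block-mean dependence.

    ``raw = sum_b coeff_b * block_mean_b + N(0, noise_sd)`` per subject, then
    normed to sample mean ``score_mean`` and sample SD ``score_sd``.  A
    constant raw vector maps every subject to ``score_mean``.

    Parameters
    ----------
    block_means : DataFrame, subjects x blocks (columns are block ids).
    """
    unknown = [b for b in effect.block_coefficients if b not in block_means.columns]
    if unknown:
        raise KeyError(f"unknown block id(s) in planted effect: {unknown}")
    rng = np.random.default_rng(seed)
    n = len(block_means)
    raw = np.zeros(n)
    for block, coeff in effect.block_coefficients.items():
        raw += coeff * block_means[block].to_numpy(float)
    raw += rng.normal(0.0, effect.noise_sd, n)
    sd = raw.std(ddof=0)
    # variation below float resolution is noise, not signal: treat as constant
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, np.abs(raw).max()):
        return np.full(n, effect.score_mean)
    return effect.score_mean + effect.score_sd * (raw - raw.mean()) / sd
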