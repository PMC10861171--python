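"""Cognition prediction from weighted connectomes.

The pipeline: split each connectivity matrix's edges into 23 functional
subnetwork blocks (per network: left-intra, right-intra, inter-hemispheric;
plus left and right between-network blocks), reduce each block (or the whole
brain) to the minimal number of PCA components covering a variance
threshold, and regress the cognitive composite on those components with
gradient-boosted trees.  Models are compared over many shared random 80/20
splits with paired Wilcoxon signed-rank tests, and subnetwork importance is
assessed by ablating feature groups.

Original (not histogram-matched) matrices are used throughout, with each
subject's edge vector sum-normalized and z-scored before PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, wilcoxon
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, train_test_split
from xgboost import XGBRegressor

from .connectome import ConnectivityMatrix
from .synthetic import AtlasDefinition

logger = logging.getLogger(__name__)

HYPERPARAM_N_TREES = (10, 50, 100, 200, 300, 500)
HYPERPARAM_ETA = (0.005, 0.01, 0.05, 0.1)


@dataclass(frozen=True)
class Block:
    block_id: int
    label: str
    edges: np.ndarray  # (m, 2) upper-triangle node pairs, i < j

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class SubnetworkPartition:
    """Edge blocks: 3 per bilateral network plus 2 between-network blocks
    (23 for a 7-network atlas).  Between-network inter-hemispheric edges
    belong to no block by construction."""

    blocks: list

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def within_network_blocks(self) -> list:
        return [b for b in self.blocks if not b.label.startswith("between_networks")]

    def by_id(self, block_id: int) -> Block:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(block_id)


@dataclass(frozen=True)
class ModelSpec:
    eta: float = 0.05
    n_trees: int = 200
    alpha: float = 1.0  # L1 leaf regularization
    max_depth: int = 6
    loss: str = "squared_error"

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class FeatureMatrix:
    values: np.ndarray  # subjects x components
    provenance: pd.DataFrame  # columns: block_id, label, component, evr_share
    variance_threshold: float

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EvaluationResult:
    label: str
    r: np.ndarray  # per-iteration held-out Pearson r (nan where undefined)
    split_seeds: np.ndarray
    test_fraction: float = 0.2

    @property
    def median_r(self) -> float:
        return float(np.nanmedian(self.r))


@dataclass(frozen=True)
class AblationResult:
    group: str
    r: np.ndarray
    delta_median_r: float  # ablated minus full
    wilcoxon_statistic: float
    p_corrected: float  # Bonferroni x 30 (10 groups x 3 weightings)


# --------------------------------------------------------------------------
# subnetwork blocks


def partition_subnetworks(atlas: AtlasDefinition) -> SubnetworkPartition:
    """Assign every upper-triangle edge to at most one of 3K + 2 blocks.

    For each of the K networks: edges inside the left hemisphere, inside the
    right, and between hemispheres within the network.  Two further blocks
    hold within-hemisphere edges connecting different networks.  Edges that
    cross both hemisphere and network boundaries are deliberately left out.
    """
    hemi = atlas.hemispheres
    nets = atlas.networks
    labels = sorted(set(nets))
    for lab in labels:
        if not (np.any((nets == lab) & (hemi == "L")) and np.any((nets == lab) & (hemi == "R"))):
            raise ValueError(f"network {lab!r} is absent from one hemisphere")

    n = atlas.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    same_net = nets[iu] == nets[ju]
    same_hemi = hemi[iu] == hemi[ju]
    left = (hemi[iu] == "L") & (hemi[ju] == "L")

    blocks: list[Block] = []
    bid = 0
    for lab in labels:
        in_net = (nets[iu] == lab) & (nets[ju] == lab)
        for name, mask in (
            (f"{lab}_left", in_net & same_hemi & left),
            (f"{lab}_right", in_net & same_hemi & ~left),
            (f"{lab}_interhemi", in_net & ~same_hemi),
        ):
            blocks.append(
                Block(bid, name, np.column_stack([iu[mask], ju[mask]]))
            )
            bid += 1
    for name, mask in (
        ("between_networks_left", ~same_net & same_hemi & left),
        ("between_networks_right", ~same_net & same_hemi & ~left),
    ):
        blocks.append(Block(bid, name, np.column_stack([iu[mask], ju[mask]])))
        bid += 1
    return SubnetworkPartition(blocks)


def edge_columns(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Column indices of (i, j) pairs in the canonical upper-triangle
    vectorization (row-major order of ``np.triu_indices``)."""
    i = edges[:, 0].astype(np.int64)
    j = edges[:, 1].astype(np.int64)
    return (i * (2 * n_nodes - i - 1)) // 2 + (j - i - 1)


# --------------------------------------------------------------------------
# features


def prepare_features(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Subjects x edges matrix of normalized, standardized edge weights.

    Per subject: vectorize the upper triangle, divide by the subject's total
    weight, then shift/scale to mean 0 and SD 1.  Requires original
    (unmatched) matrices of a single weight kind.
    """
    if not matrices:
        raise ValueError("no matrices given")
    kind = matrices[0].kind
    shape = matrices[0].values.shape
    rows = []
    for m in matrices:
        if m.values.shape != shape or m.kind != kind:
            raise ValueError("matrices must share shape and kind")
        if m.normalized:
            raise ValueError("prediction features require original (unmatched) matrices")
        iu, ju = np.triu_indices(m.n_nodes, k=1)
        x = m.values[iu, ju].astype(float)
        total = x.sum()
        if total <= 0:
            raise ValueError(f"all-zero subject matrix ({m.provenance})")
        x = x / total
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"constant edge vector for subject {m.provenance}")
        rows.append((x - x.mean()) / sd)
    return np.vstack(rows)


def block_pca(
    features: np.ndarray, edge_cols: np.ndarray, variance_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of one edge block across subjects.

    Keeps the minimal number of components whose cumulative explained
    variance reaches the threshold.  Returns (subject scores (S, k),
    explained-variance shares (k,)).
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    if len(edge_cols) == 0:
        raise ValueError("empty edge subset")
    x = features[:, edge_cols]
    if x.shape[0] < 2:
        raise ValueError("need >= 2 subjects for PCA")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(x)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, scores.shape[1])
    return scores[:, :k], evr[:k]


def assemble_features(
    matrices: list[ConnectivityMatrix],
    partition: SubnetworkPartition,
    mode: str = "subnetworks",
    variance_threshold: float = 0.2,
) -> FeatureMatrix:
    """Model input features.

    ``mode="subnetworks"``: per-block PCA at the block threshold, columns
    concatenated with block provenance.  ``mode="whole_brain"``: one PCA on
    every edge (all edges, including those outside the 23 blocks).
    """
    feats = prepare_features(matrices)
    n_nodes = matrices[0].n_nodes
    cols, prov = [], []
    if mode == "subnetworks":
        for b in partition.blocks:
            if b.n_edges == 0:
                raise ValueError(f"block {b.label!r} has no edges")
            scores, evr = block_pca(
                feats, edge_columns(b.edges, n_nodes), variance_threshold
            )
            cols.append(scores)
            prov.extend(
                {"block_id": b.block_id, "label": b.label, "component": c,
                 "evr_share": float(evr[c])}
                for c in range(scores.shape[1])
            )
    elif mode == "whole_brain":
        scores, evr = block_pca(
            feats, np.arange(feats.shape[1]), variance_threshold
        )
        cols.append(scores)
        prov.extend(
            {"block_id": -1, "label": "whole_brain", "component": c,
             "evr_share": float(evr[c])}
            for c in range(scores.shape[1])
        )
    else:
        raise ValueError(f"mode must be 'subnetworks' or 'whole_brain', got {mode!r}")
    return FeatureMatrix(
        values=np.hstack(cols),
        provenance=pd.DataFrame(prov),
        variance_threshold=variance_threshold,
    )


# --------------------------------------------------------------------------
# model fitting and evaluation


def _regressor(spec: ModelSpec, seed: int = 0) -> XGBRegressor:
    return XGBRegressor(
        n_estimators=spec.n_trees,
        learning_rate=spec.eta,
        reg_alpha=spec.alpha,
        max_depth=spec.max_depth,
        objective="reg:squarederror",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def tune_hyperparameters(
    features: FeatureMatrix,
    scores: np.ndarray,
    spec: ModelSpec = ModelSpec(),
    n_folds: int = 10,
    seed: int = 0,
    plateau_tolerance: float = 0.02,
) -> tuple[float, int, pd.DataFrame]:
    """10-fold cross-validated mean MAE over the 6 x 4 (n_trees, eta) grid.

    Returns the plateau choice — the smallest (n_trees, then eta) whose mean
    MAE is within ``plateau_tolerance`` (relative) of the grid minimum —
    plus the full grid table.
    """
    y = np.asarray(scores, float)
    if len(y) < 20:
        raise ValueError("need >= 20 subjects for hyperparameter tuning")
    if len(y) < n_folds:
        raise ValueError("fewer subjects than folds")
    x = features.values
    folds = list(KFold(n_folds, shuffle=True, random_state=seed).split(x))
    records = []
    for n_trees in HYPERPARAM_N_TREES:
        for eta in HYPERPARAM_ETA:
            cell = ModelSpec(eta=eta, n_trees=n_trees, alpha=spec.alpha,
                             max_depth=spec.max_depth)
            maes = []
            for tr, te in folds:
                model = _regressor(cell, seed)
                model.fit(x[tr], y[tr])
                maes.append(float(np.abs(model.predict(x[te]) - y[te]).mean()))
            records.append({"n_trees": n_trees, "eta": eta, "mae": float(np.mean(maes))})
    grid = pd.DataFrame(records)
    best = grid["mae"].min()
    ok = grid[grid["mae"] <= best * (1.0 + plateau_tolerance)]
    chosen = ok.sort_values(["n_trees", "eta"]).iloc[0]
    return float(chosen["eta"]), int(chosen["n_trees"]), grid


def derive_split_seeds(seed: int, n_iter: int) -> np.ndarray:
    """Split seeds derived from the master seed so that different models
    evaluated with the same (seed, n_iter) share identical splits."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n_iter)


def fit_and_evaluate(
    features: FeatureMatrix,
    scores: np.ndarray,
    spec: ModelSpec = ModelSpec(),
    n_iter: int = 1000,
    seed: int = 0,
    label: str = "model",
) -> EvaluationResult:
    """Resampled evaluation: ``n_iter`` random 80/20 train/test splits,
    gradient-boosted regression on each, held-out Pearson r recorded.

    Iterations whose test-set truth is constant have undefined r and are
    recorded as NaN (and logged).
    """
    y = np.asarray(scores, float)
    if len(y) < 10:
        raise ValueError("need >= 10 subjects")
    x = features.values
    split_seeds = derive_split_seeds(seed, n_iter)
    r = np.full(n_iter, np.nan)
    for i, s in enumerate(split_seeds):
        xtr, xte, ytr, yte = train_test_split(
            x, y, test_size=0.2, random_state=int(s)
        )
        if np.ptp(yte) == 0:
            logger.info("iteration %d: constant test truth, r undefined", i)
            continue
        model = _regressor(spec, seed=0)
        model.fit(xtr, ytr)
        pred = model.predict(xte)
        if np.ptp(pred) == 0:
            r[i] = 0.0
            continue
        r[i] = pearsonr(yte, pred)[0]
    return EvaluationResult(label=label, r=r, split_seeds=split_seeds)


def compare_models(results: list[EvaluationResult]) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests on per-iteration r for every
    unordered pair of models, Bonferroni-corrected by the number of pairs.

    All results must share their split seeds (otherwise pairing is invalid).
    """
    if len(results) < 2:
        raise ValueError("need >= 2 models to compare")
    ref = results[0].split_seeds
    for res in results[1:]:
        if len(res.split_seeds) != len(ref) or not np.array_equal(res.split_seeds, ref):
            raise ValueError("split seeds differ between models; pairing invalid")
    pairs = [
        (a, b) for i, a in enumerate(results) for b in results[i + 1:]
    ]
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        mask = np.isfinite(a.r) & np.isfinite(b.r)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("compare_models %s vs %s: %d undefined iterations dropped",
                        a.label, b.label, dropped)
        ra, rb = a.r[mask], b.r[mask]
        if np.allclose(ra, rb):
            stat, p = 0.0, 1.0
        else:
            stat, p = wilcoxon(ra, rb)
        rows.append(
            {
                "model_a": a.label,
                "model_b": b.label,
                "median_r_a": float(np.median(ra)),
                "median_r_b": float(np.median(rb)),
                "wilcoxon_statistic": float(stat),
                "p_raw": float(p),
                "p_corrected": float(min(1.0, n_pairs * p)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# subnetwork-ablation importance


def ablation_groups(partition: SubnetworkPartition) -> dict:
    """The 10 feature groups whose removal is tested: each network's 3
    blocks, the 2 between-network blocks, and each hemisphere's 8 blocks
    (7 intra-network + its between-network block)."""
    networks = sorted(
        {b.label.rsplit("_", 1)[0] for b in partition.within_network_blocks}
    )
    groups: dict[str, set[int]] = {}
    for net in networks:
        groups[net] = {
            b.block_id
            for b in partition.blocks
            if b.label in (f"{net}_left", f"{net}_right", f"{net}_interhemi")
        }
    groups["internetwork"] = {
        b.block_id for b in partition.blocks
        if b.label.startswith("between_networks")
    }
    for hemi in ("left", "right"):
        groups[f"{hemi}_hemisphere"] = {
            b.block_id for b in partition.blocks if b.label.endswith(f"_{hemi}")
        }
    return groups


def drop_feature_group(features: FeatureMatrix, block_ids: set) -> FeatureMatrix:
    keep = ~features.provenance["block_id"].isin(list(block_ids)).to_numpy()
    if keep.all():
        raise ValueError("feature group contributes no columns")
    if not keep.any():
        raise ValueError("feature group removes all columns")
    return FeatureMatrix(
        values=features.values[:, keep],
        provenance=features.provenance.loc[keep].reset_index(drop=True),
        variance_threshold=features.variance_threshold,
    )


def ablation_importance(
    features: FeatureMatrix,
    partition: SubnetworkPartition,
    scores: np.ndarray,
    spec: ModelSpec = ModelSpec(),
    n_iter: int = 100,
    seed: int = 0,
    full_result: EvaluationResult | None = None,
    correction_factor: int = 30,
) -> tuple[EvaluationResult, list[AblationResult]]:
    """Drop each of the 10 subnetwork groups in turn and re-evaluate over
    splits shared with the full model; paired Wilcoxon against the full
    model, Bonferroni-corrected by ``correction_factor`` (30 = 10 groups x
    3 weightings).
    """
    if full_result is None:
        full_result = fit_and_evaluate(
            features, scores, spec, n_iter=n_iter, seed=seed, label="full"
        )
    out = []
    for name, block_ids in ablation_groups(partition).items():
        reduced = drop_feature_group(features, block_ids)
        res = fit_and_evaluate(
            reduced, scores, spec, n_iter=n_iter, seed=seed, label=f"ablate_{name}"
        )
        mask = np.isfinite(res.r) & np.isfinite(full_result.r)
        if np.allclose(res.r[mask], full_result.r[mask]):
            stat, p = 0.0, 1.0
        else:
            stat, p = wilcoxon(res.r[mask], full_result.r[mask])
        out.append(
            AblationResult(
                group=name,
                r=res.r,
                delta_median_r=float(np.nanmedian(res.r) - np.nanmedian(full_result.r)),
                wilcoxon_statistic=float(stat),
                p_corrected=float(min(1.0, correction_factor * p)),
            )
        )
    return full_result, out


# --------------------------------------------------------------------------
# planted-effect helper


def block_mean_table(
    matrices: list[ConnectivityMatrix],
    partition: SubnetworkPartition,
    prepared: bool = True,
) -> pd.DataFrame:
    """Subjects x blocks table of mean edge weight per block.

    With ``prepared=True`` (default) the means are taken over the
    normalized, per-subject standardized edge vectors — the same
    representation the prediction models consume — so a score planted on
    these block means has a defined relationship to the model features.
    ``prepared=False`` gives raw edge-weight means (zeros included).
    """
    n_nodes = matrices[0].n_nodes
    if prepared:
        feats = prepare_features(matrices)
    else:
        iu, ju = np.triu_indices(n_nodes, k=1)
        feats = np.vstack([m.values[iu, ju] for m in matrices])
    cols = {}
    for b in partition.blocks:
        idx = edge_columns(b.edges, n_nodes)
        cols[b.block_id] = (
            feats[:, idx].mean(axis=1) if len(idx) else np.zeros(len(matrices))
        )
    return pd.DataFrame(cols)


def default_planted_effect(
    partition: SubnetworkPartition,
    networks: tuple = ("visual", "somatomotor", "default"),
    hemisphere: str = "left",
    noise_sd: float = 0.12,
):
    """The canonical simulation condition for parameter-recovery studies: a
    unit coefficient on the intra-hemispheric block of each named network in
    one hemisphere, with Gaussian noise sized so the full subnetworks model
    reaches moderate (r around 0.4) held-out accuracy at the generator
    defaults."""
    from .synthetic import PlantedEffect

    label_to_id = {b.label: b.block_id for b in partition.blocks}
    coeffs = {}
    for net in networks:
        key = f"{net}_{hemisphere}"
        if key not in label_to_id:
            raise KeyError(f"no block {key!r} in partition")
        coeffs[label_to_id[key]] = 1.0
    return PlantedEffect(block_coefficients=coeffs, noise_sd=noise_sd)
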