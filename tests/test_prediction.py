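"""Subnetwork blocks, PCA features, boosted-tree evaluation, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import wilcoxon

import connweight as cw
from connweight import prediction as pr

from conftest import symmetric_matrix


@pytest.fixture(scope="module")
def atlas(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="module")
def partition(atlas):
    return pr.partition_subnetworks(atlas)


@pytest.fixture(scope="module")
def fa_matrices(small_cohort):
    atlas, tables = small_cohort
    return [cw.build_mean_scalar(t, "fa", atlas.n_nodes) for t in tables]


class TestPartition:
    def test_23_blocks_of_which_21_within_network(self, partition):
        assert partition.n_blocks == 23
        assert len(partition.within_network_blocks) == 21

    def test_blocks_disjoint_and_cover_all_but_cross_edges(self, atlas, partition):
        """Exhaustive edge audit: blocks are pairwise disjoint and their
        union misses exactly the between-network inter-hemispheric edges."""
        n = atlas.n_nodes
        seen = {}
        for b in partition.blocks:
            for i, j in b.edges:
                assert (i, j) not in seen, "edge in two blocks"
                seen[(i, j)] = b.label
        hemi, nets = atlas.hemispheres, atlas.networks
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            excluded = hemi[i] != hemi[j] and nets[i] != nets[j]
            assert ((i, j) not in seen) == excluded

    def test_network_missing_from_hemisphere_rejected(self):
        df = pd.DataFrame(
            {
                "node_id": range(4),
                "hemisphere": ["L", "L", "R", "R"],
                "network": ["visual", "default", "visual", "visual"],
                "x": [-1.0, -2.0, 1.0, 2.0],
                "y": 0.0,
                "z": 0.0,
            }
        )
        with pytest.raises(ValueError, match="hemisphere"):
            cw.AtlasDefinition(df)


class TestPrepareFeatures:
    def test_rows_standardized(self, fa_matrices):
        x = pr.prepare_features(fa_matrices)
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(x.std(axis=1), 1.0, atol=1e-12)

    def test_scale_invariance(self, fa_matrices):
        m = fa_matrices[0]
        x1 = pr.prepare_features([m, m.with_values(m.values * 3.0)])
        assert np.allclose(x1[0], x1[1], atol=1e-12)

    def test_matches_two_step_loop_oracle(self, fa_matrices):
        x = pr.prepare_features(fa_matrices)
        n = fa_matrices[0].n_nodes
        iu, ju = np.triu_indices(n, k=1)
        for s, m in enumerate(fa_matrices):
            v = m.values[iu, ju]
            v = v / v.sum()
            v = (v - v.mean()) / v.std()
            assert np.allclose(x[s], v, atol=1e-12)

    def test_matched_matrices_rejected(self, small_cohort):
        atlas, tables = small_cohort
        n = atlas.n_nodes
        nos = [cw.build_nos(t, n) for t in tables]
        matched = [cw.histogram_match(m, m) for m in nos]
        with pytest.raises(ValueError):
            pr.prepare_features(matched)

    def test_all_zero_subject_rejected(self):
        z = cw.ConnectivityMatrix(np.zeros((6, 6)), kind="FA", provenance="z")
        with pytest.raises(ValueError):
            pr.prepare_features([z, z])


class TestBlockPCA:
    def test_single_edge_block(self, rng):
        x = rng.normal(0, 1, (10, 5))
        scores, evr = pr.block_pca(x, np.array([2]), 0.2)
        assert scores.shape == (10, 1)
        assert np.isclose(evr[0], 1.0)

    def test_minimal_component_count(self, rng):
        # one dominant direction explaining > 30% of variance
        base = rng.normal(0, 1, (40, 1)) @ np.ones((1, 8))
        x = base + rng.normal(0, 0.5, (40, 8))
        scores, evr = pr.block_pca(x, np.arange(8), 0.2)
        assert scores.shape[1] == 1
        assert evr[0] >= 0.2

    def test_explained_variance_matches_eigenvalue_oracle(self, rng):
        x = rng.normal(0, 1, (25, 12))
        _, evr = pr.block_pca(x, np.arange(12), 1.0)
        xc = x - x.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(xc.T)))[::-1]
        assert np.allclose(evr, (eig / eig.sum())[: len(evr)], atol=1e-9)

    def test_threshold_bounds(self, rng):
        x = rng.normal(0, 1, (10, 4))
        with pytest.raises(ValueError):
            pr.block_pca(x, np.arange(4), 0.0)
        with pytest.raises(ValueError):
            pr.block_pca(x, np.arange(4), 1.5)


class TestAssembleFeatures:
    def test_subnetwork_provenance_names_23_blocks(self, fa_matrices, partition):
        fm = pr.assemble_features(fa_matrices, partition, "subnetworks", 0.2)
        assert fm.provenance["block_id"].nunique() == 23
        assert len(fm.provenance) == fm.n_features

    def test_whole_brain_single_provenance(self, fa_matrices, partition):
        fm = pr.assemble_features(fa_matrices, partition, "whole_brain", 0.3)
        assert set(fm.provenance["block_id"]) == {-1}

    def test_component_counts_follow_block_size(self, fa_matrices, partition):
        """Per-block counts equal independent per-block PCA runs."""
        fm = pr.assemble_features(fa_matrices, partition, "subnetworks", 0.5)
        feats = pr.prepare_features(fa_matrices)
        n = fa_matrices[0].n_nodes
        counts = fm.provenance.groupby("block_id").size()
        for b in partition.blocks:
            scores, _ = pr.block_pca(feats, pr.edge_columns(b.edges, n), 0.5)
            assert counts[b.block_id] == scores.shape[1]


class TestEvaluation:
    def _linear_features(self, rng, n=60, k=6):
        x = rng.normal(0, 1, (n, k))
        fm = pr.FeatureMatrix(
            values=x,
            provenance=pd.DataFrame(
                {"block_id": np.arange(k) % 3, "label": "b", "component": 0,
                 "evr_share": 1.0 / k}
            ),
            variance_threshold=0.2,
        )
        return fm, x

    def test_iteration_count_and_shared_splits(self, rng):
        fm, x = self._linear_features(rng)
        y = x[:, 0] * 10 + 100
        spec = pr.ModelSpec(n_trees=20, max_depth=2)
        r1 = pr.fit_and_evaluate(fm, y, spec, n_iter=8, seed=3, label="a")
        r2 = pr.fit_and_evaluate(fm, y, spec, n_iter=8, seed=3, label="b")
        assert len(r1.r) == 8
        assert np.array_equal(r1.split_seeds, r2.split_seeds)

    def test_noise_free_linear_target_recovered(self, rng):
        fm, x = self._linear_features(rng, n=80)
        y = 100 + 15 * x[:, 0]
        spec = pr.ModelSpec(eta=0.1, n_trees=300, max_depth=3)
        res = pr.fit_and_evaluate(fm, y, spec, n_iter=20, seed=1)
        assert res.median_r > 0.9

    def test_permuted_scores_give_null_accuracy(self, rng):
        fm, x = self._linear_features(rng, n=120)
        y = rng.permutation(100 + 15 * x[:, 0])
        spec = pr.ModelSpec(n_trees=50, max_depth=2)
        res = pr.fit_and_evaluate(fm, y, spec, n_iter=200, seed=2)
        assert abs(res.median_r) < 0.1


class TestCompareModels:
    def _result(self, rng, label, seeds, shift=0.0):
        return pr.EvaluationResult(
            label=label, r=np.clip(rng.normal(0.3 + shift, 0.1, len(seeds)), -1, 1),
            split_seeds=seeds,
        )

    def test_six_models_give_15_comparisons(self, rng):
        seeds = pr.derive_split_seeds(0, 50)
        results = [self._result(rng, f"m{k}", seeds, 0.02 * k) for k in range(6)]
        table = pr.compare_models(results)
        assert len(table) == 15
        assert np.allclose(
            table["p_corrected"], np.minimum(1.0, 15 * table["p_raw"])
        )

    def test_self_comparison_p_is_one(self, rng):
        seeds = pr.derive_split_seeds(0, 30)
        a = self._result(rng, "a", seeds)
        table = pr.compare_models([a, a])
        assert table["p_corrected"].iloc[0] == 1.0

    def test_wilcoxon_matches_hand_rank_computation(self):
        a = np.array([0.50, 0.42, 0.61, 0.39, 0.55, 0.48, 0.70, 0.44])
        b = np.array([0.45, 0.44, 0.52, 0.38, 0.50, 0.49, 0.60, 0.40])
        seeds = pr.derive_split_seeds(0, 8)
        ra = pr.EvaluationResult("a", a, seeds)
        rb = pr.EvaluationResult("b", b, seeds)
        table = pr.compare_models([ra, rb])
        # hand computation: rank |d|, W = min(sum of +ranks, sum of -ranks)
        d = a - b
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        w_plus = ranks[d > 0].sum()
        w_minus = ranks[d < 0].sum()
        assert table["wilcoxon_statistic"].iloc[0] == min(w_plus, w_minus)
        assert np.isclose(table["p_raw"].iloc[0], wilcoxon(a, b)[1])

    def test_mismatched_split_seeds_rejected(self, rng):
        a = self._result(rng, "a", pr.derive_split_seeds(0, 30))
        b = self._result(rng, "b", pr.derive_split_seeds(1, 30))
        with pytest.raises(ValueError):
            pr.compare_models([a, b])


class TestAblation:
    def test_ten_groups(self, partition):
        groups = pr.ablation_groups(partition)
        assert len(groups) == 10
        names = set(groups)
        assert {"internetwork", "left_hemisphere", "right_hemisphere"} <= names
        # network groups have 3 blocks; hemisphere groups have 8
        assert all(len(g) == 3 for n, g in groups.items()
                   if n not in ("internetwork", "left_hemisphere", "right_hemisphere"))
        assert len(groups["internetwork"]) == 2
        assert len(groups["left_hemisphere"]) == len(groups["right_hemisphere"]) == 8

    def test_group_with_no_columns_rejected(self, rng):
        fm = pr.FeatureMatrix(
            values=rng.normal(0, 1, (20, 3)),
            provenance=pd.DataFrame(
                {"block_id": [0, 1, 2], "label": "x", "component": 0,
                 "evr_share": 0.3}
            ),
            variance_threshold=0.2,
        )
        with pytest.raises(ValueError):
            pr.drop_feature_group(fm, {99})
        with pytest.raises(ValueError):
            pr.drop_feature_group(fm, {0, 1, 2})

    def test_ablation_correction_factor_30(self, fa_matrices, partition, rng):
        fm = pr.assemble_features(fa_matrices, partition, "subnetworks", 0.2)
        bm = pr.block_mean_table(fa_matrices, partition)
        eff = pr.default_planted_effect(partition, noise_sd=0.05)
        scores = cw.generate_scores(bm, eff, seed=1)
        spec = pr.ModelSpec(n_trees=10, max_depth=2)
        full, results = pr.ablation_importance(
            fm, partition, scores, spec, n_iter=4, seed=0
        )
        assert len(results) == 10
        assert all(0.0 <= res.p_corrected <= 1.0 for res in results)


class TestTuning:
    def test_grid_has_24_cells_and_is_deterministic(self, rng):
        x = rng.normal(0, 1, (24, 4))
        y = 100 + 10 * x[:, 0] + rng.normal(0, 1, 24)
        fm = pr.FeatureMatrix(
            values=x,
            provenance=pd.DataFrame({"block_id": np.zeros(4, int), "label": "b",
                                     "component": range(4), "evr_share": 0.25}),
            variance_threshold=0.2,
        )
        eta, n_trees, grid = pr.tune_hyperparameters(fm, y, n_folds=4, seed=0)
        assert len(grid) == 24
        assert set(grid["n_trees"]) == {10, 50, 100, 200, 300, 500}
        assert set(grid["eta"]) == {0.005, 0.01, 0.05, 0.1}
        # plateau rule: chosen cell within tolerance of the minimum
        assert grid.loc[
            (grid["n_trees"] == n_trees) & (grid["eta"] == eta), "mae"
        ].iloc[0] <= grid["mae"].min() * 1.02
        eta2, n2, grid2 = pr.tune_hyperparameters(fm, y, n_folds=4, seed=0)
        assert (eta, n_trees) == (eta2, n2)
        pd.testing.assert_frame_equal(grid, grid2)

    def test_too_few_subjects_rejected(self, rng):
        x = rng.normal(0, 1, (10, 3))
        fm = pr.FeatureMatrix(
            values=x,
            provenance=pd.DataFrame({"block_id": [0, 0, 0], "label": "b",
                                     "component": range(3), "evr_share": 0.3}),
            variance_threshold=0.2,
        )
        with pytest.raises(ValueError):
            pr.tune_hyperparameters(fm, np.zeros(10))
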