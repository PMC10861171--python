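# connweight

Weighted structural connectome comparison and cognition prediction.

The way edges of the human structural connectome are weighted — number of
tractography streamlines (NOS), mean fractional anisotropy (FA), or mean
axon diameter distribution index (ADD) — changes the network you end up
analyzing. `connweight` is a toolkit for studying exactly that: it builds
all three weighted connectomes per subject from streamline-level data,
makes them comparable by histogram matching, characterizes them with graph
measures, and asks which weighting best predicts a cognitive composite
score. A seeded synthetic-cohort generator with the same statistical
structure (distance-decaying connection counts, signed weight–distance
couplings, between-subject regional variability, planted score effects)
makes every stage testable without restricted imaging data.

## What it computes

For subjects s with streamline tables {(i, j, FA, ADD)} over an N-region
bilateral 7-network atlas:

- **Connectomes** — W^NOS_ij = #streamlines(i,j); W^FA_ij, W^ADD_ij = mean
  scalar over those streamlines; Dist_ij = ‖c_i − c_j‖₂.
- **Normalization** — quantile mapping of each matrix's nonzero weights
  onto the subject's NOS distribution; mapped values < 1 are excluded.
- **Group matrices** — per-edge mean over subjects (zeros excluded) with
  modified-z MAD outlier rejection (|x − med|·0.6745/MAD > 3.5).
- **Graph measures** — node strength Σ_j w_ij; nodal efficiency
  1 / mean_j d(i,j) on 1/w edge lengths; Pearson r of ln w vs distance.
- **Communities** — resolution-γ Louvain (Q(γ) = (1/2m)Σ[w_ij −
  γ s_i s_j/2m]δ) sampled at 1000 log-spaced γ inside the range giving
  4 to N/4 communities, aggregated into an agreement matrix, thresholded
  at τ = 0.2, and re-clustered to consensus.
- **Small-world propensity** — Φ = 1 − √((δ_C² + δ_L²)/2) against lattice
  and random nulls that preserve degrees and the weight multiset; Φ > 0.6
  is the conventional small-world criterion.
- **Prediction** — edges split into 23 functional subnetwork blocks
  (3 per network + 2 between-network), per-block PCA components covering a
  variance threshold, gradient-boosted regression (squared error, L1 α = 1)
  on a mean-100/SD-15 composite score, evaluated over many shared 80/20
  splits with paired Wilcoxon model comparisons and subnetwork-ablation
  importance (10 groups, correction ×30).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import connweight as cw
from connweight import prediction as pr

# 1. simulate a cohort: 30 subjects, 200 regions, 40,000 streamlines each
cfg = cw.CohortConfig(n_subjects=30, seed=0)
atlas, tables = cw.generate_cohort(cfg)
n = atlas.n_nodes
dist = cw.build_distance(atlas)

# 2. per-subject connectomes, histogram-matched to each subject's NOS
nos = [cw.build_nos(t, n) for t in tables]
fa = [cw.build_mean_scalar(t, "fa", n) for t in tables]
matched_fa = [cw.histogram_match(m, ref) for m, ref in zip(fa, nos)]
group_fa = cw.group_average(matched_fa)
r, p, n_edges = cw.edge_distance_correlation(group_fa, dist)
print(f"FA log-weight vs distance: r = {r:+.3f} (p = {p:.2g}, {n_edges} edges)")

# 3. small-world propensity of one subject's original NOS connectome
res = cw.swp(nos[0], n_nulls=5, seed=0)
print(f"NOS small-world propensity: phi = {res.phi:.3f} "
      f"(delta_C = {res.delta_c:.3f}, delta_L = {res.delta_l:.3f})")

# 4. plant a left-hemisphere effect and compare prediction models
partition = pr.partition_subnetworks(atlas)
scores = cw.generate_scores(
    pr.block_mean_table(fa, partition),
    pr.default_planted_effect(partition), seed=1,
)
spec = pr.ModelSpec(max_depth=3)
feats_sub = pr.assemble_features(fa, partition, "subnetworks", 0.2)
feats_wb = pr.assemble_features(fa, partition, "whole_brain", 0.3)
res_sub = pr.fit_and_evaluate(feats_sub, scores, spec, n_iter=50, seed=2,
                              label="FA subnetworks")
res_wb = pr.fit_and_evaluate(feats_wb, scores, spec, n_iter=50, seed=2,
                             label="FA whole-brain")
table = pr.compare_models([res_sub, res_wb])
print(f"subnetworks model: median held-out r = {res_sub.median_r:.3f}")
print(f"whole-brain model: median held-out r = {res_wb.median_r:.3f}")
print(f"paired Wilcoxon (corrected): p = {table['p_corrected'].iloc[0]:.2g}")
```

Output:

```
FA log-weight vs distance: r = +0.927 (p = 0, 19900 edges)
NOS small-world propensity: phi = 0.525 (delta_C = 0.651, delta_L = 0.162)
subnetworks model: median held-out r = 0.474
whole-brain model: median held-out r = -0.018
paired Wilcoxon (corrected): p = 1.3e-05
```

The FA group connectome shows the positive log-weight/distance relation the
generator plants (FA rises with tract length); this subject's NOS network
sits between lattice and random regimes (Φ ≈ 0.53); and because the score
effect lives in specific left-hemisphere subnetwork blocks, the 23-block
subnetworks model recovers it (median held-out r ≈ 0.47) while whole-brain
PCA at the same budget does not — a significant difference under the paired
Wilcoxon test on shared splits.

## Command line

The same pipeline runs from a YAML/JSON config:

```sh
connweight run --config config.yaml --outdir out/ --seed 1
connweight smallworld --config config.yaml --outdir out/
```

Stages: simulate, build, normalize, metrics, communities, smallworld,
predict, ablate. Each run writes a `manifest.json` with the config
snapshot, seeds, and output hashes; reruns reproduce identical hashes.

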