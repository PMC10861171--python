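# Methods

`connweight` implements a complete desk-scale pipeline for comparing
differently weighted structural connectomes and for predicting a cognitive
composite score from them. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic cohort does and
does not emulate.

## Weighted connectomes

A structural connectome is an undirected graph over N parcellated brain
regions. From a per-subject streamline table (endpoint pair, mean FA, mean
ADD per streamline) the package builds four N×N matrices:

- **NOS** — number of streamlines joining each region pair (integer counts);
- **FA** — arithmetic mean fractional anisotropy over the pair's
  streamlines (unitless, in (0,1));
- **ADD** — arithmetic mean axon-diameter-distribution index (µm);
- **DIST** — Euclidean distance between region centroids (mm).

All matrices are symmetric with a zero diagonal; FA and ADD are nonzero
exactly where NOS is nonzero; node ids are 0-based everywhere.

## Histogram matching

The three weightings live on incommensurable scales, so for network
property analyses FA and ADD (and, trivially, NOS) are quantile-mapped onto
the subject's own NOS weight distribution: nonzero entries are ranked (ties
share their average rank) and replaced by the linearly interpolated
empirical quantile of the reference's nonzero entries. Mapped values below
1 are zeroed — on the count scale a weight below one streamline is no
connection. Matching operates on nonzero entries only: the matrices are
sparse and the exclusion rule is only meaningful on supported edges.
Quantile mapping was chosen over bin-histogram matching because it aligns
the cumulative distributions exactly and is resolution-free. Matching is
monotone, so edge rankings within a matrix are preserved and no new edges
are ever created.

## Group averaging

Group matrices are the per-edge mean of nonzero subject values after
excluding outliers by modified z-score |x − median|·0.6745/MAD > 3.5
(threshold configurable; 3.5 and the 0.6745 consistency constant are the
standard recommendation of the outlier-detection literature). When an
edge's MAD is zero, values at the median are kept and any deviant value is
treated as infinitely deviant and excluded; an edge with no surviving
values is zero.

## Graph measures

- **Node strength**: sum of incident edge weights.
- **Nodal efficiency**: edge lengths are reversed weights ℓ = 1/w (the
  scale-free convention; stronger connections are shorter), shortest paths
  are Dijkstra's, and a node's efficiency is the reciprocal of its mean
  distance to the other nodes. Unreachable pairs are excluded from the mean
  (and logged) rather than treated as infinite, keeping the statistic
  finite on sparse subjects; a fully isolated node scores 0. Efficiency
  therefore scales linearly with a global weight rescaling.
- **Edge-weight/distance relation**: Pearson r between ln(weight) and
  centroid distance over supported edges of the *histogram-matched
  group-average* matrix (one sample per edge; natural log, since the base
  only rescales and leaves r unchanged). Whether to pool edges across
  subjects or use group matrices was genuinely open; the group-matrix
  choice is the default and the function accepts any matched matrix.

## Community detection

Communities are found on group-averaged, histogram-matched matrices with
resolution-parameterized Louvain (weighted Newman–Girvan modularity,
Q(γ) = (1/2m)Σ[w_ij − γ s_i s_j/2m]δ(c_i,c_j)) followed by a greedy
refinement: single-node modularity moves until stable, plus a best
pairwise label exchange to escape interleaved local optima that single
moves cannot leave. The protocol:

1. **Gamma range**: geometric expansion plus bisection (fixed seed) finds
   the smallest γ whose partition has more than 3 communities and the
   largest with fewer than N/4 (counts in [4, ⌈N/4⌉−1], the strict reading
   of "between 4 and N/4"); ties at the boundaries break toward the wider
   range.
2. **Sampling**: 1000 partitions at log-uniformly spaced γ (exponential
   sampling) with per-sample derived seeds.
3. **Consensus**: co-classification (agreement) matrix; entries below
   τ = 0.2 zeroed; Louvain at γ = 1 re-run over 100 seeded restarts
   (configurable — the restart count per consensus iteration is not
   standardized anywhere); iterate agreement → threshold → cluster until
   all restarts agree, with an iteration cap of 50 (empirically convergence
   takes a handful of rounds; the cap guards against adversarial inputs).

## Small-world propensity

Φ quantifies joint deviation of clustering and path length from matched
lattice and random nulls:

    δ_C = clip((C_latt − C_obs)/(C_latt − C_rand), 0, 1)
    δ_L = clip((L_obs − L_rand)/(L_latt − L_rand), 0, 1)
    Φ   = 1 − sqrt((δ_C² + δ_L²)/2)

C is the mean Onnela weighted clustering coefficient (geometric mean of
triangle weights, scaled by the global maximum weight); L is the mean
shortest-path length on 1/w lengths over reachable pairs. Both ratios are
scale-free, so Φ is invariant to global weight rescaling. Φ > 0.6 is the
conventional small-world criterion; a network that is its own ring lattice
has δ_C ≈ 0, δ_L ≈ 1 and Φ ≈ 1 − √(1/2) ≈ 0.293.

Null models preserve node count, edge count, and the exact weight multiset.
The random null rewires the binary topology with degree-preserving
double-edge swaps and reassigns the weights uniformly at random to the
surviving edges. The lattice null re-lays the edges on a ring with the
largest weights at the smallest ring distances (a banded matrix); the
precise banded construction is not standardized, and this minimal
ring-distance placement is the package's documented choice. Null statistics
are averaged over 10 realizations per family by default (variance reduction
at desk-scale cost). Φ is computed on original, pre-matching matrices —
enforced by asserting the `normalized` flag is false. Group comparison uses
one-way repeated-measures ANOVA across the three weightings plus three
paired t tests, Bonferroni-corrected ×3.

## Cognition prediction

The prediction target is a cognitive composite on the normed scale of the
NIH-Toolbox total composite (mean 100, SD 15).

**Subnetwork blocks.** Edges are split by the 7 functional networks and
hemisphere into 23 blocks: per network, left-intra, right-intra, and
inter-hemispheric-within-network (21 blocks), plus a left and a right
between-network block. Between-network inter-hemispheric edges belong to no
block and are excluded from subnetwork models; whole-brain models use all
edges.

**Features.** Original (unmatched) matrices only. Per subject the
upper-triangle vector is divided by its total weight, then z-scored
("normalized and standardized" read as sum-normalization followed by
per-subject standardization; both steps are part of `prepare_features`).
Each block (or the whole edge set) is reduced by PCA to the minimal number
of components whose cumulative explained variance reaches the threshold
(default 20% per subnetwork, 30% whole-brain). PCA is fit on the full
cohort before splitting, mirroring the described analysis order; note this
leaks unsupervised structure across splits — a leakage-safe variant would
refit PCA per training fold, and the package deliberately does not default
to it so results remain comparable with the reference procedure.

**Learner.** Gradient-boosted regression trees (XGBoost), squared-error
loss, L1 leaf regularization α = 1, defaults eta = 0.05 and 200 rounds (the
plateau of the tuning grid), max_depth 6 (not dictated by the procedure;
recorded in the run manifest). Hyperparameters are tuned by 10-fold CV mean
MAE over the 6×4 grid n ∈ {10,50,100,200,300,500} × eta ∈
{0.005,0.01,0.05,0.1}; the chosen cell is the smallest (n, then eta) within
2% of the grid-minimum MAE, operationalizing "the plateau of the curve".
Tuning is done once per (weight kind, mode) when used.

**Evaluation and comparison.** 1000 (configurable) random 80/20 splits;
held-out Pearson r per split. Split seeds derive from the master seed so
different models see identical splits, making per-iteration r vectors
pairable; `compare_models` verifies seed identity and applies paired
Wilcoxon signed-rank tests with Bonferroni correction by the number of
pairs (6 models → 15). Iterations with constant test-set truth have
undefined r, are recorded as missing, and are dropped pairwise (logged).

**Ablation importance.** For the subnetworks model at the 20% threshold,
10 feature groups are removed in turn: each network's 3 blocks, the 2
between-network blocks, and each hemisphere's 8 blocks (7 intra + its
between-network block). Each ablated model is re-evaluated on shared splits
(100 by default) and tested against the full model; correction ×30
(10 groups × 3 weightings).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes —
it simulates no diffusion signal, voxels, streamline geometry, or cortical
anatomy, and all distributional choices are stand-ins:

- **Atlas**: 100 nodes per hemisphere, 7 networks assigned round-robin;
  each network is a spatial cluster (8 mm jitter around a network center)
  so same-network nodes are nearer each other than across networks; the
  right hemisphere mirrors the left's cluster geometry. Left x < 0,
  right x > 0.
- **Streamlines**: 40,000 per subject; endpoint pairs drawn with
  probability ∝ exp(−λ·d), λ = 0.015/mm — a one-parameter decay that
  reproduces the negative count–distance relation of tractography.
- **Edge scalars**: FA is logit-normal, ADD log-normal (each respects its
  support), with latent-scale distance couplings of +0.008/mm (FA) and
  −0.004/mm (ADD), giving the characteristic sign pattern: FA rises and
  counts and ADD fall with distance.
- **Between-subject variability**: a global multiplicative factor per
  subject per modality (SD 0.02 on the latent scale), applied on the logit
  scale for FA (multiplicative on odds) and log scale for ADD
  (multiplicative on values), plus per-subject per-node latent offsets
  (SD 0.4) emulating regional microstructure profiles; a streamline
  inherits the mean offset of its endpoints. The regional term is
  essential: a purely global factor produces rank-1 between-subject
  structure that per-subject standardization removes entirely, leaving
  block PCA nothing but isotropic sampling noise — no planted signal would
  be recoverable, which real cohorts (where regional microstructure varies
  coherently between subjects) do not resemble.
- **Scores**: a planted linear combination of subnetwork block means plus
  Gaussian noise, normed to sample mean 100 / SD 15. Block means are taken
  over the *prepared* (normalized, standardized) edges by default, so the
  planted dependence refers to the representation the models consume. The
  canonical recovery condition (`default_planted_effect`) puts unit
  coefficients on the left-hemisphere intra blocks of three networks with
  noise SD 0.12, sized so the full subnetworks model reaches moderate
  (median r ≈ 0.4) held-out accuracy at the generator defaults.
- **Determinism**: per-subject seeds are master seed + subject index; the
  same configuration reproduces the cohort bytewise.

Because subjects are exchangeable, noise is Gaussian on latent scales, and
regional effects are unstructured, passing tests demonstrate the
*machinery* — construction, normalization, statistics, model comparison and
ablation logic — not that the pipeline's effect sizes or accuracies
transfer to real imaging cohorts.

## Problem sizes and numerics

Tests run the full pipeline at reduced scale (tens of subjects, 28–40
nodes, thousands of streamlines) and the recovery study at 120 subjects,
200 nodes, 200 shared splits — sizes chosen so the whole suite runs on a
single CPU in minutes while keeping every statistic in its intended regime.
Tolerances: builders match oracles to 1e−12; shortest-path and matching
oracles to 1e−9; modularity recomputation to 1e−12. Degenerate inputs
(all-zero matrices, constant weight vectors, empty blocks, missing values)
raise errors rather than propagate NaNs.

## Known limitations

- The connectome is treated as undirected; real axonal projections are not.
- The lattice-null banding and the consensus restart count are documented
  package choices, not community standards.
- Whole-cohort PCA leaks across evaluation splits (kept for comparability;
  see above).
- The generator's unstructured regional variability cannot produce realistic
  network topology differences between weightings (e.g. genuinely bilateral
  vs unilateral community structure); community-detection outputs on
  synthetic cohorts are only exercised for protocol correctness.
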