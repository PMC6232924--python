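# Methods

## Network construction

For one subject and hemisphere, the input is an `n_r × n_v` table of mean
cortical-attribute values (default attributes: maximum principal curvature,
mean cortical thickness, mean sulcal depth, mean average curvature; mm for
thickness/depth, 1/mm for curvatures). Each attribute yields a low-order
view `X^k_ij = |x_i^k − x_j^k|` — symmetric, zero-diagonal, nonnegative,
and invariant to adding a constant to all ROIs of an attribute. ROI pairs
are ordered lexicographically (i < j, 0-based); feature vectors take the
strict upper triangle row-major, views concatenated view-by-view for the
low-order (CON) signature.

The high-order network correlates the length-`n_v` edge vectors of two ROI
pairs with Pearson's r. With the default `n_v = 4` each correlation is
computed over only four points; this is deliberate — the high-order
representation is defined across views, not across subjects — and is the
main reason HON features are individually noisy. The HON diagonal is set to
zero inside the matrix (the feature vector excludes it anyway). An edge
vector that is constant across views has no defined correlation; by default
its row/column is set to 0 (no evidence of co-variation) with a warning,
or, under `degenerate_policy="error"`, construction aborts naming the pair.
Entries are clipped to [−1, 1] against floating-point overshoot.

No cross-subject standardization is applied before network construction:
the networks are absolute differences of raw attribute means.

## Kernel bank

Subject similarity starts from adaptive-bandwidth Gaussian kernels

    K(h_i, h_j) = (1 / (ε_ij √(2π))) exp(−‖h_i − h_j‖² / (2 ε_ij²)),
    ε_ij = σ (μ_i + μ_j) / 2,

with `μ_i` the mean Euclidean distance from subject i to its k nearest
neighbors (self excluded). Norms are Euclidean. The default grid
σ ∈ {1.0, 1.25, …, 2.5} × k ∈ {10, 12, 14} gives m = 21 kernels, ordered
σ-major. Duplicate subjects give μ = 0; ε is floored at 1e−12 × the mean
pairwise distance (or 1e−12 when all distances vanish) so duplicates yield
a large finite density rather than an infinity.

Because of the 1/(ε√(2π)) prefactor, raw kernels at different bandwidths
live on incommensurable scales, so every kernel is degree-normalized
(`D^{−1/2} K D^{−1/2}`, symmetrized) before entering the optimizer; the
largest eigenvalue of a normalized kernel is ≤ 1, making the fit,
regularization and Laplacian terms of the objective comparable.

## Similarity learning

The objective

    F(S, L, w) = −Σ_l w_l ⟨K_l, S⟩ + β‖S‖_F² + γ tr(Lᵀ(I_n − S)L)
                 + ρ Σ_l w_l log w_l

is minimized under row-stochastic S, orthonormal L (n × c), and simplex w,
by exact alternating block updates:

* **L** — the c bottom eigenvectors of the Laplacian of (S + Sᵀ)/2 (the
  objective value is invariant to this symmetrization and to rotations of
  L's columns);
* **w** — the entropic closed form `w_l ∝ exp(⟨K_l, S⟩ / ρ)`, computed with
  max-subtraction;
* **S** — row-wise Euclidean projection of `a_i / (2β)` onto the
  probability simplex, `a_ij = Σ_l w_l K_l(i,j) + γ (LLᵀ)_ij` (the row
  subproblem is a diagonal simplex QP with this exact solution).

S is initialized as the row-normalized uniform average of the normalized
kernels, w as uniform. Each update is an exact minimizer of its block, so
the objective trace is monotone non-increasing over full cycles when graph
diffusion is off — this is asserted in the tests. Optional diffusion
(default: one step through the row-truncated top-knn graph, knn = median of
the k grid) strengthens weak within-cluster links at the cost of that
guarantee; truncation uses a stable sort so ties resolve deterministically.
Convergence is declared at relative objective change ≤ 1e−6 (default
`max_iter = 30`; a run that has not met the tolerance returns its last
state with a warning — at the package's problem sizes each cycle is
milliseconds, so `max_iter` can simply be raised when the warning matters).

β, γ, ρ default to 0.8, 1.0, 1.0 — chosen so that on degree-normalized
kernels (entries and spectra of order one) no single term dominates; all
three are exposed in every interface and logged with each run.

**Degenerate input.** When every kernel in the bank is a constant matrix
(e.g., all subjects identical), the bottom eigenspace of the uniform
Laplacian is degenerate and alternating updates would break the symmetry in
a direction chosen arbitrarily by the eigensolver. The fit detects this
case and returns the maximum-entropy uniform similarity (with a warning)
instead of solver-determined spurious structure.

Given S and L: k-means (50 seeded restarts) on L's rows assigns the c
clusters; t-SNE embeds S in 2-D for visualization, feeding the symmetrized,
globally normalized S in directly as the joint-probability affinity matrix
(standard KL gradient descent with a Student-t low-dimensional kernel,
early exaggeration 12 for the first half of 500 iterations, learning rate
200, momentum 0.5→0.8, seeded 1e−4 Gaussian initialization — deterministic
given the seed).

## Evaluation protocol

The *performance rate* of a clustering against binary labels is
majority-mapped purity: each cluster maps to its majority label and the
rate is `1 − misclassified/n`. It is invariant to cluster relabeling and
lower-bounded by the majority-class proportion. The harness shuffles and
splits the cohort into k folds (k = 5 or 10), re-runs the method per fold —
clustering methods cluster the training portion into c = 4 groups and
score purity there; supervised methods score held-out accuracy — and
averages over folds, then over 20 repeats. All sub-seeds derive from one
integer, and two executions are bit-identical.

Because clusters are finite, the purity of *random* labels exceeds the
majority proportion (for c = 4 balanced clusters of ~12 at n_train = 48 the
null mean is ≈ 0.60, not 0.50). The package therefore ships
`permutation_null_rate`, the same harness with labels permuted per repeat,
as the correct chance level; null-cohort tests compare against it rather
than the raw majority share.

An optional `score_heldout` mode also labels the held-out fold: test
subjects are assigned to the nearest training-cluster centroid and take
that cluster's majority label. Centroids live in feature space — the
spectral latent has no out-of-sample coordinates without a Nyström-type
extension, which is out of scope — and the mode is off by default.

## Feature ranking

`LS(f) = fᵀSf / fᵀf` scores each feature column against the symmetrized
learned similarity; high scores mean the feature varies smoothly over
strongly similar subjects. Under a row-stochastic S a constant feature
scores exactly 1.0 regardless of the data, so features are mean-centered
across subjects before scoring by default (a raw mode exists). Scores are
scale-invariant per column. Ranking is descending (most concordant first)
with ties to the lower index; an ascending export is available since the
original graph-Laplacian formulation of the score ranks ascending. The S
used for ranking is the one learned on the full cohort. Ranked positions
resolve to named ROI pairs/attributes through the feature index maps.

## Ensemble classifiers

`ClusterPairingSVC` splits each class into c subgroups — via the similarity
learner or Ward's linkage — pairs every subgroup of one class with every
subgroup of the other (≤ c² pairings; empty subgroups are dropped, a class
smaller than c gets fewer subgroups with a warning), trains one linear SVM
(C = 1) per pairing, and predicts by majority vote. Exact vote ties break
on the sign of the summed signed margins; a summed margin of exactly zero
goes to the lexicographically later class (NC for ASD/NC labels). Each
member's within-pairing leave-one-out accuracy is recorded as a
diagnostic. Pairings of unequal subgroup sizes are inherently imbalanced —
a known weakness of cluster-pairing ensembles — so members use
inverse-frequency class weighting by default; the baseline SVM is built by
the same factory with the same weighting, which makes the c = 1 ensemble
*identical* to the baseline on any cohort (asserted in tests). Setting
`class_weight=None` on both disables the reweighting.

## Synthetic cohorts

The generator emulates the shape of a FreeSurfer-style cohort: two
diagnostic groups, per-subject ROI × attribute tables, attribute scales
differing by orders of magnitude (template means/spreads: curvatures
0.13 ± 0.03 and 0.03 ± 0.015 1/mm, thickness 2.6 ± 0.35 mm, sulcal depth
1.6 ± 0.5). Measurement noise is iid Gaussian per cell with a single SD
(`noise_sd`, default 1.0; optionally Student-t with 3 df scaled to the same
SD), and all planted effects are expressed in units of that SD: the group
effect shifts every cell of group 1's template by `separation` SDs times a
random standard-normal pattern (a *common* shift would be invisible to
absolute-difference networks), subgroups shift analogously by
`subgroup_separation`, and `plant_discriminative_edge` moves exactly one
ROI pair's attribute difference by `effect` (± effect/2 on the two ROIs,
with the pair's template values repositioned about their midpoint at a gap
of (effect + 8) SDs so the absolute difference is sign-stable). Because an
edge is a function of two ROI values, a mean shift that moves one pair
necessarily moves edges incident to either ROI by half the effect; the
construction tests assert exactly this full/half/zero shift pattern. The
default scale — 60 subjects (30 + 30), 12 ROIs, 4 attributes, P = 66 pairs,
2145 high-order features — keeps the complete high-order path at a few
seconds per fit.

What the generator does *not* emulate: cortical geometry, site/scanner
batch effects, attribute-specific noise correlations, or age/sex structure.
Passing the synthetic benchmarks demonstrates the machinery — construction
correctness, optimizer contracts, recovery under planted signal, honest
null behavior — not clinical performance on real cohorts.

## Known limitations and observed behavior

* High-order correlations over n_v = 4 views are individually unstable;
  they are informative in aggregate.
* Laplacian-score ranking uses the similarity learned from the same
  features, so features that shaped S are favored; on planted-edge cohorts
  the top-1 feature is occasionally an edge *incident* to the planted pair
  (which necessarily carries half the planted effect) rather than the
  planted edge itself — the planted attribute/locus is recovered
  essentially always, the exact edge in roughly four of five draws at a
  5-SD effect.
* The cluster-purity statistic is biased upward for finite clusters; always
  read it against the permutation null the package computes.
* The alternating optimizer guarantees monotone descent only with diffusion
  off; with diffusion the trace can fluctuate (convergence is then a fixed
  point of the full cycle).
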