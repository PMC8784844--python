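# Methods

## Model

LSSD (local-scaling self-diffusion) denoises a cell–cell similarity graph
built from an scRNA-seq expression matrix and clusters cells on the
denoised graph. It has three stages.

**1. Local-scaling affinity.** From Euclidean distances d(x_i, x_j) over
genes, the affinity is

    W(i, j) = exp( −d²(x_i, x_j) / (σ_i σ_j) ),

where σ_i = d(x_i, x_K) is the distance from cell i to its K-th nearest
*other* cell (default K = 5). Dividing by the product of the two local
scales makes W exactly invariant to a uniform rescaling of the input
coordinates (the d² and σ_i σ_j factors both pick up c²) and adapts the
bandwidth to local density. Self is excluded from the neighbor ranking,
otherwise σ_i would always be 0. If duplicated cells still make σ_i = 0 it
is replaced by the smallest positive distance in the row (or by
1e−12 · max(D) when the whole row is zero) with a warning; crashing on
duplicate barcodes would be worse than a repaired scale.

**2. Self-diffusion.** A row-stochastic transition operator restricted to
each cell's k strongest edges,

    P(i, j) = W(i, j) / Σ_{l ∈ knn(i)} W(i, l)   for j ∈ knn(i), else 0,

drives the iteration, starting from S₀ = W,

    S_{t+1} = τ · S_t P + (1 − τ) · I.

Each step propagates similarity mass along locally reliable edges; the
(1 − τ) I term anchors the walk so the iteration does not converge to a
rank-one blur. Weak spurious edges — absent from the KNN support — decay
geometrically, while paths inside a cluster reinforce each other. S_t is
asymmetric (P is row-normalized), so the spectral stages consume
(S + Sᵀ)/2.

**3. Spectral clustering.** Normalized-cut style: the C eigenvectors of
L_sym = I − D^{−1/2} S D^{−1/2} with smallest eigenvalues are
row-normalized to unit length and partitioned by k-means (k-means++
initialization, 25 restarts, fixed seed, at most 5 re-seedings if an empty
cluster appears). Labels are relabeled to first-appearance order so runs
are bitwise reproducible given (S, C, seed).

## Parameters

| name | default | meaning |
|---|---|---|
| `k_scale` | 5 | neighbor rank defining the local scale σ_i |
| `knn` | min(30, n−1) | support size of the transition operator P |
| `tau` | 0.8 | diffusion retention weight, must lie in (0, 1) |
| `steps` (t) | 4 | number of diffusion iterations |
| `cmin`, `cmax` | 2, 15 | scan range for cluster-number estimation |
| `seed` | 0 | k-means / simulation seed |

`k_scale` and `knn` play different roles and are deliberately decoupled:
one tunes a bandwidth, the other the walk's support. Tying both to 5 makes
P pathologically sparse at realistic n. The transition support must stay
local relative to cluster size — if `knn` exceeds the smallest cluster, P
necessarily carries mass across clusters and diffusion blurs rather than
denoises; this is visible already on a 40-cell two-block toy, where the
within/between similarity contrast improves for knn ≤ 10 and degrades for
knn ≥ 15. τ has no canonical value; on separable data results are flat
over τ ∈ [0.5, 0.9]. t trades denoising against over-smoothing; t = 4 is
the default and the iteration-step sweep (`lssd sweep-steps`) reproduces
the reasoning on simulated data.

## Cluster-number estimation

For each candidate C, the n×C matrix X of top Laplacian eigenvectors is
row-normalized and rotated by R (a product of C(C−1)/2 Givens rotations)
to minimize the separation cost

    J(R) = Σ_i Σ_j Z(i,j)² / M_i²,   Z = X R,   M_i = max_j |Z(i,j)|.

J ≥ n always, with equality exactly when every row has a single nonzero —
an indicator matrix. M uses |Z| because eigenvector signs are arbitrary.
The optimizer is gradient descent on the Givens angles (analytic gradient
with the per-row argmax held locally constant, fixed step 0.1 on J/n with
halving on non-decrease, tolerance 1e−7, 200 iterations). The cost is
non-convex; a single start from zero angles stalls on saddles often enough
to distort the J*(C) curve by ~10% of n, so the scan takes the best of a
warm start (the optimum of C−1, exploiting that the Givens angle vector
for C columns is a prefix of the one for C+1), a zero start, and six
seeded random starts. `optimal_rotation` called directly performs the
single documented descent.

**Selection rule.** The scan always starts at C = 2 and is anchored by the
identity J*(1) = n (one column is always a perfect indicator). Candidates
are first restricted to the bottom fifth of the observed J* range — a
credible cluster count must itself be a near-indicator solution — and
among those the chosen C maximizes

    score(C) = [J*(C−1) − J*(C)] + [J*(C+1) − J*(C)],

the negative curvature of the cost curve, i.e. the largest drop measured
against the local trend. The drop term alone is unreliable on connected
graphs, where merging well-separated clusters is costless and J* is
flat-minimal for every C below the true count; the rise term alone is
shallow when an extra eigenvector splits a cluster almost cleanly. Their
sum identifies the elbow in both regimes; ties break toward the smaller C
(parsimony). On exact block-diagonal affinities this recovers 2–10 equal
blocks across independent weight draws, and it returns 6 on a six-group
simulated dataset.

Cells whose eigenvector rows are numerically zero (only possible when the
graph is exactly disconnected and C is below the number of components) are
excluded from the rotation and charged the worst-case per-row cost C.

**Known limitation.** On exactly disconnected graphs the zero eigenvalue
is degenerate and "the first C eigenvectors" is an arbitrary basis choice
of the eigensolver; J*(C) for C below the component count is then genuinely
basis-dependent, and can change under a permutation of the cells. On
connected graphs (every diffused graph in practice) eigenvalues are simple
and the scan is permutation-invariant.

## Synthetic data

`simulate_counts` generates grouped counts with known labels following the
standard structure used for clustering benchmarks: per-gene base means
λ_g ~ Gamma(shape 0.6, rate 0.3); per group, each gene is differential
with probability `de_prob` (default 0.1) and receives a multiplier
exp(±N(`de_fac_loc`, `de_fac_scale`)) (defaults 1.0, 0.4) with random
sign; group profiles are normalized and scaled per cell to a library size
L_c ~ LogNormal(11, 0.2) (mean ≈ 60k counts); counts are gamma–Poisson
(negative binomial) with dispersion bcv² (bcv = 0.2); finally an entry is
zeroed with probability logistic(−(log μ − 1.5)) — logistic dropout, hitting
weakly expressed genes hardest. Everything is driven by one seed.

What this emulates: overdispersed grouped counts, uneven library sizes,
and expression-dependent dropout — the features that break naive Euclidean
similarity. What it does not emulate: mean-dependent dispersion trends
(dispersion is a single constant), batch effects, trajectories/doublets,
and gene–gene correlation beyond group structure. Tests passing on these
simulations therefore demonstrate the pipeline's behavior under clean
group-structured noise, not performance on any particular real dataset.
The default settings give well-separated groups (the regime in which the
published simulation benchmarks report NMI/ARI ≈ 0.99); `hard_params()`
lowers the DE factor (0.6) so that the benefit of increasing diffusion
steps is visible in `sweep-steps`.

Problem sizes used by the packaged experiments: the headline run uses
2,000 cells × 2,000 genes × 10 groups (3 seeds, median reported); the
size-stability sweep uses n ∈ {1,000, 2,000, 5,000} at 2,000 genes; the
cluster-number surfaces use 20-cell blocks and a 600-cell six-group
simulation.

## Numerical choices

- Distances use the Gram-matrix expansion in double precision with
  clipping at 0 and explicit symmetrization; exact neighbor ranking (no
  approximate NN) up to the 10⁴-cell scale.
- P is held sparse (≤ knn nonzeros per row); S @ P is a dense×sparse
  product, keeping each diffusion step O(n²·knn).
- Eigenvectors: dense `eigh` for n ≤ 800 (or when C_max > n/4), otherwise
  Lanczos (`eigsh`) with a fixed all-ones start vector for determinism;
  columns get a deterministic sign (largest-magnitude entry positive).
- Matrices read from disk are held sparse when more than half the entries
  are zero; Matrix Market indices convert to 0-based at the boundary only.
- Degenerate inputs: duplicate cells repair σ (warning); zero-degree cells
  are a hard error naming the cell; t = 0 returns W unchanged; an empty
  label vector refuses to write a file.

## Design choices made where the construction was open

- Dispersion for highly-variable-gene selection is computed on counts as
  read (variance-to-mean is a count-scale statistic), with the unbiased
  (n−1) variance and ties broken by gene index. HVG selection and log1p
  are both off by default; the benchmark pipeline runs on the full matrix.
- Self is excluded from knn(i) in P; the (1 − τ) I term already restores
  self-similarity.
- Spectral clustering consumes the symmetrized diffused graph; the
  normalized-cut (row-normalized eigenvector) variant is used.
- NMI is normalized by the arithmetic mean of the entropies.

## Limitations

Beyond the degenerate-graph caveat above: the pipeline is O(n²) in memory
(dense similarity matrices), appropriate up to ~10⁴ cells; no
library-size normalization, imputation or batch correction is performed
(out of scope by design); alternative metrics (cosine, correlation) and
graph community detection are not provided.
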