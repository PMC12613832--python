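# Methods

## The model

`omicsgcn` integrates paired multi-omics profiles (e.g. mRNA and miRNA
expression measured on the same tumours) for supervised classification.
Unlike sample-similarity approaches, the graphs here live in *feature
space*: nodes are molecular features, node signals are the vectors of
values across samples, so the hidden representation of omics block *m*
is a matrix `H_m` of shape features × samples with `H_m^(0) = X_m^T`.

Each layer runs two kinds of convolution in parallel:

* **Intra-omics.** `Z_m = σ(W_m Â_m H_m)`, where `Â = D^{-1/2}(A + I)D^{-1/2}`
  is the symmetrically normalized adjacency of the intra-omics feature
  graph (self-loops added before computing degrees, so isolated features
  are well defined) and `σ` is LeakyReLU.
* **Inter-omics (bipartite).** `Z_{o→m} = σ(W_{o→m} B̂_{m,o} H_o)`, where
  `B̂_{m,o}` is the m-rows × o-columns block of the jointly normalized
  bipartite adjacency. The joint (p+q)×(p+q) matrix has the incidence and
  its transpose off the diagonal, gets self-loops and the same symmetric
  normalization, and the off-diagonal blocks are extracted; by symmetry
  `B̂_{o,m} = B̂_{m,o}^T` exactly.

The branches are fused per layer by a weighted sum
`H_m' = k·Z_m + (1−k)·mean_o Z_{o→m}`, `k ∈ [0,1]`. With two omics the
mean is a single term; with M omics the M−1 incoming inter terms share
the `1−k` mass equally (per-pair weights would be a straightforward
extension, but equal sharing keeps the M-omics model permutation
symmetric in the other blocks, which the tests assert). The ablation
modes drop one branch entirely: `intra_only` uses `H' = Z_intra`,
`inter_only` uses the inter mean; the fused model at `k = 1` (resp.
`k = 0`) is bit-identical to these modes, which the suite checks
exactly.

All weight matrices are square (d × d per block), so the feature-space
dimension never changes and every coordinate of the final representation
remains identified with an input feature — this is what makes the
embeddings directly interpretable feature-wise. No graph layer has a
bias term; the prediction head is a single linear map from the
concatenated final blocks, `Ŷ = σ((H_u^(L) ‖ H_v^(L))^T W)`, with
sigmoid (binary, one output unit) or row softmax (multiclass). The
activation is applied inside every layer including the last; the fused
output then feeds the head.

## Training

Two strategies:

* **Weighted message passing (WMP).** End-to-end minimization of mean
  binary/categorical cross-entropy (probabilities clipped to
  `[1e−7, 1−1e−7]` before logs).
* **Dual alignment (DA).** Unsupervised pretraining of the graph
  weights on `α·L_A + (1−α)·L_R`, where the alignment loss
  `L_A = MSE(Z_u, Z_{v→u}) + MSE(Z_v, Z_{u→v})` pulls the two views of
  each block together and the reconstruction loss
  `L_R = MSE(Z_u, X_u^T) + MSE(Z_v, X_v^T)` anchors the intra view to
  the inputs. Both are evaluated at the final layer by default
  (configurable to a sum over all layers — which layer the published
  formulation intends is not fixed, so it is a switch). After
  pretraining, the whole model (head included) is fine-tuned end-to-end
  on the classification loss, with weighted fusion still active
  (default k = 0.5); whether the original dataflow keeps fusion during
  DA fine-tuning is ambiguous, so this is the documented default rather
  than a claim.

Optimization is full-batch Adam (cohorts are hundreds of samples;
mini-batching would only add variance) at learning rate 1e−3. The
forward/backward passes are dense numpy with hand-derived gradients; a
finite-difference check in the test suite verifies every parameter
family to 1e−4 relative error. Early stopping monitors validation loss:
an epoch "improves" when it decreases the best value by at least 1e−6,
training stops after `patience` (default 20) consecutive
non-improvements, and the returned parameters are the snapshot of the
best validation epoch. Weight initialization is scaled-uniform
(Glorot-style) from a seeded generator; every source of randomness in
the pipeline flows from explicit seeds, so reruns are bit-identical.

LeakyReLU's negative slope defaults to 0.01. `k` defaults to 0.5,
consistent with the reported best range of roughly 0.4–0.5 for this
architecture family.

## Graph construction

Intra-omics graphs are built by thresholding a pairwise feature
affinity — cosine (default; it performed best for this architecture
family), Pearson correlation, or a Gaussian RBF kernel with `σ`
defaulting to the median pairwise distance — at a per-omics `ε`;
the diagonal is zeroed before normalization so self-loops are not
double-counted. When `ε` is unspecified it is chosen from the affinity
quantiles so that the expected node degree is ~10 (a sparse,
biologically plausible regime; the median degree lands in [3, 30]).
Degenerate features (zero norm under cosine, zero variance under
Pearson) get affinity 0 and a warning, so constant features never gain
edges.

Bipartite graphs come from three sources: a prior edge list
(TargetScan-style regulator/target records; context++ scores are more
negative for stronger repression, so the default cutoff keeps
`score ≤ cutoff`, switchable to `≥` for generic weights; unknown
identifiers are skipped with a logged count; duplicates collapse), a
data-driven construction thresholding cross-block affinities, or a
hybrid keeping edge (i,j) when `λ·prior_ij + (1−λ)·a_ij ≥ ε` (the
blending rule is this package's choice; λ = 1 and λ = 0 reduce to the
pure cases).

## Preprocessing protocol

KNN imputation (K = 5, mean of the K nearest samples by Euclidean
distance on mutually observed features, via scikit-learn's
`KNNImputer`); top-variance feature selection (ddof = 1; descending
variance, ties keep input order; conventional sizes 1000 mRNA /
200 miRNA / 1000 methylation); restriction to features with at least
one network edge. Splits are stratified 80/20 train/test, then 80/20
train/validation inside the training portion, repeated with seeds
`base + r` (100 repeats for a full run; 20 at CI scale). Each subset is
z-scored per feature **from its own statistics** — including the test
set — which is the protocol followed here deliberately, even though
transforming held-out data with training statistics is the more common
convention; since standardization uses no labels, this choice affects
calibration but cannot leak class information. Stratification is not
part of the source protocol but is adopted because several real cohorts
in this setting are heavily imbalanced; it degrades gracefully (with a
warning) when a class has fewer than 5 samples. Intra-omics graphs are
rebuilt per repeat from the training split only (configurable), so
graph construction cannot leak test-set structure.

## Evaluation

AUROC on predicted probabilities (scikit-learn; ties count one half) and
MCC (scikit-learn; zero-marginal convention 0). For binary tasks the
probability→label threshold is Youden's index, maximizing
sensitivity + specificity: candidate thresholds are the distinct
observed scores, a sample is positive at score ≥ t, and the smallest
optimal threshold wins ties; it is computed on the evaluated set's own
ROC by default (configurable to validation-derived). Multiclass uses
macro one-vs-rest AUROC and argmax labels (no Youden analogue).
Aggregation reports per-repeat values plus mean/SD. The ablation and
k-sweep runners share split seeds across arms so differences are
attributable to the model variant, and the rewiring probe removes
⌈fraction·|E|⌉ random bipartite edges and adds the same number of
random absent pairs, preserving the edge count.

## Synthetic cohorts

The generator emulates the regime these models target: n = 300 samples,
a large "target" block (p = 200, mRNA-like), a small "regulator" block
(q = 50, miRNA-like). Ten driver features of the regulator block carry
a class mean shift of 2 (noise SD 1); the target block receives class
signal *only* through a sparse Bernoulli(0.05) regulator→target
incidence, each linked target being `coupling` (default 1) times the
mean of its linked regulators plus noise. Five correlated modules per
block (shared latent factor, weight 0.5) give the intra-omics graphs
realistic structure, and uniform missingness (exact-count masking) is
optional. Labels are balanced; all ground truth (incidence, modules,
driver identities) is returned, and the default sizes keep the full
repeated protocol tractable on one CPU.

What this emulates — and what it does not: the planted-signal design
reproduces the *routing* structure (class signal reachable from one
block only through cross-omics edges) but not TCGA marginals, count
scales, methylation boundedness, batch effects, or label noise.
Passing the recovery tests therefore shows the machinery finds
cross-omics signal when it exists and finds nothing when it does not
(the effect = 0 null sits at chance); it does not certify performance
on real cohorts. Note also that at the default effect size the task is
strongly separable, so test AUROC sits near its ceiling and differences
between trained variants are small.

## Numerical choices and limitations

* Dense float64 everywhere; feature counts beyond a few thousand per
  block make the square weight matrices expensive (memory is O(p²)) —
  the intended regime is post-selection matrices of ~10²–10³ features.
* Affinity matrices are symmetrized (`(S + S^T)/2`) and cosine/Pearson
  values clipped to [−1, 1] to absorb floating-point drift.
* Early-stopping ties: strictly-smaller-by-1e−6 improvement; the first
  best epoch is kept.
* Degenerate inputs: empty graphs are legal (a feature with no edges
  becomes a pure self-loop under normalization; an empty bipartite
  graph yields zero blocks and the model degrades to intra-only
  signal); single-class training labels are refused.
* The divergence guard aborts with a diagnostic if any loss goes
  non-finite.
* Determinism holds bit-for-bit on a fixed platform/BLAS; across BLAS
  builds results may differ in the last few ulps.
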