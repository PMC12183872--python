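# Methods

## Problem and model

Spatially resolved transcriptomics (SRT) measures a gene expression profile
at each capture location ("spot") together with its 2-D coordinates.
`spotview` identifies *spatial domains* — groups of spots with coherent
expression and spatial organization, such as cortical layers — in one slice
or jointly across several slices, where each slice may carry its own
technical (batch) effect.

The model is a two-view graph-convolutional autoencoder trained with
contrastive objectives.

**Preprocessing.** Genes with zero total count across all spots of all
slices are removed. Counts are library-size normalized to 10⁴ per spot and
log-transformed, `ŷ_ij = ln(10⁴ · y_ij / Σ_j y_ij + 1)`, then each gene is
z-scored with the sample (1/(m−1)) standard deviation; zero-variance genes
become zero columns (their z-score is undefined and they carry no signal,
but dropping them would shift indexing). PCA by exact SVD retains the first
`n_pcs` score columns, with each component's sign fixed so its
largest-magnitude loading is positive (determinism). For multi-slice data
the slices are concatenated *before* standardization and PCA, so that
additive slice effects survive into the feature space where the batch
module can see and remove them; per-slice standardization would silently
delete part of the batch effect while leaving nonlinear residues behind.

**Multi-view graphs.** Per slice, two directed K-nearest-neighbor graphs
over spots: spatial (Euclidean distance between coordinates, K = 6 by
default — the physical neighbor count of hexagonal Visium arrays) and
expression (Pearson correlation between PCA feature rows, K = 6). Each
binary adjacency A is hybridized with self-connections,
`Â = λI + (1−λ)A` with λ = 0.3, and symmetrically degree-normalized,
`Ã = D^{−1/2} Â D^{−1/2}` with D the row sums of Â. The KNN matrices are
kept directed exactly as defined; Ã may be mildly asymmetric, which the
graph convolution tolerates. Multi-slice operators are block-diagonal —
no operator entry ever links spots of different slices. Graphs are built
once from the uncorrected features and held fixed during training
(rebuilding from corrected features each epoch is a cheap swap but adds a
moving target to the optimization).

**Network.** Per view, a two-layer GCN with ELU and no biases maps the
(corrected, augmented) feature matrix to embeddings
`Z_v = elu(Ã(elu(Ã X W₁₁)) W₁₂)` of width d = 64. Two projection heads
shared across views produce an instance projection
`H_v = relu(Z_v W₂₁) W₂₂` (width f = 32) and a pseudo-cluster assignment
`Q_v = softmax(relu(Z_v W₃₁) W₃₂)` with N_c columns (default: the number
of domains K). Per-spot scalar attention scores `tanh(Z_v W₄₁) W₄₂`,
softmax-normalized across the two views, fuse the embeddings as the
convex combination `Z = α_spa ⊙ Z_spa + α_expr ⊙ Z_expr`. A tied-weight
decoder `X̂ = relu(Z⁽ᵇ⁾ W₁₂ᵀ) W₁₁ᵀ` reconstructs the feature matrix; the
decoder tensors are the encoder tensors, so gradients accumulate from both
paths.

**Augmentation** (training only, redrawn each step): feature perturbation
`x̃_ij = b_ij (x_ij + α ε_ij)` with ε ~ N(0,1), b ~ Bernoulli(p), α = 0.1,
p = 0.9; and edge masking that independently keeps each stored edge with
probability p_m = 0.9, drawn separately per view and per GCN layer (the
propagation rule applies the corruption at each layer and nothing couples
the draws).

**Losses.** Three terms, `L = L_rec + L_cls + κ·L_ins` with κ = 1:

- *Reconstruction*: mean squared error between X and X̂ over all entries.
- *Instance contrast* (τ_ins = 0.5): symmetric cross-view InfoNCE on
  cosine similarities of H rows. For anchor spot i in one view the positive
  is spot i in the other view and the negatives are only the *other spots
  of the other view*: same-view negatives are deliberately omitted because
  forcing neighboring spots apart would fight the smoothing role of the
  graph convolution.
- *Cluster contrast* (τ_cls = 1.0): InfoNCE over the N_c assignment
  *columns* of Q — for anchor column j of one view the positive is column
  j of the other view and the negatives are the other columns of both
  views — plus the entropy regularizer `Σ_j π_j log π_j` on the normalized
  column masses π, minimized (at −log N_c) by balanced cluster usage; it
  prevents collapse onto few pseudo-clusters. The denominator asymmetry
  relative to the instance loss (the cluster loss *does* include same-view
  negative columns) is intentional and kept.

Cosine norms are floored at 1e-8 for gradient stability; exactly-zero rows
still raise in the public contract.

**Batch prompting.** For L slices, two per-slice prompt matrices: B₁
(L × n_pcs) is subtracted from each spot's input row, and B₂ (L × d) is
added back to the fused embedding before decoding. The forward pass is
`X⁽ᵇ⁾ = X − E B₁` and `Z⁽ᵇ⁾ = Z + E B₂` with E the one-hot spot-by-slice
indicator. For a single slice both are zero and the model reduces exactly
to the single-slice chain. Embeddings used for clustering are extracted
with augmentation off and *without* adding B₂ — they are the
batch-corrected representations.

*Estimation choice.* B₂ is trained by gradient descent from zero. B₁ is
set to its moment estimate — each slice's feature-mean deviation from the
global mean, the natural estimator of an additive slice effect — and held
fixed. This is deliberate: the objective itself is indifferent to whether
the slice offset lives in the prompts or in the embeddings (reconstruction
is equally happy either way, and mildly prefers the embeddings), so a
gradient-trained B₁ is not identified as "the batch effect". Empirically,
zero-initialized gradient-trained prompts leave the embeddings
batch-confounded on the two-slice simulation (domain ARI 0.28, batch ARI
0.47 at the default settings), and raising the prompt learning rate makes
it worse; the moment-estimated B₁ removes the confound (domain ARI 0.90,
batch ARI 0.00). With B₁ fixed, the encoder never sees the slice offsets
and cannot leak them into Z, while B₂ still learns to restore them for the
decoder.

**Training.** Full-graph Adam (lr 1e-3, no weight decay, no scheduler),
500 epochs by default; one numpy Generator seeded from the run config
drives initialization and every augmentation draw, so runs are bitwise
reproducible. Weights are Glorot-uniform. Ablation modes are loss-term
switches: `no_instance` (κ = 0), `no_cluster` (drop L_cls), `no_both`
(autoencoder only), `no_prompting` (both prompts frozen at zero). Training
aborts with the epoch index and offending component if the loss goes
non-finite. Differentiation is by reverse-mode autodiff over numpy arrays
with a custom primitive for sparse-operator products, keeping each epoch
at a few sparse matmuls plus small dense ones (about 50 ms for 500 spots
on one CPU core).

**Clustering.** A K-component Gaussian mixture is fitted to the extracted
embeddings by EM with k-means++ initialization from the run seed, and
spots take their maximum-posterior component. Covariances are *diagonal*
by default: with d = 64 embedding dimensions and on the order of 10²
spots per component, per-component full covariances (~2 080 free
parameters each) are badly overparameterized — EM fits noise, and domain
recovery measurably degrades with training length (median ARI 0.63 vs
0.92 on the 500-spot simulation at 500 epochs). The diagonal restriction
plays the role of the constrained covariance families of model-based
clustering; full covariance remains selectable. K is user-supplied; there
is no automatic model selection.

**Refinement.** One synchronous pass of strict-majority smoothing: a spot
whose `refinement_radius` (= 6) nearest spatial neighbors *within its own
slice* show a strict majority for one label different from the spot's own
is reassigned; ties and plurality-only votes keep the original label.

**Evaluation.** ARI and NMI (arithmetic-mean normalization) against
annotations; mean Euclidean silhouette and Calinski–Harabasz on the
embeddings; and two dataset statistics: label smoothness LS (fraction of
directed spatial-KNN edges whose endpoints share a label, in [0,1]) and
label entropy LE (Shannon entropy of label proportions, natural log).
LS and LE here are this package's operationalization of the stated
semantics and ranges. Multi-slice metrics are computed on pooled spots.

## Synthetic data

The generator emulates layered tissue measured across slices: spots on a
regular lattice, domains as contiguous horizontal row-bands (one block per
domain — high LS, the regime where graph-based domain identification is
expected to work best), disjoint marker-gene sets per domain, and counts
drawn as `Poisson(base_mean · exp(signal·1[marker] + shift_jl))` followed
by independent zeroing with probability `dropout_p` (zero-inflation).
`shift_jl ~ N(0, batch_shift_sd)` is an additive per-gene log-scale
location shift drawn once per slice — the standard batch model. Defaults
chosen once as realistic for sparse SRT counts: `base_mean = 1.0` (mean
counts below one per gene per spot, as in Visium-scale data),
`dropout_p = 0.3`, Poisson rather than negative-binomial noise (the
pipeline assumes only count-like nonnegative data, and zero-inflation
supplies the overdispersion).

Two named study conditions: `easy` — one 20×25 slice (500 spots), 5
domains, 200 genes, 20 markers per domain at log-fold effect 1.5, no
batch effect; `batchy` — two such slices with `batch_shift_sd = 1.0`.
On `batchy`, the leading PCs of pooled uncorrected data separate slices
rather than domains (verified as a test invariant), establishing the
confound the prompting module must remove.

What the generator does *not* emulate: irregular domain geometry, smooth
within-domain expression gradients, spot-to-spot library-size variation,
gene–gene correlation beyond the domain programs, and realistic platform
noise. Passing tests therefore demonstrate that the machinery recovers
planted structure under controlled conditions, not field performance on
real tissue.

`oracle_separability` clusters the PCA of the noise-free mean matrix — an
upper-bound reference for what any pipeline could recover (1.0 on `easy`,
~0 when the signal is zero).

## Numerical choices and edge cases

- KNN distance/correlation ties break toward the lower spot index; all
  stochastic steps draw from one seeded Generator — fixed seed implies
  byte-identical label files.
- Expression KNN requires non-constant feature rows (correlation is
  undefined otherwise) and raises naming the offending spot.
- Zero-library spots are an input error; the generator re-assigns a
  single count to a random gene in the rare case dropout empties a spot.
- `λ > 0` guarantees positive degrees, so the normalization never divides
  by zero; `λ = 0` with an isolated node raises.
- EM failures retry once with diagonal covariance before raising.
- Problem sizes used by the test-suite and the acceptance script (500 and
  1 000 spots, 200 genes, 3 seeds per condition) were chosen as the
  smallest at which the planted structure is non-trivially recoverable
  and the contrasts of interest (ablation directions, batch confound) are
  expressed.

## Known limitations

- The prompt model is additive per slice in feature space; multiplicative
  or domain-specific batch effects are out of its reach.
- Full-graph training is quadratic-memory in spots via the m×m cosine
  matrix of the instance loss; intended scale is ≤ ~10⁴ spots.
- The attention module's weights drift toward the reconstruction-favored
  view late in training; with long budgets the fused embeddings can be
  noisier than at convergence of the contrastive terms. The default
  budget and the diagonal-covariance clustering absorb this in practice.
- K must be supplied; no automatic selection of the number of domains.
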