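# spotview

Spatial-domain identification for spatially resolved transcriptomics (SRT)
by multi-view graph contrastive learning, for single-slice and multi-slice
data.

SRT platforms (10x Visium, Slide-seqV2, Stereo-seq, BaristaSeq, ...)
measure a gene expression profile at each capture spot together with its
2-D position. A central analysis task is partitioning the spots into
*spatial domains* — regions such as cortical layers that are coherent both
transcriptionally and spatially. When several tissue slices are analyzed
jointly, per-slice technical (batch) effects additionally confound the
shared structure. `spotview` is aimed at computational biologists who want
batch-corrected spot embeddings and domain labels from count matrices and
coordinates alone.

## Model

Two directed K-nearest-neighbor graphs are built over the spots of each
slice — a **spatial view** from Euclidean distances between coordinates
and an **expression view** from Pearson correlations between PCA feature
rows — each hybridized with self-connections, `Â = λI + (1−λ)A`, and
degree-normalized, `Ã = D^{−1/2} Â D^{−1/2}`. Multi-slice operators are
block-diagonal. Per view, a two-layer GCN encoder with ELU produces spot
embeddings

    Z_v = σ(𝒞(Ã_v) σ(𝒞(Ã_v) X̃ W₁₁) W₁₂),   v ∈ {spa, expr},

where X̃ is the noise/mask-augmented feature matrix and 𝒞 masks edges at
random during training. Training minimizes

    ℒ = ℒ_rec + ℒ_cls + κ·ℒ_ins

— a mean-squared reconstruction loss through per-spot attention fusion
`Z = α_spa ⊙ Z_spa + α_expr ⊙ Z_expr` and a tied-weight decoder; a
cross-view instance InfoNCE aligning each spot's projection across the two
views (cross-view negatives only); and a cluster-level InfoNCE over
pseudo-cluster assignment columns with an entropy regularizer
`Σ_j π_j log π_j` against collapse. For L slices, per-slice prompt vectors
are removed from the input (`X⁽ᵇ⁾ = X − E B₁`) and restored before
decoding (`Z⁽ᵇ⁾ = Z + E B₂`), isolating additive batch effects from the
embeddings. Domains are called by a seeded Gaussian-mixture EM on the
extracted embeddings plus one pass of strict-majority spatial refinement.

See `docs/methods.md` for assumptions, defaults, estimation choices, and
limitations.

## Worked example

```python
from spotview import SpatialDomainModel, RunConfig, presets, generate
from spotview.evaluate import ari

spec = presets()["easy"]          # 500 spots, 5 banded domains, 200 genes
spec.seed = 0
slices, domains, _ = generate(spec)

res = SpatialDomainModel(slices, RunConfig(seed=0)).fit()
part = res.cluster()
print(res.summary())
print(res.evaluate(domains, partition=part).to_dict())
```

prints

```
Spatial domain model fit
===============================================
slices                     1
spots                      500
embedding dim              64
epochs                     500
ablation                   full
seed                       0
loss (epoch 1)             14.31159
loss (final)               10.07496
final reconstruction loss  0.92202
final cluster loss         -0.38951
final instance loss        9.54245
n_domains (K)              5

               ari: 0.9704
               nmi: 0.9652
        silhouette: 0.1737
 calinski_harabasz: 62.8356
  label_smoothness: 0.8557
     label_entropy: 1.6091
```

The total loss falls from 14.31 to 10.07 over training; the five planted
domains are recovered almost exactly (ARI 0.97 against the generating
labels), the refined labels agree with their spatial neighbors 86% of the
time (label smoothness), and the five domains are used in near-equal
proportion (label entropy ≈ ln 5 ≈ 1.609).

The same pipeline is available from the shell:

```bash
spotview simulate --preset easy --seed 0 --out data/
spotview run --matrix data/s0.counts.mtx --coords data/s0.coords.tsv \
             --truth data/true_domains.tsv --out results/
spotview ablate no-prompting --matrix ... --coords ... --out results_ablate/
```

Inputs may be MatrixMarket, delimited text, or `.h5ad`; all outputs are
TSV/JSON. A fixed seed and config reproduce label files byte-for-byte.

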