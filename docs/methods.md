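# Methods

## Scope and model

`scalestack` implements slide-level multiclass classification of
whole-slide images from tile-level embeddings, comparing single- and
multi-magnification variants of two aggregation strategies:
attention-based multiple instance learning (MIL) and the
cluster-proportion ("barcode") representation. The package is organised
around a staged pipeline (geometry → embeddings → aggregation →
evaluation); the two learnable stages follow the model/results idiom:
`AttentionMIL(bags).fit(config)` and `BarcodeClassifier(X, y).fit(...)`
return results objects carrying parameters, predictions, diagnostics
and a `summary()`.

## Tile geometry

Coordinates are 0-based half-open footprints in base-magnification
pixels; a tile at magnification m covers `tile_size * base_mag/m` base
pixels per side, which makes all cross-magnification arithmetic exact
integer arithmetic. Magnifications must divide the base magnification
integrally; non-integral ratios raise rather than interpolate.

Grid tiling drops partial right/bottom edge tiles (floor division);
nothing in the pipeline depends on edge remainders. Concentric sets
keep the strict 1:1 correspondence even at slide borders: border
members carry a `pad_fraction` (area outside the slide / footprint
area) and are padded with white (255) at read time instead of being
dropped, since silently dropping sets would break the correspondence.
QC is an abstract tissue-fraction filter (default threshold 0.5) over a
user- or generator-supplied binary mask, evaluated exactly by
area-weighting partial mask cells over the clipped footprint; the
threshold comparison uses a 1e-12 tolerance so exact boundary cases
(a tile exactly half on tissue at threshold 0.5) are kept.

## Synthetic cohorts

The generator emulates the statistical structure the methods rely on,
not histology appearance. Each class c has a phenotype distribution
θ[c, m] over P latent tissue phenotypes per magnification m; a tile
with phenotype p receives an embedding μ[p, m] + σ·N(0, I), with the P
means placed at mutual Euclidean distance s (defaults s = 6, σ = 1,
P = 8, achieved by scaling an orthonormal random frame by s/√2).
Phenotypes are drawn hierarchically down the pyramid: a grid child
copies its parent's phenotype with probability ρ (default 0.8),
emulating spatially coherent tissue regions. A single global seed fans
out to per-slide child seeds through `SeedSequence` spawn keys, so
cohorts are byte-reproducible and order-independent.

The *scale-complementary* cohort used for the multi-scale comparisons
sets ρ = 0 by design: cross-magnification phenotype copying would leak
each scale's class signal into the others and the complementarity
(classes 0–4 distinct only at 20x, classes 5–9 only at 5x, 10x
uninformative) would no longer hold by construction. Its conditions are
10 classes × 30 slides, separation 6, unit noise; an 8×8 base grid
(64/16/4 tiles at 20/10/5x) for MIL runs, and a 32×32 base grid
(1024/256/64 tiles) wherever the 64-tile-minimum barcode filter is
active, so that every magnification can satisfy the filter. Embedding
width 32 and K = 16 clusters are used in these desk-scale runs; the
package defaults remain 512 and 150.

What passing these tests does *not* show: robustness to staining or
scanner variation, realistic intra-class texture heterogeneity,
imperfect QC masks, or embedding quality of any particular backbone —
the synthetic embeddings are exactly the mixture the generator states.

## Embeddings

The supervised baseline is a weak-label tile classifier: every tile
inherits its slide's label, the network is a dense tanh layer of the
declared penultimate width (default 512, matching common convolutional
backbones at 224×224) plus a linear softmax head, trained with Adam and
per-slide per-epoch subsampling (budget 500 tiles; self-supervised
provider budgets are 500/500/1000 for 5x/10x/20x). Tile images, when
used, are resized to a small fixed grid before the dense layers;
rotation/flip augmentation applies at training only, never at
inference. The embedding is the penultimate activation; slide scores
for the baseline method are the arithmetic mean of tile probability
vectors with argmax ties broken toward the lowest class index.
Self-supervised extractors are a provider interface (any callable
tiles → N×M with a declared M, keyed by magnification); training such a
network is out of scope here. In synthetic-embedding mode the
generator's matrices pass through unchanged, so aggregation results are
identical whether embeddings come from memory or the HDF5 store.

## Attention-MIL

Non-gated tanh attention: a_k = softmax_k(wᵀ tanh(V h_kᵀ)), z = Σ a_k
h_k, linear softmax head on z. The softmax is computed with max
subtraction; weights are strictly positive and sum to 1; pooling is
permutation invariant. Hidden width defaults to 128. Multi-scale bags
concatenate embeddings in fixed descending magnification order; with
grid tiling a stacked row is emitted only if the highest-magnification
tile *and* all its ancestors passed QC (rows with a QC-failed ancestor
are dropped; an ancestor outside the slide's grid is a broken-lineage
error). Training minimizes cross-entropy — optionally weighted by
median-frequency balancing w_c = median(counts)/count_c — with Adam,
per-epoch without-replacement subsampling of each bag to `bag_size`
(whole bag when smaller), inverted dropout on the attention hidden
layer, and explicit manual gradients; runs are deterministic given the
config seed up to floating-point associativity. Default optimizer
settings (lr 1e-4, weight decay 1e-5, dropout 0.25) are a starting
grid; the desk-scale comparison runs pass lr 1e-3, 30 epochs, hidden 64
for quick convergence on the small cohorts.

## Barcodes

Clustering is fit per magnification on training-set tiles pooled across
slides — per-slide clustering could not give comparable barcode
coordinates across slides — with scikit-learn's MiniBatchKMeans
(K = 150 by default; fitting requires at least K pooled tiles).
Assignment is exact nearest-centroid (Euclidean; squared distances are
rounded at 1e-9 before argmin so ties deterministically resolve to the
lowest centroid index), and never updates centroids, which the tests
assert as a leakage guard. Barcode blocks are tile proportions (each
block sums to 1; empty clusters contribute zeros); multi-scale barcodes
concatenate blocks in descending magnification order and slicing
recovers the blocks bit-exactly. The 64-tile minimum filter counts
QC-passing tiles and only over the magnifications the experiment uses.
Classification uses XGBoost with optional class-prevalence sample
weights (weight = total/(n_classes·count_c)); hyperparameter tuning is
a random search (default 30 draws; 0 draws = fixed mid-range values)
over learning rate, max depth, subsample ratio, column subsample ratio
and L2 regularization, scored by validation macro F1. Monte Carlo CV
draws repeated random patient-wise holdouts (default 5 folds, 20%
holdout, mirroring the global split) and reports mean ± t_{0.975,n−1}·sd/√n.

## Evaluation

Splits are patient-wise and class-stratified: patients are assigned as
whole units, per-class train counts use largest-remainder rounding, and
single-slide classes go to train with a warning. Patients whose slides
span several classes are assigned once, globally, and counted toward
each class's target; a leakage assertion runs on every pipeline run.
Per-class F1 uses the 0/0 → 0 convention (so a class never predicted
and never recovered scores 0.00); macro F1 averages over all declared
classes, weighted F1 weights by support. The multiclass MCC is
(c·s − Σ p_k t_k)/√((s²−Σp_k²)(s²−Σt_k²)) with 0 returned when either
margin has zero variance (e.g. a constant predictor). Reports label
overall accuracy explicitly as `overall_accuracy` because "ACC" is also
a tumor-class acronym in this field.

## Numerical and design choices

- Argmax ties anywhere in the package break toward the lowest index.
- Mean-pooled inputs must be probability rows (sum to 1 within 1e-6).
- Attention agreement with the direct softmax formula is tested at
  1e-9; barcode block normalization at 1e-9.
- The workflow's caching keys on a content hash of the full config;
  identical configs re-read the cached report byte-for-byte.
- Concentric experiments are restricted to the undersampling balancing
  mode (the configuration validator enforces it, with an explicit
  override flag), reflecting the storage asymmetry of concentric
  extraction.
- The CLI (`scalestack simulate|tile|run|compare`) is a thin wrapper;
  the library functions are the supported interface.

## Known limitations

No stain normalization, segmentation, or real artifact detection; the
concentric pipeline reads synthetic gridwise embeddings by giving each
base tile its ancestors as co-centered context rather than re-cutting
overlapping tiles; no GPU paths; absolute performance numbers from
terabyte-scale real cohorts are out of reach of the synthetic setting —
only the qualitative single- vs multi-scale comparison transfers.
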