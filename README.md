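# scalestack

Single- and multi-scale classification of whole-slide histopathology
images (WSIs), built as a tested, fully reproducible pipeline:
pyramidal tile geometry, attention-based multiple instance learning
(MIL) over stacked multi-magnification embeddings, and the
cluster-proportion "barcode" slide representation — exercised end to
end on synthetic cohorts, so no external imaging data or GPU is needed.

## Who this is for

Computational pathology researchers who want a reference implementation
of multi-magnification slide classification: exact grid/concentric tile
arithmetic across pyramid levels, leakage-safe patient-wise evaluation,
and two slide-level aggregation methods that can each be run at one
magnification or across several.

## The methods

**Tile geometry.** A WSI pyramid stores the same slide at several
magnifications (here 5x, 10x, 20x); tiles are 224×224-pixel squares.
*Grid* tiling tiles each level independently: one 5x tile covers 4
tiles at 10x and 16 at 20x (a 1:N parent/child linkage). *Concentric*
tiling takes each 20x tile as an anchor and cuts one co-centered tile
per lower magnification (a strict 1:1 correspondence with overlapping
low-mag footprints). A tissue-fraction QC filter over a binary mask
removes background/artifact tiles.

**Attention-MIL.** A slide is a bag B = {x₁, …, xₙ} of tile embeddings
h_k with one slide-level label. Pooling uses learned attention

    a_k = softmax_k( wᵀ tanh(V h_kᵀ) ),    z = Σ_k a_k h_k,

followed by a linear softmax head on z. Multi-scale bags concatenate
per-magnification embeddings row-wise (descending magnification);
with grid tiling the lower-magnification embedding is duplicated across
the higher-magnification tiles it covers. Class imbalance is handled
either by median-frequency balancing of the loss or by per-class
undersampling with plain cross-entropy.

**Barcodes.** Tile embeddings from the *training* slides are pooled and
clustered per magnification with mini-batch k-means (K = 150); each
slide becomes the K-vector of its tiles' cluster proportions. Slides
with fewer than 64 tiles at any selected magnification are discarded.
Multi-scale barcodes concatenate per-magnification blocks slide-wise
and feed a gradient-boosted tree classifier with class-prevalence
sample weights; evaluation supports 5-fold Monte Carlo cross-validation
with a t-based 95% CI.

**Metrics.** Macro/weighted F1 (zero-division convention: 0), the
multiclass Matthews correlation coefficient, confusion matrices, and a
patient-wise stratified 80/20 split with an asserted leakage guard.

## Worked example

```python
import numpy as np
from scalestack.synthetic import scale_complementary_config
from scalestack.workflow import ExperimentConfig, run_experiment
from scalestack.mil import MILTrainConfig

# 10 tumor classes x 30 slides; half the classes are separable only at
# 20x, half only at 5x, so no single magnification suffices.
cohort = scale_complementary_config(n_classes=10, slides_per_class=30,
                                    tiles_base=8, embedding_dim=32, seed=1)
mil = MILTrainConfig(epochs=30, learning_rate=1e-3, bag_size=64,
                     hidden=64, loss_mode="plain_CE", seed=1)
for scales in [(5,), (10,), (20,), (5, 10, 20)]:
    cfg = ExperimentConfig(cohort=cohort, scales=scales, method="mil",
                           balancing="undersample_ce", mil=mil, seed=1)
    res = run_experiment(cfg)
    macro = res.metrics.set_index("metric").loc["macro_f1", "value"]
    print(scales, round(float(macro), 3))
```

prints

```
(5,) 0.535
(10,) 0.099
(20,) 0.498
(5, 10, 20) 0.948
```

Each single magnification resolves only the classes whose signal lives
at that scale (10x carries none by construction, so it sits at chance);
the three-scale model concatenates the complementary signals and
recovers nearly all classes. The same comparison with
`method="barcode"` (32×32 base grid so the 64-tile filter can stay
active) yields 0.58 / 0.06 / 0.68 for the single scales and 1.00 for
the concatenated barcodes.

A command-line wrapper is included: `scalestack run --help`.

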