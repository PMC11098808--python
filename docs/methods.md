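# Methods

## Network architecture

ResMini is a residual CNN of 10 weighted layers for single-channel 2D
slice classification:

| stage | layers | output width |
|---|---|---|
| stem | 3×3 conv (stride 1, padding 3) + BN + ReLU | f |
| pool | 3×3 max pool, stride 2, padding 1 | f |
| module 1 | 2 × (3×3 conv + BN + ReLU), 1×1 projection shortcut, add | f |
| module 2–4 | same, first conv and shortcut at stride 2 | 2f, 4f, 8f |
| head | global average pool, dense 8f→K, softmax | K |

Defaults: base width f = 9, grayscale input, K = 3, input 95×79 (but any
height/width ≥ 32 is accepted — global average pooling makes the head
size-independent, so the output shape depends only on K).

Conventions adopted where the published description is under-specified:

- **"Three Conv_BN_ReLU blocks" per residual module** is read as two
  main-path 3×3 convolutions plus the 1×1 projection shortcut. This is the
  only reading consistent with a depth of 10 under the standard convention
  that counts main-path convolutions and the dense layer but not shortcut
  projections, batch norms, pooling or activations.
- **Stem geometry** is implemented exactly as printed (3×3, stride 1,
  padding 3), although padding 3 exceeds 'same' for a 3×3 kernel; the
  parameter count is unaffected. A 7×7/padding-3 stem (classic ResNet
  convention) would be the natural alternative but is not implemented.
- **Downsampling** happens at modules 2–4 (stride 2 on the first main
  conv and on the shortcut); module 1 keeps stride 1 — the standard
  residual-network convention.
- **Convolutions carry no bias** (each is followed by batch norm); the
  dense head carries bias.
- **Shortcut policy**: every module uses a projection shortcut
  (`projection_all`, the ResMini default); `projection_on_downsample`
  (identity where shapes match) is available and is what the ResNet-18
  baseline plan uses.

## Parameter counting

Counts are closed-form functions of the layer plan: conv `kh·kw·cin·cout`
(+`cout` if biased), dense `in·out + out`, batch norm `4·channels` when
running statistics are included (2 scale/shift + 2 moving statistics,
mirroring the "Total params" convention of framework model summaries) or
`2·channels` otherwise. For the projection-all four-module plan the total
reduces to `1195f² + f(9c₀ + 184) + 8fK + K`; the test suite verifies the
polynomial against the per-layer sum over a grid of f, c₀ and K, and
verifies that the constructed network's actual arrays realize exactly the
same total.

The default configuration totals 98,751 parameters. The published total
for this architecture is 98,907 — a 156-parameter (0.16%) gap that no
enumerated structural variant reproduces exactly (the closest three-channel
variant gives 98,913); the filter widths and input-channel count behind the
printed figure are not stated. We therefore document the gap rather than
tune the architecture toward the printed number, and parameter-economy
comparisons treat the printed totals (98,907; 196,595 for BHCnet;
11,181,379 for ResNet-18) as the reference constants. Our canonical
ResNet-18 plan totals 11,187,651 with BN statistics — within 0.06% of the
printed figure, whose exact input/head adaptation is likewise unstated.
BHCnet is not reimplemented; only its published count enters reports.

## The NumPy engine

The trainable network is implemented directly in NumPy: im2col/col2im
convolution, batch normalization (momentum 0.9, ε = 1e-5, running
statistics used at inference), ReLU, overlapping 3×3/stride-2 max pooling,
global average pooling, dense, and a softmax cross-entropy head, with Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). All arithmetic is float32. Every layer's
backward pass is validated against central finite differences in the test
suite. Weight initialization is He-normal from a seeded generator; epoch
shuffling uses the same training seed, so a fixed seed gives bit-identical
histories on a given platform (single-threaded BLAS assumed for exact
reproducibility).

## Data pipeline

- **Slice extraction**: the axial middle slice is the plane at index
  `floor(D/2)` (0-based) along the axial axis (default: third array axis,
  overridable). 4D series are reduced to their first time frame before
  slicing — which frame or statistic the original study used is unknown,
  and the first frame is the simplest deterministic choice. Slices are
  min-max normalized per image to [0, 1] (constant images map to zeros)
  and exported as 8-bit grayscale PNG; labels live only in the manifest
  CSV (columns: image_id, path, class_name, provenance, source_id, split;
  class order and image size ride in a comment header so round trips are
  lossless and byte-stable).
- **Augmentation** doubles the dataset: each original receives exactly one
  variant, translated by integer offsets drawn uniformly from
  [−0.1·dim, +0.1·dim] per axis and then flipped about the vertical
  midline, vacated pixels filled with the dark background (0). Offset
  magnitudes are not published; 10% of each dimension preserves the brain
  within the frame while moving it visibly. One variant per original is
  the only reading consistent with 155 originals becoming 310 samples
  while both offsets and flips are described. By default augmentation runs
  before splitting, reproducing the published workflow in which the
  61-sample test set is drawn from the 310 augmented samples — a leakage
  risk (an original and its variant can straddle the train/test boundary);
  the CLI's `--leakage-safe` flag instead augments only training records
  after splitting.
- **Splitting** is stratified with floor-per-class rounding: the held-out
  part gets `floor(fraction·n_c)` per class via a seeded shuffle, applied
  twice (20% test, then 20% of the remaining training records as
  validation). Floor rounding is the only simple rule whose test-set total
  (26 + 22 + 13 = 61 from class sizes 130/114/66) matches the published
  61; the published per-class test counts 27/21/13 match no standard
  rounding of those sizes and are treated as an internal inconsistency of
  the source tables, reproduced in the worked example only as a printed
  composition.

## Training and evaluation

Training defaults follow the published regime: Adam at learning rate
2e-5, batch size 24, 200 epochs. The loss is categorical cross-entropy —
unstated in the source, but the standard pairing with a softmax head. No
early stopping, learning-rate schedule or weight decay. Histories record
train/val loss and accuracy per epoch; models serialize to a single `.npz`
whose restoration yields bit-identical predictions.

Evaluation: confusion matrices with rows as true classes; accuracy =
trace/total; per-class recall (row-normalized diagonal) and precision
(column-normalized, 0 for empty columns); macro metrics are unweighted
class means — the only averaging convention that reproduces the published
0.972 recall from the described errors (one 3–5 error, one 7–12 error,
adults 13/13 on a 27/21/13 test set). Argmax ties resolve to the lowest
class index. The published per-class "accuracy" figures 0.961/0.954 match
neither per-class recall nor one-vs-rest accuracy computable from the
described errors and are not reproduced. Where the two misclassified test
samples were predicted is not published, so the worked example places each
error in the adjacent age class; accuracy and macro recall are unaffected
by that placement, printed precision would not be.

## Phantom generator

Phantoms are 95×79 images of an elliptical brain (uniform tissue
intensity) with a brighter cortical ring and a dark central ventricle
disc, plus clipped additive Gaussian noise (default SD 0.05). The class
signal is morphological: children get a proportionally larger brain,
thicker cortex, smaller ventricle and lower tissue intensity than adults —
a caricature of neurodevelopmental atrophy/ventricle-enlargement structure,
chosen because it is the kind of signal the real age classes carry. A
global `separation` factor interpolates each class's morphology toward
(0) or away from (>1) the across-class mean, so separability is a single
dial: at separation 0 the class distributions coincide exactly and any
above-chance test accuracy would indicate label leakage. Default
per-class original counts are 65/57/33 (total 155), mirroring the study's
pre-augmentation composition. Phantom volumes stack the designed slice
with linear attenuation away from the middle plane, so middle-slice
extraction recovers the design exactly at zero noise.

What passing phantom tests does *not* show: phantoms have none of real
MRI's anatomy, intra-class variability, intensity inhomogeneity, partial
volume effects or registration error, so phantom accuracy says nothing
about accuracy on real data — it validates the pipeline's mechanics
(learnability of a separable signal, chance-level behaviour of an
inseparable one, determinism, arithmetic).

## Experiment sizes and numerical choices

The end-to-end learnability check trains 30 epochs on 60 phantoms per
class (separation 1, noise SD 0.05, seed 42) and requires ≥ 0.9 held-out
accuracy on an independent phantom draw; it uses learning rate 1e-3 — the
published 2e-5 is tied to a 200-epoch budget, and a standard Adam rate is
the appropriate choice for a 30-epoch run. The zero-separation guard
trains 5 epochs on 30 per class across 5 seeds and requires mean held-out
accuracy ≤ 0.5 (chance is 1/3 for balanced classes). The smoke check runs
2 epochs on 40 phantoms and requires a strict training-loss decrease and
seed-exact reproducibility. These sizes are the package's chosen study
conditions for its synthetic experiments.

Other numerical conventions: probability rows sum to 1 within 1e-6
(float32 softmax); cross-entropy clips probabilities at 1e-12; inputs
smaller than 32×32 are rejected before the feature map would collapse;
8-bit PNG round trips quantize intensities to 1/255.

## Known limitations

- Real-data accuracies (0.967 on the three-class age dataset, 96.4% on the
  four-class dementia dataset) require the original downloads and are out
  of scope; no phantom result stands in for them.
- The NumPy engine is CPU-only and single-threaded by design; it is sized
  for ~10⁵-parameter models on ~10²-image datasets, not for large-scale
  training.
- Execution-time comparisons between architectures are hardware-dependent
  and not modelled.
- Subject-level grouping is not implemented: splits are at image level,
  as in the published workflow.
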