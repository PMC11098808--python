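# resmini

A lightweight residual CNN pipeline for classifying 2D brain-MRI slices
into age (or dementia-stage) classes, built for settings where parameter
economy matters — small datasets, modest hardware, deployable models.

Brain age prediction treats the apparent age class of a brain scan as a
proxy for neurodevelopment and aging. This package implements the full
slice-classification workflow around **ResMini**, a residual network of
only 10 weighted layers: symbolic architecture planning with closed-form
parameter counting, middle-axial-slice extraction from NIfTI volumes,
offset+flip data augmentation, stratified splitting, seeded training, and
confusion-matrix evaluation — plus a synthetic phantom generator so every
stage runs and is tested without downloading any imaging data. The
trainable network itself (convolution, batch norm, pooling, dense,
softmax, Adam — forward and backward) is implemented in NumPy inside the
package.

## The model

ResMini consists of a stem `Conv_BN_ReLU` (3×3, stride 1, padding 3, *f*
filters), a 3×3/stride-2 max pool, four residual modules, global average
pooling, a dense layer and softmax. Each residual module stacks two
main-path 3×3 `Conv_BN_ReLU` blocks with a 1×1 projection shortcut
(`Conv_BN`) into an elementwise add + ReLU; module output widths double:
*f*, 2*f*, 4*f*, 8*f*. Counting main-path convolutions plus the dense head,
the depth is 1 + 4·2 + 1 = **10 weighted layers**.

With the default base width *f* = 9, grayscale input and 3 classes the
total parameter count (including batch-norm running statistics) is
**98,751**, matching the closed form

```
total = 1195 f² + f (9 c₀ + 184) + 8 f K + K
```

for input channels c₀ and K classes — about half of BHCnet's published
196,595 parameters and under 1% of ResNet-18's ~11.2 M.

## Worked example

```sh
python examples/phantom_pipeline.py
```

```
trained on 90 phantoms, tested on 30
final training loss: 0.0047
held-out accuracy:   1.000
macro recall:        1.000
confusion matrix (rows = true, cols = predicted):
  ages_3_5   [10  0  0]
  ages_7_12  [ 0 10  0]
  adults     [ 0  0 10]
```

The phantoms are 95×79 elliptical "brains" whose class signal lives in
morphology (brain size, cortical-ring thickness, ventricle radius); an
accuracy near 1.0 against a chance level of 0.333 means the network
recovered that signal from noisy images. The other examples —
`architecture_summary.py`, `augment_and_split.py`, `slice_extraction.py` —
demonstrate parameter counting, the 155 → 310 → 61 dataset arithmetic, and
NIfTI middle-slice extraction.

A command-line interface chains the same stages
(`resmini synth | prepare | augment | split | train | eval | summary | run`);
`resmini run --out-dir out --seed 0` executes the whole phantom pipeline
from one seed and records a provenance file.

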