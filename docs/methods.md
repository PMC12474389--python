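# Methods

## Problem and scope

`tailbcs` classifies rear-view images of dairy cattle into five body-condition
scores (3.25–4.25 in 0.25 steps) from tail-root morphology. The package
provides the model family, its training and compression machinery, and a
synthetic data generator that makes every component testable at desk scale.
It does not attempt to reproduce accuracies reported on real farm corpora;
those require tens of thousands of annotated images and GPU training.

## Numerical core

No deep-learning framework is a dependency. The package ships a compact
neural-network core on numpy: grouped/strided convolutions via
`sliding_window_view` + einsum, batch normalisation, ReLU/ReLU6/SiLU/
hard-swish/hard-sigmoid activations, max/global-average pooling, linear
layers, dropout, and hand-derived backward passes for all of them (verified
against central finite differences in the test suite). Adam is the only
optimiser. All arrays are float32 NCHW; every source of randomness flows
from explicit `numpy.random.Generator` seeds, so corpus generation, model
initialisation and training are pure functions of their seeds.

## Model zoo

The six backbones follow their standard reference configurations
layer-for-layer; only the final classification layer is resized to 5 classes
(SqueezeNet's final 1×1 convolution; a linear layer everywhere else). Two
naming ambiguities were resolved by parameter accounting: "SqueezeNet-1" is
realized as v1.1 and "ShuffleNet" as ShuffleNetV2 ×1.0, the variants whose
counts match the published 0.73 M and 1.26 M after the head swap. Parameter
counts include trainable weights and biases only; buffers (BN running
statistics) are excluded. Serialized size uses the float32 convention
`params × 4 B / 2²⁰` MiB — together these conventions reproduce every cell of
the published parameter row and the 15.31 MiB EfficientNet-B0 size.

Composites place one SE block (reduction 16, both projections biased) on the
final backbone feature map, followed by the 7×7 spatial-attention mask, then
the head. This placement is a design choice: the source material states
neither the SE position nor its ratio, but this configuration adds 206,160
parameters (+0.21 M), matching the published delta. The spatial module per
its defining equation has 7·7·2 + 1 = 99 parameters; the +0.07 M reported for
it elsewhere cannot be produced by that equation and is treated as an
unexplained discrepancy rather than guessed at. Similarly, the YOLO-style
head (1×1 → 512, 3×3 depthwise, 1×1 → 1280, GAP, linear; BN + SiLU
throughout) realizes the published *description* — depthwise-separable, light
convolutional — but its channel widths are chosen for architectural
plausibility, not to match any reported head size.

The ablation presets map A1 = bare backbone, A2 = +SE, A3 = +spatial,
A4 = +label smoothing, A5 = +YOLO head, A6 = SE+spatial, A7 = A6+label
smoothing, A8 = everything. A `tiny` three-stage CNN backbone (final width
64, divisible by the SE ratio) extends the zoo for desk-scale experiments.

MAC ("FLOP") counts sum `H·W·K²·C_in·C_out/groups` over convolutions plus
`in·out` over linear layers. The convention is tool-dependent, so the count
is informational only, as is wall-clock latency.

## Losses

Natural logarithm throughout; probabilities are floored at 1e-12 before logs
(standard numerical guard). Label smoothing uses ε = 0.1 by default. The
distillation objective is the temperature-softened forward KL (teacher as
reference) scaled by T² plus hard-label cross entropy, weights α = 0.7,
T = 4 — conventional values, exposed as configuration; teacher logits are
treated as constants.

## Data handling

Bounding boxes are 0-based half-open `[x0,x1)×[y0,y1)`. The 7:2:1 split
takes `floor(0.7n)` train and `floor(0.2n)` validation items after a seeded
shuffle, with the remainder as test — the only simple rule that yields
37,496 / 10,713 / 5,357 from 53,566 items. The split is plain (unstratified)
shuffling, matching the stated ratio and nothing more. Preprocessing resizes
to a square input (224 px for the reference backbones; 32–64 px in the
synthetic studies), scales to [0, 1] and normalizes with the conventional
pretrained-pipeline channel statistics (mean 0.485/0.456/0.406,
sd 0.229/0.224/0.225). No augmentation is applied.

## Synthetic generator

The generator encodes exactly one class-separating feature — the depth of the
two depression patches flanking the tail root, scaled by a per-class ladder
(defaults 0.9, 0.7, 0.5, 0.3, 0.1 from leanest to fattest; deeper depression
= darker patch, up to 110 intensity units at depth 1) — plus the nuisance
factors of field imagery: additive Gaussian pixel noise (sd 8), multiplicative
brightness jitter (±8%), and per-item pose jitter of the tail's position,
length and width. Images are 256×256 RGB on a hide-toned background with a
soft vertical gradient, so that tail cropping and resizing are real
operations. These defaults were chosen once as a plausible mid-difficulty
regime: adjacent classes differ by 22 intensity units in the depression
centre, comfortably above the pixel noise but below trivial separability
under brightness jitter (absolute intensity is unreliable; the network must
use local contrast).

What passing tests show: the pipeline can learn, distill and spatially
localise a single morphological feature under noise. What they do not show:
robustness to breed/region variation, multi-animal scenes, occlusion or any
real-image statistics — the generator makes no attempt at photorealism.

## Training protocol

Adam with early stopping on validation loss (patience 10, min-delta 1e-4;
an improvement of exactly min-delta counts as no improvement), best-epoch
weight restoration, sample-weighted epoch losses (order-independent at fixed
weights). Grid search trains one model per configuration and selects the
highest best-epoch validation accuracy, first-in-grid on ties. Distillation
selects the student by validation loss under the distillation objective;
the teacher checkpoint is its best-validation state. Desk-scale studies use
the `tiny` backbone at 32 px (64 px for full-frame Grad-CAM work), batch 32,
learning rate 1e-3, ≤ 20 epochs, 100 synthetic images per class — sizes at
which the full study runs in minutes on one CPU core. The teacher in the
distillation study is the A8-style composite (SE + spatial + YOLO head,
label smoothing) on the `tiny` backbone; the reference student architecture
for edge deployment is MobileNetV2 (2.23 M parameters). Accuracies on the
50-image synthetic test split have a granularity of 2 percentage points per
sample, so teacher–student gaps measured there fluctuate by a few points
across seeds.

## Evaluation conventions

Confusion matrices are rows-actual × columns-predicted. Precision, recall
and F1 are macro-averaged with 0/0 → 0: weighted-average recall is
algebraically identical to accuracy, and the published metric tables report
recall ≠ accuracy, which rules weighted averaging out. Tolerance accuracy
compares BCS values with `|pred − true| ≤ tol + 1e-9`; at tol = 0 it equals
plain accuracy, and at tol ≥ 1.0 it is 100 by construction (the scale spans
1.0). Percentages are rounded to two decimals.

## Grad-CAM

Original Grad-CAM (not Grad-CAM++): channel weights are spatial means of the
target-logit gradient at the chosen feature map, the raw map is the ReLU of
the weighted channel sum, bilinearly upsampled and min-max normalized
(identically-zero maps stay zero). The default target layer is the last
convolutional feature map before pooling — after any attention blocks; an
integer index selects an earlier backbone layer instead. For misclassified
images the predicted class's logit is visualised. The localization check
compares heatmap mass inside the tail bounding box against an equal-area
uniformly-placed random box, averaged over ≥ 50 correctly classified
full-frame images.

## Known limitations

* The numpy core is single-threaded BLAS-bound; the reference backbones are
  practical for profiling and inference but not for full-scale training.
* Stochastic depth, pretrained weights and data augmentation are not
  implemented; parameter accounting does not need them and the synthetic
  studies do not use them.
* The synthetic corpus is deliberately minimal; accuracy numbers on it
  characterise the pipeline, not real-world performance.
* BN running statistics update even in no-op (zero-learning-rate) training
  passes; only trainable weights are guaranteed bit-identical there.
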