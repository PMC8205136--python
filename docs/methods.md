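# Methods

## Problem and approach

`echoseg` segments breast-ultrasound-style greyscale images into three
tissue classes — normal tissue, benign tumour, malignant tumour — and
recognises the class at the same time, by training a U-shaped convolutional
network against *grey-level probability labels* rather than one-hot masks.
Each class is encoded by the same soft value on all three output channels
(normal 0, benign 0.5, malignant 1; equivalently grey 0 / 127.5 / 255 after
multiplying by 255), so the network's output is read as a greyscale map in
which class identity is carried by grey level and texture/edge detail is
preserved rather than collapsed to a hard mask.

## Label encoding

Grey labels are normalized by 255, the only divisor under which the benign
grey level 127.5 maps exactly to the probability 0.5. On disk, masks store
the ordinary labels {0, 1, 2} in single-channel 8-bit PNGs (127.5 has no
8-bit representation); the 0.5/127.5 encodings exist in memory only. The
displayed grey value of a 3-channel prediction is the channel mean times
255 — the convention under which the benign optimum (1/3, 1/3, 1/3) of the
softmax-constrained loss lands at grey 85, inside the expected benign band.

## Loss

The expanded (ternary) cross-entropy of a batch of N elements is

    ECE = -(1/N) * sum_i sum_k [ y_i^(k) log p_i^(k) + (1 - y_i^(k)) log(1 - p_i^(k)) ],   k = 1..3,

with natural logarithms and predictions clipped to (1e-7, 1 - 1e-7). Within
an element the per-pixel channel sums are averaged over pixels, so the loss
magnitude does not depend on image resolution (the per-pixel vs per-image
summation is not otherwise constrained; the mean was chosen for scale
stability). Per channel the loss takes the binary cross-entropy form with
three regimes:

* y = 1: `loss = -log p`, minimised as p -> 1;
* y = 0.5: `loss = -0.5 log p(1-p)`, minimised at p = 0.5 with minimum
  `-0.5 log(1/4) = ln 2 ≈ 0.693`;
* y = 0: `loss = -log(1-p)`, minimised as p -> 0.

Because all three channels carry the same target, the 3-channel ECE at
identical per-channel (y, p) equals exactly 3x the single-channel binary
cross-entropy, in value and gradient — the claimed 3x update-rate increase.
This is formalized (and tested) as that ratio; it is the only reading under
which the claim is checkable. A `bce` variant (the per-channel mean,
ECE / 3) is provided as the deployment-compatibility mode; it has the same
gradient direction at 1/3 the magnitude. ECE is the default.

## The softmax head and the grey reduction rate

The output head applies three 1x1 convolution filters to the 8-channel
top-level feature map and a per-pixel softmax across the 3 channels.
Minimising the benign per-pixel loss subject to the softmax constraint
p1 + p2 + p3 = 1 (strictly convex objective, linear constraint) gives
p = (1/3, 1/3, 1/3), channel-mean grey 85 and grey reduction rate
alpha = 85 / 127.5 ≈ 0.667 — matching the observed benign output band
(80, 90). The package computes this optimum numerically (SLSQP, verified
against a projected-gradient oracle in the tests) rather than hard-coding it.

A structural consequence the source method leaves unreconciled: with equal
targets on all channels, the constrained per-pixel optimum is the uniform
vector for *every* class, and the channel-mean grey of any softmax output is
identically 255/3 = 85. Malignant grey levels in (170, 255) are therefore
unreachable under a softmax head; they are reachable under an independent
per-channel sigmoid head, which however places the benign optimum at grey
127.5, not 85. Neither head reproduces both observed bands at the loss
optimum. Both heads are implemented (`head="softmax"` is the default;
`"sigmoid"` is a configuration away) and the tension is surfaced here rather
than silently resolved.

## Architecture

Depth-4 symmetric encoder–decoder. Per level: two 3x3 same-padded
convolutions, each followed by batch normalization and leaky ReLU
(slope 0.01, configurable); 2x2 max-pool down-sampling with channel counts
8 → 16 → 32 → 64 and a 128-channel bottleneck; 2x2 stride-2 transposed
convolutions (also normalized) for up-sampling; skip concatenation
("fusion") at every decoder level. `base_channels = 8` so the head maps an
8-channel feature vector to the 3-channel output.

Seven dropout layers (P = 0.5) are placed: one after each of the four fusion
concatenations, one after each of the two deepest encoder blocks, one after
the bottleneck. The count of 7 is fixed by the method; the exact positions
are under-determined, so the placement is explicit and configurable
(`dropout_after`), and generalises to `depth + 3` at other depths. Dropout
is inverted (activations rescaled by 1/(1-P) during training) and disabled
at inference, so prediction is deterministic.

The whole network, including backpropagation, is implemented in NumPy
(float64, CPU) in `echoseg.nn`; every layer's backward pass is validated
against central finite differences in the test suite. Adam (lr 1e-3,
betas 0.9/0.999) is the optimizer; no optimizer was prescribed, and Adam is
the standard default for this scale.

## Grey-mass Dice and IOU

The network output is a grey map, not a mask, so overlap is measured on
grey mass. For a class with reduction rate alpha, tolerance delta and band
(lo, hi]: x_t is the class's encoding grey level summed over the true region;
x_p is the sum of output grey values over pixels falling in the band;
Δx = alpha*x_t − x_p. With m/M the min/max of alpha*x_t and x_p,

    Dice = 2m / (alpha*x_t + x_p),      IOU = m / M.

The source text gives the coefficients only by their "geometric meaning";
min/max over scalar masses is the unique scalar analogue that preserves
Dice = 2*IOU/(1+IOU), and is documented as an interpretation. delta is read
as the per-pixel grey tolerance that generates the printed bands (benign
85 ± 5 → (80, 90); malignant 255 − 85 → (170, 255)); band membership drives
extraction, and the Δx tolerance flag uses the per-pixel scaling
|Δx| ≤ delta·n_true (two-sided for benign, one-sided [0, delta·n_true] for
malignant). Degenerate inputs: a truth with no tumour scores 1 iff the
prediction is also empty (with a warning); classical set Dice/IOU of two
empty masks is defined as 1 with a warning. Band membership is half-open
(lo, hi] so the exact malignant grey 255 is counted.

## Synthetic phantoms

The phantom generator emulates the cues the method relies on: a mid-grey
background (0.55 of full scale) with correlated multiplicative speckle
(gamma-distributed with unit mean, variance `speckle_strength**2 = 0.0625`
by default, smoothed with a sigma-0.7 Gaussian); hypoechoic lesions (benign:
smooth rotated ellipse at 0.20 intensity with a Gaussian-blurred margin;
malignant: irregular radial polygon at 0.14 with 2–4 internal bright spots
at 0.85). Labels come pixel-exactly from the rendered footprints. Defaults:
64 images at 64x64, benign fraction 0.885 (the approximate clinical
benign:malignant imbalance), lesion radii 8–16 px, seeded and bit-exactly
reproducible.

What the phantoms do *not* model: acoustic point-spread functions,
attenuation and shadowing, heterogeneous parenchyma, operator-dependent
artefacts, and the scale of clinical images. Passing tests on phantoms show
the pipeline's mechanics and the loss/metric algebra are correct; they say
nothing about clinical segmentation accuracy, and the clinical Dice/IOU
table and epoch counts of the source study are explicitly not reproduced.

Geometric augmentation samples horizontal/vertical flips, rotations within
±15°, translations within ±10% of each side and zooms in 0.9–1.1, applying
one identical affine transform to image (bilinear, reflected borders) and
mask (nearest-neighbour, so labels stay in {0, 1, 2}).

## Training experiment sizes

The in-repo end-to-end experiment trains on 32 phantoms at 64x64 for 12
epochs with batch size 4 — small enough to run routinely on a single CPU,
large enough for the loss to descend visibly and for the benign-region
output grey to sit in its expected band. Loss histories are recorded per
epoch (TSV), and grey-probability vs ordinary one-hot label modes write
separate histories so their convergence can be compared; the comparison
asserts only that both decrease, not any absolute epoch count.

## Numerical choices

* Prediction clipping 1e-7 before logarithms; gradients are zeroed where
  the clip is active.
* Batch-norm epsilon 1e-5, running-statistics momentum 0.9.
* Max-pool ties break toward the first maximum (argmax order).
* Constrained optimization: SLSQP with ftol 1e-14, bounds (1e-9, 1-1e-9);
  non-convergence raises with diagnostics.
* Checkpoints are NumPy `.npz` archives holding all weights, batch-norm
  running statistics and the architecture configuration as JSON; a plain-text
  layer summary is written next to each checkpoint for audit.

## Known limitations

* The softmax head cannot express malignant grey levels above 85 under the
  channel-mean display convention (see above); the sigmoid head can, but
  shifts the benign optimum. This mirrors an unresolved tension in the
  source method.
* The NumPy implementation targets correctness and desk-scale problems, not
  GPU-scale training.
* Grey-mass metrics ignore spatial position inside the band: a correctly
  massed but displaced prediction scores the same as an aligned one.
  Classical overlap Dice/IOU are provided alongside for that reason.
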