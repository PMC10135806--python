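# Methods

This note documents the models, conventions and design choices in
`osteoseg`, the reasoning behind its defaults, and what its tests do and
do not demonstrate.

## Problem and data model

The task is 3-class semantic segmentation of cortical-bone
microphotographs: every pixel is background (0), fragmentary osteon (1) or
intact osteon (2). Ground truth comes from polygon tracings made in the
VGG Image Annotator (VIA); only osteons are traced — background is
everything untraced. Typical source images are 4:3 microscope frames
(2592×1944 or 1600×1200 px) of crowded cortices with dozens of annotated
regions per image.

### Annotation conventions

* Coordinates are VIA's: x = column, y = row, origin top-left, 0-based.
* A pixel belongs to a polygon when its center `(col + 0.5, row + 0.5)` is
  inside under the **even-odd rule**; centers exactly on an edge count as
  inside. The same rule is used by the brute-force oracle in the tests, so
  rasterization is checked pixel-for-pixel against an independent
  implementation.
* **Overlap priority**: fragment polygons are painted first, intact
  polygons second. This encodes the annotation protocol in which an intact
  osteon lying on top of a fragmentary one is traced overlapping it; the
  overlap is therefore intact. Same-class overlaps merge (annotators leave
  a small gap between same-class instances, so merging is a no-op on
  conforming data; the gap size is not enforced).
* Polygons extending past the frame are clipped (frame-cut osteons are
  legitimate annotations). Zero-area polygons contribute no pixels and
  raise a warning.
* The traced outer contour's full interior is osteon — the Haversian canal
  is not excluded, since the protocol does not state that it was.
* VIA JSON does not record image pixel dimensions (its `size` key is file
  bytes). The writer therefore stores `width`/`height` in
  `file_attributes`; the reader takes dimensions from there, from an
  explicit mapping, or from the image files.
* Class encoding (0/1/2 = background/fragment/intact) is fixed so
  confusion matrices line up without permutation everywhere.

## Preprocessing and augmentation

Images are converted to luminance with ITU-R BT.601 weights
(0.299, 0.587, 0.114) — the choice of grayscale standard is a convention,
exposed as an argument — scaled to [0, 1] (8-bit inputs divided by 255),
and stretched to 512×512 by bilinear interpolation with half-pixel-center
sampling (no aspect-ratio preservation). Masks follow with
nearest-neighbor interpolation, which provably cannot invent labels.

Training-time augmentation applies, per sample per epoch: horizontal and
vertical flips (each Bernoulli ½), a uniform 90°-rotation count, zoom
uniform in [0.8, 1.2] and shear uniform in [−0.2, 0.2] rad, applied
independently (not mutually exclusively) about the image center. Flips and
rotations are exact pixel permutations. Zoom and shear share a single
affine resample: bilinear for the image with nearest-edge replication
outside the frame, nearest-neighbor for the mask with background fill.
Using one geometric transform for both keeps the pair registered; a test
verifies that warping the mask "as an image" equals warping the mask.

## Network

A modified U-Net sized for 512×512 single-channel input:

| parameter | default | notes |
| --- | --- | --- |
| depth | 5 resolution levels | encoder 512→32 px |
| base filters | 16 | doubling per level (16…256) |
| convolutions | 3×3, zero-padded, biased, ReLU | no batch normalization |
| downsampling | 2×2 max pool | |
| upsampling | 2×2 stride-2 transpose convolution | halves channels |
| skip connections | channel concatenation | at matching resolutions |
| head | 1×1 convolution → 3 logits, softmax | |
| dropout | 0.3 | see below |

This configuration has exactly **1,940,851** trainable parameters; `count_parameters`
computes it in closed form and a test pins it against the built network's
own tally across varied configurations. Dropout is parameter-free, so its
placement cannot be inferred from the parameter count; it is applied after
the second convolution of the deepest encoder level and of the bottleneck
— the two highest-capacity blocks, where regularization does the most
work. Weights are He-uniform initialized from a seeded generator.

The engine is a compact NumPy implementation (im2col convolutions,
einsum transpose convolutions, explicit forward/backward pairs, Adam).
Analytic gradients are validated against central finite differences in
float64 to 1e-4 relative tolerance. Training uses float32; inference is
deterministic given fixed weights (dropout disabled), and argmax labelling
breaks exact ties toward the lowest class index.

## Training

* Loss: weighted categorical cross-entropy, mean over pixels of
  `−w[y]·log(max(p_y, 1e-7))`. The floor keeps the loss finite; gradients
  use the fused softmax/cross-entropy form.
* Class weights: inverse pixel frequency over the training masks, rescaled
  to mean 1 (a manual triple can be supplied instead). Background
  dominates these images, so unweighted training collapses toward it.
* Optimizer: Adam, lr 1e-3, β = (0.9, 0.999); batch size 2.
* Early stopping: "patience 25" is interpreted as 25 *epochs* without
  improvement of the validation loss, monitored on a 10% holdout drawn
  from the training images; the best-validation weights are restored. A
  strictly worsening validation sequence therefore stops training at epoch
  patience + 1.
* max_epochs defaults to 200; early stopping normally governs.
* Cross-validation: seeded shuffle, round-robin assignment into k = 10
  folds (sizes differ by at most one); per-fold seeds derive from the
  master seed via `SeedSequence`. Pixel confusion counts are pooled over
  all held-out predictions and normalized once globally
  (micro-averaging), making the result permutation-invariant in fold
  order.

All randomness flows through `numpy.random.Generator` objects seeded from
a single integer, so training, cross-validation and generation are
bit-reproducible.

## Evaluation

All metrics derive from the 3×3 confusion matrix (rows = manual, columns
= predicted): per-class Dice `2TP/(2TP+FP+FN)`; mean Dice as the
unweighted 3-class average; sensitivity `TP/(TP+FN)` and specificity
`TN/(TN+FP)`; a binary collapse summing the fragment/intact block into a
single osteon class; row/column sums as manual/predicted class
proportions. Dice and the rates are invariant to global rescaling, so
count and normalized matrices give identical metrics. Reported values are
rounded (Dice to 2 decimals, rates to whole percent) but raw values are
always retained. An empty class (zero denominator) yields NaN with a
warning rather than a silent 0.

One caveat worth stating: when metrics are recomputed from a matrix whose
entries were *already rounded* (e.g. a published 3-decimal matrix),
rounding noise of up to ±0.0005 per cell propagates into the metrics — a
binary Dice computed from such a matrix can differ in the second decimal
from the value computed on the unrounded counts, and row proportions can
shift by 0.1 points. `metrics-from-cm` reports what the given matrix
implies and does not attempt to undo such rounding.

## Synthetic scenes

The generator emulates the visual grammar of semi-polarized cortical-bone
microphotographs: intact osteons as wobbly ellipses (radius 12–32 px at
the default 256 px scene size) with concentric sinusoidal lamellae and a
dark central canal at 0.15–0.3 of the osteon radius; fragments as
annular-sector crescents (arc 1–4 rad) placed abutting an existing
structure with probability 0.6 (remnants cluster around later osteons);
background as low-frequency blotches with faint streaks; additive Gaussian
noise (σ = 0.03), clipped to [0, 1].

Scenes are built **polygon-first**: structures are placed as polygons, the
mask is produced by the same rasterizer used for real annotations
(fragment-then-intact priority included), and the image is rendered last.
The emitted VIA JSON therefore reproduces every mask bit-exactly, and a
test enforces it.

What the generator does *not* emulate: birefringence color, osteocyte
lacunae, drifting/double-zonal osteon morphology, slide-preparation
artifacts (colored markings, scratches), or the long-range intensity
gradients of real microscopy. Passing tests on synthetic scenes
demonstrate that the pipeline is implemented correctly and can learn this
class of structure from exact ground truth; they do not predict accuracy
on real histology.

## Problem sizes used in the tests

Chosen to exercise every code path at desk scale:

* Learnability benchmark: 50 scenes at 128×128 (40 train / 10 held out),
  structure density scaled to the smaller frame (2–6 intacts, 2–5
  fragments, radii 8–20 px), reduced U-Net (depth 4, 8 base filters),
  up to 60 epochs with patience 15, fixed seed. The trained network must
  beat binary Dice 0.60 and 3-class mean Dice 0.40, and the all-background
  baseline.
* CV reproducibility: two complete 3-fold runs over 12 scenes at 64×64
  with a depth-3/base-4 network, 3 epochs per fold, compared bit-exactly.
* Rasterization: 50 random scenes (≤6 star-shaped polygons, frames up to
  64 px, mixed float and integer-snapped vertices) against a pure-Python
  per-pixel oracle, plus a hypothesis property test of the point-in-polygon
  primitive itself.

## Known limitations

* The fragment class is intrinsically hard (small, rare, irregular);
  fragment Dice is the weakest metric on synthetic scenes too.
* Validation-holdout early stopping spends 10% of each training fold;
  with very small datasets this costs signal.
* The NumPy engine targets correctness and reproducibility on CPU, not
  throughput; 512×512 training at full depth is feasible but slow, and the
  benchmark sizes above are the intended operating point for tests.
* Instance-level analysis (per-osteon counts, areas) is out of scope; the
  output is a per-pixel labelling.
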