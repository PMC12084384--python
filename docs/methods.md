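# Methods

## The transform

The package converts each row of a labeled table into a square grayscale
image in four deterministic steps.

1. **Encoding.** Categorical columns are label-encoded: categories are
   sorted lexicographically and mapped to 0, 1, 2, … . Lexicographic order
   is a design choice made for cross-platform determinism; the
   alternative (first-appearance order) would make the transform depend
   on row order.
2. **Min–max normalization.** Each column is rescaled to [0, 1] using
   minima/maxima fitted on the *training rows only*; validation cells that
   fall outside the fitted range are clipped, and constant columns
   (max = min, where the rescaling formula is undefined) map to 0 — a
   constant carries no information and 0 keeps the pixel dark. Fitting on
   training rows avoids leaking validation statistics into the features;
   the alternative (fitting on all rows) changes values only near the
   column extremes.
3. **Square construction.** A length-N normalized row is stacked into an
   N×N matrix, either by duplication or, in the default
   `duplicate_rotate` mode, as the sequence of its N progressive cyclic
   rotations (row i shifted left by i). The rotated square is a Latin
   square: every value appears exactly once in each row and column, so
   all row and column sums equal the source row's sum — the property the
   conservation tests exercise. "Left" rotation is fixed as
   `output[j] = input[(j+k) mod N]`; the rightward variant produces a
   transposed-equivalent image and is exposed as an option because the
   choice must be pinned for byte-exact reproducibility.
4. **Quadrant tiling.** The N×N square is copied unchanged into all four
   quadrants of a 2N×2N image. Tiling quadruples the pixel sum and gives
   the convolutional stack two extra levels of spatial hierarchy; it also
   guarantees the four stride-2 blocks never collapse below a 1×1 map for
   any N ≥ 2.

Values remain real numbers in [0, 1] throughout the in-memory pipeline and
are quantized to 8-bit (round half-up, byte = ⌊255·v + 0.5⌋) only when a
PNG stack is written. Reading a stack back therefore recovers each pixel
to within 1/510.

When PCA is requested (either a fixed component count, or the smallest
count whose cumulative explained-variance ratio reaches a target fraction
such as 0.95), it is fitted on training rows and applied unchanged to
validation rows. PCA scores are unbounded, so a second min–max pass
(again fitted on training rows) restores the [0, 1] pixel contract before
imaging.

## The classifier

Four convolutional blocks of 64 filters, each `Conv(3×3, stride 2) →
BatchNorm → ReLU`. Padding is chosen per layer from the parity of the
incoming side (0 for odd sides ≥ 3, otherwise 1), which floor-halves the
spatial extent at every block and sends a 31-pixel input through the
15 → 7 → 3 → 1 progression; a 1×1 map is a fixed point. Global average
pooling collapses the 64 maps to a length-64 vector, followed by a dense
hidden layer (width 64 by default, ReLU) and a dense softmax output with
one unit per class. ReLU and the kernel-3/stride-2 parameterization are
the minimal standard choices consistent with the printed map sizes; the
architecture generalizes to any square input ≥ 4 pixels and any class
count ≥ 2.

Training: Adam (β₁ = 0.9, β₂ = 0.999), learning rate 8e-4, batch size 64,
categorical cross-entropy, 30 epochs by default. No early stopping,
weight decay or augmentation. The stratified 80:20 split shuffles each
class with a seeded generator; classes contribute ⌊0.8·m_c⌋ rows
(minimum 1) to training, and single-row classes go entirely to training
with a logged warning. Validation accuracy is recorded after every epoch;
the reported metrics (accuracy, macro precision/recall/F1, confusion
matrix) are computed at the epoch with the highest validation accuracy,
earliest on ties, and the returned model carries that epoch's weights so
`predict()` matches the report. Macro averaging weights every class
equally regardless of size, the symmetric choice for imbalanced medical
tables; per-class precision/recall are defined as 0 when their
denominator vanishes.

The whole network is implemented in NumPy with float32 tensors: im2col
gather + one GEMM per convolution forward, nine strided slice-adds for
the backward scatter, a fused softmax/cross-entropy gradient, and
analytic batch-norm backprop (verified against central finite differences
in the test suite). All randomness — weight initialization, batch order,
split shuffling, data generation — flows from a single integer seed, so a
run is bit-reproducible on one platform/BLAS; bit-identity across
different BLAS builds is not claimed.

## Synthetic data

Three seeded generator families make every stage testable without
downloads:

- **ringnorm**: two balanced multivariate-normal classes, class 0 ~
  N(0, 4I) and class 1 ~ N((2/√d)·1, I), the canonical DELVE/Breiman
  parameterization with d = 20 by default. The classes differ in both
  mean and covariance scale and no single feature separates them, so the
  problem genuinely requires a multivariate decision rule. Exact equality
  with any particular published file of this benchmark is not guaranteed
  — only the generating distributions are matched.
- **gaussian_blobs**: K unit-noise isotropic Gaussians with means at
  `separation · e_i` (standard basis; a (d+1)-th class may sit at the
  origin). `separation` dials the difficulty from chance (0) to trivially
  separable (≥ 8); the defaults used in the acceptance runs (n = 200,
  d = 8, K = 2, separation 8) make a sanity check that any working
  pipeline must pass.
- **categorical_mix**: uniform-[0, 100] numeric columns plus 2–5-category
  string columns, with the label thresholding the first numeric column;
  exercises the label-encoding branch end to end.

These generators emulate the *structure* of benchmark tables (class
count, feature count, separation, mixed column kinds), not their
idiosyncrasies: no missing data, no label noise, no feature correlations
beyond the class structure, no covariate shift between the splits.
Passing tests therefore demonstrate that the mechanism — transform,
architecture, optimization, evaluation — works, not that any particular
real-data accuracy will be attained.

## Problem sizes and numerical choices

The packaged experiment scripts and acceptance checks run at desk scale:
the blobs run trains on 160 16×16 images for 10 epochs (seconds), the
ringnorm-style run on 800 40×40 images for 15 epochs (tens of seconds on
one CPU). These sizes are the package's chosen study conditions for a
mechanism check; the ringnorm benchmark at full size (7,400 samples,
30 epochs) is the same code path, only longer.

Other numerical details: min–max idempotence and affine invariance hold
exactly in exact arithmetic and to ~1e-8 in floats (a column whose spread
underflows under an affine map degenerates to constant and maps to 0);
PNG quantization rounds half up; checkpoint files are NumPy `.npz`
archives holding every parameter and batch-norm running buffer plus a
JSON architecture header.

## Known limitations

- The transform uses the given feature order; it does not search for a
  layout that groups correlated features, by design. Orderings are not
  augmented.
- Images scale as O(n²) pixels per row (4n² after tiling), which is
  wasteful for very wide tables; PCA reduction is the provided mitigation.
- Missing cells are rejected, not imputed — silent imputation would
  change the transform's semantics.
- Training is single-CPU NumPy: adequate for thousands of rows and images
  up to ~100 pixels a side, not for ImageNet-scale work.
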