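# Methods

## Model

`hybridcs` classifies each labeled pixel of a hyperspectral scene from the
`C × C × P` patch centered on it (`C` odd so the center is unique; the
patch label is the center pixel's class). Two branches extract features in
parallel.

**Spectral–spatial branch.** The patch enters as a single-channel 3-D
volume. The first 3-D convolution uses a `(1, 1, 7)` kernel with spectral
stride 2 and valid spectral padding — for `P = 100` input bands the
spectral depth becomes `(100 − 7)/2 + 1 = 47` — with 24 filters. Two
further `(3, 3, 3)` convolutions (same-padded in all three axes, 24
filters) mix neighboring bands and pixels without changing the shape. The
`47 × 24` spectral-by-filter axes are then reshaped into channels and
collapsed by a `1 × 1` 2-D convolution to 60 channels, and global average
pooling yields the 60-d branch feature. Activations throughout are Smish,
`x · tanh(ln(1 + σ(x)))`, evaluated with `log1p` and a split-sign sigmoid
so large magnitudes cannot overflow; this branch carries no batch
normalization.

**Sandglass branch.** The same patch viewed as a `P`-channel 2-D image
passes through two C-B-M units (3×3 convolution → batch norm → Smish,
width 24) alternating with two sandglass blocks. A sandglass block is an
inverted-bottleneck residual unit

    y = x + BN(dw3x3( smish(BN(pw 6→24( BN(pw 24→6( smish(BN(dw3x3(x))) )) ))) ))

— depthwise 3×3 convolutions at both (wide) ends, a pointwise reduce →
expand pair through a width/4 bottleneck, Smish after the first depthwise
and the expanding pointwise, batch norm after every convolution, and the
identity shortcut connecting the 24-channel representations. Keeping the
depthwise convolutions in the wide representation encodes spatial detail
cheaply; the shortcut at high dimension preserves low-level information
and keeps gradients flowing. The branch ends with a stride-1 3×3 average
pool, global average pooling to 24, and a linear expansion to 60.

**Fusion and head.** The two 60-d features are concatenated to 120 —
concatenation rather than addition, because the branches live in different
feature domains and addition would entangle them — then projected back to
60 by a learned linear map with batch norm and Smish. A final linear layer
produces `K` raw class scores. There is no softmax: training minimizes the
squared Weston–Watkins multiclass hinge

    L = (1/n) Σ_i Σ_{j≠y_i} max(0, m − s_{y_i} + s_j)² + λ‖W_head‖²,

with margin `m = 1` and weight decay `λ = 5·10⁻⁴` applied to the head
weights only, so the network behaves as a soft-margin machine on deep
features. Prediction is the argmax of the scores, ties broken toward the
lowest class index.

The interpretation of the fusion stage deserves a note: the reference
layer table lists a 60-d joint vector *and* a 60-wide post-fusion C-B-M,
which cannot both hold literally for a 60+60 concatenation; this package
resolves the conflict as concat-to-120 followed by a learned projection to
60, honoring both printed widths. Likewise the first sandglass-tunnel
C-B-M is read as a 3×3 convolution over the `P` spectral channels (its
"×1" third axis taken as the collapsed spectral dimension), and the
follow-up 3-D kernels — whose sizes the table omits — are `(3,3,3)`
same-padded, the only standard choice that reproduces the unchanged
printed shapes. The spectral stride of the first 3-D convolution is
likewise not stated anywhere; stride 2 with valid padding is the unique
setting mapping 100 bands to the printed depth 47.

## Optimization

Mini-batch SGD with momentum 0.9; gradients come from a small tape-based
reverse-mode autodiff core written on NumPy (convolutions lowered to
gather + matmul; the gather adjoint is a precomputed sparse scatter
matrix). Per epoch the training set is reshuffled with a seeded generator;
per-epoch training loss/accuracy and validation accuracy are logged, and
the weights with the best validation accuracy are restored at the end.
Training aborts with the last finite state if the loss diverges. Three
presets are provided: `paper-epochs` (lr 0.001, batch 100, 1000 epochs)
and `paper-iterations` (lr 0.001, batch 256, 50 epochs) mirror the two
published regimes, and `desk` (lr 0.01, batch 100, 25 epochs) is the
CPU-scale default. On scenes smaller than ~64×64 the tests drop the batch
size to 32 and raise the rate to 0.02 — a few hundred training patches
give too few batch-100 updates per epoch to converge. With a single-seed
initialization all runs are bit-reproducible.

Inputs are standardized per band to zero mean and unit variance with
statistics computed on the training patches only (variance clamped at
1e-8 for degenerate bands); this is an optimization aid, switchable off,
not a claim about the sensor.

A post-hoc alternative head is available (`svm_refit`): an RBF-kernel
soft-margin classifier (with internal feature standardization) fit on the
frozen 60-d fused features, the classical two-stage deep-features-plus-SVM
reading of the architecture.

## Pipeline

Rasters load from ENVI (any of BSQ/BIL/BIP interleaves), GeoTIFF or HDF5
into a band-last `M × N × Q` array with 0-based `(row, col)` indexing.
Spectral PCA (full SVD, fit on all pixels) reduces `Q` bands to `P`
components; component signs are fixed so each column's largest-magnitude
entry is positive, making the fit deterministic. Patch extraction is
valid-window only — border pixels whose `C × C` window would leave the
image are skipped, so a fully labeled scene yields exactly
`(M−C+1)(N−C+1)` patches. The stratified split draws
`round(fraction × count)` training patches per class (minimum 1, seeded,
disjoint and exhaustive). The band-count parameters are deliberately
configuration, not constants: the architecture contract is checked at
`P = 100` (the reference table's input depth), while desk-scale training
uses `P ≈ 8–10` — with `K = 6` species the class structure spans at most
6 spectral dimensions, so little is lost and CPU cost drops sharply.

## Synthetic scenes

The generator emulates the regime of a boreal forest survey:

* **Endmembers** — per class, a sloped baseline plus 3–6 Gaussian bumps
  (widths 2.5–8 bands, amplitudes −0.25–0.35), lightly smoothed and
  clipped to [0, 1.5]; libraries are redrawn until all pairwise L2
  distances reach the configured separation (default 0.5) and adjacent
  bands differ by at most 0.2 (spectra of vegetation are smooth).
* **Label maps** — seeded Voronoi growth: `⌈MN/s²⌉` seeds for region
  scale `s` (default 12 px), one seed placed in the central part of each
  cell of a jittered grid (near-equal cell areas keep realized class
  frequencies within ±5 points of target), classes allocated to seeds by
  largest remainder with at least one seed per class, each pixel labeled
  by its nearest seed. Spatial contiguity is the property the spatial
  branch exploits.
* **Default composition** — K = 6 classes with proportions 0.523 / 0.158
  / 0.232 / 0.012 / 0.062 / 0.014 (birch, larch, mongolica, poplar,
  spruce, willow — the survey's ~43:1 imbalance), 96 × 96 pixels, 40
  bands.
* **Radiometry** — pixel spectrum = class endmember + per-pixel scalar
  brightness jitter (σ = 0.02, emulating illumination/canopy variation as
  a spectrally correlated offset) + i.i.d. white noise per band
  (σ = 0.2 by default).

What the generator does **not** emulate: mixed boundary pixels (each
pixel belongs to exactly one class), sensor point-spread, band-correlated
noise, atmospheric effects, and spatially varying illumination. Passing
tests on these scenes therefore demonstrate that the implementation
learns joint spectral–spatial structure under noise and imbalance — not
that any particular accuracy level transfers to real imagery.

## Numerical choices and degenerate inputs

* Convolution layers are checked against direct nested-loop references to
  1e-5 (float32 path).
* Batch norm: ε = 1e-5, running-statistics momentum 0.1; a training batch
  of one sample falls back to running statistics with a warning.
* PCA orthonormality is enforced to 1e-6; explained variances are
  sample variances (n−1 denominator).
* Average accuracy excludes classes with no test samples (with a warning)
  rather than scoring them zero; an empty confusion matrix or degenerate
  kappa denominator raises instead of returning a number.
* Argmax ties go to the lowest class index; splits guarantee at least one
  training sample per class; zero-variance bands are clamped, not
  dropped.
* One global seed fans out to scene, split, initialization and shuffle
  sub-seeds via `SeedSequence([seed, role])`, so every stage is
  independently reproducible; HDF5 outputs disable timestamp tracking so
  identical runs produce byte-identical files.

## Problem sizes used by the test suite

The architecture contract runs at full reference size (7×7×100). The
end-to-end species-recovery check uses the default 96×96×40 scene with
10 PCA components, a 30% stratified split and 10 desk-preset epochs. The
sandglass ablation (5 paired replicates × 2 variants) and the
training-fraction trend (fractions 0.1/0.3/0.5/0.8 × 2 replicates) run on
48×48 versions of the default scene with 8 components and 6 epochs —
small enough that the whole suite trains a few dozen networks in minutes,
large enough that all six classes keep two-digit test counts.

## Known limitations

* **Boundary pixels.** Both branches end in global average pooling, so
  the decision is driven by the whole window, not the center pixel; a
  center whose 7×7 window is majority another class is systematically
  outvoted. On synthetic scenes every observed error lies within 1 px of
  a class boundary, and training accuracy itself saturates once only
  boundary-adjacent patches remain wrong. Maps are correspondingly
  smooth, at the cost of a one-pixel error band along stand edges.
* A border ring of width `(C−1)/2` is never classified (no padding at
  prediction time either).
* The NumPy training path is single-core and patch-scale; it is meant for
  scenes of order 10⁴–10⁵ labeled pixels, not airborne campaigns.
* Batch-norm running statistics are part of the checkpoint; evaluating an
  untrained model uses the (0, 1) initialization.
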