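# Methods

## Model

The package implements a *stochastic binarized convolutional neural
network* (SBCNN): a binarized neural network (BNN) whose first layer
consumes stochastic binary samples of the input image instead of int8 or
float pixels, so that **every** arithmetic operation at inference is a
one-bit XNOR-accumulate.

### Input encoding

Pixels are standardized per channel on the training split,
`X_r = (X_d − μ_i)/σ_i` (population statistics, ddof 0).  A single binary
presentation compares each pixel to a random threshold:

* **normal sampling** — the threshold is drawn from the raw-domain
  normal `N(μ_i, σ_i)`, equivalently `X_r` is compared to a standard
  normal draw, so `P(bit=1) = Φ(X_r)`.  The printed form of the
  comparison ("normalized value vs `randn(μ_i, σ_i)`") would saturate
  for raw-scale parameters; we implement the self-consistent reading and
  expose the threshold distribution as an argument (`thresholds=`) for
  anyone who wants the literal variant.
* **uniform sampling** (baseline) — pixels are min-max rescaled to
  [0, 1] per channel over the training split and compared to a uniform
  draw, so `P(bit=1)` equals the rescaled intensity.

Averaging `N_pre` independent presentations gives the stream mean `X_m`,
an unbiased estimate of the sampling probability with variance
`Φ(1−Φ)/N_pre` — the 1/√N convergence that the test suite checks as a
log–log slope of −0.5.

The physical randomness source modelled is the cycle-to-cycle resistance
variability of an OxRAM cell feeding a comparator.
`device_threshold_sequence` is a behavioural model only: truncated-normal
resistances mapped through a configurable monotone voltage mapping.  With
an affine mapping it reproduces plain normal-threshold sampling; no
circuit-level effects (comparator offset drift, cycling endurance) are
modelled.

### Binarized arithmetic

Weights and activations live in {−1, +1}; a neuron computes
`y = sign(popcount(XNOR(w, x)) − b)` with a learned integer threshold
`b`.  Conventions fixed package-wide:

* `sign(0) = +1` everywhere (sampling ties, presentation-aggregation
  ties, neuron ties).
* Bit packing is little-endian within 64-bit words; padding bits are
  stored as zero and masked out of every popcount.
* Binarized convolutions pad with **−1**, not 0, so border windows stay
  inside the ±1 algebra and the XNOR-popcount identity
  `popcount(XNOR) = (n + w·x)/2` holds exactly at borders.

### Inference

The stochastic layer runs once per presentation: each presentation's
binary input passes through the first binarized convolution and its sign
output `a_n` is recorded; the aggregate `A_0 = sign(Σ a_n)` (ties → +1)
feeds the remaining binarized layers, which run once.  The final layer
emits integer pre-sign scores used for ranking.

### Batch-norm folding

Training places batch norm after every binarized conv/fc layer.  At
export the affine transform is folded into the integer threshold: the
float path fires iff `γ(a−μ)/√(v+ε) + β ≥ 0`, i.e. iff `a ≥ θ` with
`θ = μ − βσ/γ` (for `γ > 0`); since the popcount is an integer, the exact
integer threshold is `b = ⌈(n+θ)/2⌉`.  A negative `γ` is handled by
negating that output channel's weight row.  We use the ceiling rather
than round-to-nearest because it is the *exact* fold: the folded integer
path reproduces the float batch-norm + sign path bit for bit, which the
suite verifies on random networks and on trained models.  The exported
container keeps the pre-fold parameters so the equivalence can be
re-checked on any model.

Integer dot products in the exported path are carried in float64 BLAS
words; all values are integers well below 2^53, so this is exact.

### Training

Binarization-aware training in the Courbariaux style, implemented in
NumPy: real-valued shadow weights, `sign` on the forward pass, the
straight-through estimator with a hard-tanh window (gradient passes where
|pre-activation| ≤ 1) on the backward pass, shadow weights clipped to
[−1, 1] after each Adam step.  The stochastic input layer re-samples its
bitstream every forward pass with `n_train` presentations — sampling acts
as data augmentation, which is what makes the training presentation count
meaningful.  During training the presentation aggregate is the sign of
the presentation *mean* (identical forward semantics to the sign-of-sum,
with the STE applied through it).  The output layer has no batch norm and
no bias, so its integer scores rank classes identically in the integer
and float paths; the softmax cross-entropy loss scales scores by
1/√fan-in.

Presentation strategies: *matched* trains and infers with the same
`N_pre`; *max* trains at the maximum presentation count (256) and infers
at a smaller `N_pre`.  Batch-norm statistics are frozen at export and are
not re-estimated at the inference presentation count.

## Detector

Sliding windows with 50% overlap in both axes; the last window along each
axis is snapped inside the image.  Each window is classified and its
score is added to every pixel it covers.  The window score is the
classifier's *hard positive decision* (1/0) rather than the raw integer
margin: the heat map then counts how many of the (uniformly 4, in the
interior) covering windows voted positive, a scale comparable across
objects, whereas margin magnitudes vary with how centred an object sits
in its windows.  The raw-margin variant remains available
(`hard=False`).

The heat map is min-max normalized (a constant map becomes all zeros)
and thresholded at t = 0.5 by default; 8-connected components yield
tight bounding boxes scored by their mean normalized heat; greedy NMS at
IoU 0.3 removes duplicates.  Boxes are 0-based and half-open.  Matching
against ground truth is greedy one-to-one in descending score order with
an IoU ≥ 0.3 criterion.

## Synthetic data

The generator is a statistical stand-in for annotated microscopy fields
(thick-smear parasites, sputum bacilli, stool-slide eggs), not an attempt
at photorealism:

* **Scenes** — textured background (mean colour + low-frequency mottling
  + iid pixel noise) with `n` planted non-overlapping parametric objects
  (disk / rod / ellipse).  Object colour sits at Mahalanobis distance
  `contrast` (default 6) from the background mean in background-noise
  units.  Defaults: 132×132 px fields, 6 objects of 10–16 px, noise σ=10,
  mottling amplitude 8.  Objects keep a 12 px separation between boxes
  and a 12 px inset from the field border — pathogens in these datasets
  are sparse, and annotations avoid the vignetted field edge; both
  margins also make the ground truth unambiguous for box-level scoring.
* **Slices** — positives are crops centred on each truth box, expanded
  by the 8 dihedral transforms, each copy jittered by a shift bounded by
  both the box half-size and a quarter of the patch (the patch centre
  stays inside the box, and the object stays dominant); negatives are
  random crops with zero IoU against every box, oversampled at 16 per
  object and kept with probability 0.5, which roughly balances the
  8×-augmented positives and mimics the discard-negatives rebalancing
  used for real slice datasets.
* **Classification set** — smooth per-class colour/texture templates at
  pairwise RMS distance `separation` plus iid pixel noise; the Bayes
  error shrinks as separation/noise grows.

What passing tests on these data do **not** show: robustness to stain
variability, focus blur, occlusion, object clustering or annotation
noise — none of which the generator emulates.

## Study conditions (desk scale)

Problem sizes were chosen so each study runs in minutes on one CPU core.

* **Presentation-strategy study** — 4 classes, 12×12 RGB, 60 train / 40
  test per class, separation 4, noise 2 (hard enough that a 2-presentation
  stream visibly hurts); mini binarized CNN (conv 3→12 stochastic stem,
  conv 12→24, fc output); matched at N_pre ∈ {2, 8, 32} vs max trained at
  256; Adam lr 5·10⁻³, 6 epochs, batch 64; 5 trials with derived seeds.
* **Detection study** — 45 training scenes / 20 test scenes (120 truth
  objects); reduced mini SBCNN (width 24) on 12×12 slices; matched
  N_pre = 32 for training and inference (the setting used for the
  full-scale detector); window 12, overlap 0.5, threshold 0.5, NMS IoU
  0.3; mAP at IoU 0.3.

The full 224×224 AlexNet variants are pinned for cost accounting (they
reproduce the published memory cells; see below) and can be instantiated,
but training them is deliberately out of desk scale; a reproduction
script for the full-scale pipeline is the CLI itself
(`sbcnn train/experiment` with larger sizes).

## Hardware cost model

Parameter counts cover conv/fc weights and biases only; batch-norm
affine parameters fold into thresholds at export and carry no weight
memory.  "MB" is binary MiB (2²⁰ bytes): under the pinned 2-class
architecture this reproduces the published int8 cell (54.37) exactly and
the fp32/binary cells to ≤0.12%, which decimal MB does not.  Binary
memory applies a per-layer ceiling to whole bytes.

Tile mapping: weight matrices are partitioned into 32×32 blocks mapped
onto a 32×32 grid of 2T-2R crossbar tiles; one row per cycle → 32 cycles
per resident pass; blocks beyond the 1024-tile capacity serialize into
additional passes; one 5-bit look-up table per block for partial-sum
reduction.

The energy model is `Σ ops_k · E_k` with a configurable per-operation
energy table.  The shipped constants are **illustrative placeholders**
for relative comparisons only — absolute energies require
platform-measured constants supplied by the user.

## Numerical and design notes

* Population (ddof 0) channel statistics; constant channels raise with a
  floor-value suggestion rather than silently clamping.
* Max pooling is non-overlapping at runtime (kernel = stride); gradient
  ties route to the first maximum.
* Average precision uses all-points step integration (the
  scikit-learn definition); ROC AUC is trapezoidal with tied scores
  grouped.  Note that an AUC of 0.5 is an *uninformative* classifier,
  not the worst possible one (an anti-correlated classifier scores
  below 0.5); we implement the standard definition.
* Training is float32 with float64 batch-norm statistics and Adam
  moments; a seed-fixed single-threaded run is bit-reproducible.
* Divergent training (NaN loss) raises with epoch/batch diagnostics
  instead of returning a broken model.

## Known limitations

* The NumPy training engine is desk-scale: it is single-threaded and
  keeps im2col buffers in memory; full-scale 224×224 training is out of
  scope.
* The OxRAM noise model is behavioural; no 2T-2R/PCSA circuit
  simulation.
* Detector components assume objects comparable to the window size;
  window-scale blobs cannot localize objects much smaller than the
  window (choose the slice size accordingly).
* mAP here is the AP of the single pathogen class (binary detection);
  multi-class detection would average per-class APs.
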