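# Methods

This note records the models the package implements, the assumptions and
parameter choices behind them, and what the synthetic experiments do and do
not demonstrate.

## Synthetic phantoms

A specimen is an H × W × Λ stack of per-wavelength intensity images. The
generator places one elliptical lesion (uniform random center, semi-axes and
rotation; one lesion per specimen, since real lesion counts are unknown) in a
spectrally flat background of intensity 0.2. Lesion pixels carry a smooth
class mean-absorption profile: both classes share a Gaussian absorption bump
(peak at 35 % of the wavelength axis, amplitude 0.6 — this is what separates
lesion from background and makes segmentation learnable), and the cancer
class adds a second bump at 65 % of the axis with amplitude
`effect_size × noise_sigma`, so the per-voxel standardized mean difference
between classes at the discriminative wavelengths equals `effect_size`.
Setting `effect_size = 0` produces a proper null dataset: lesions remain
segmentable but carry no class information.

Noise follows the standard first-order model for ultrasound-derived images:
multiplicative speckle `I · (1 + s·u)` with `u ~ N(0,1)` (default s = 0.05)
followed by additive Gaussian noise (default σ = 0.05). Defaults for geometry
are 64 × 64 × 200; per-specimen heights can be drawn from a range such as
20–64 to emulate non-uniform acquisition extents that the resizing stage must
normalise. All generators are pure functions of (config, seed).

What the phantoms deliberately do **not** model: photoacoustic wave
propagation, fluence inhomogeneity, depth-dependent attenuation, multiple or
non-elliptical lesions, and correlated (structured) noise. Passing tests on
phantoms therefore demonstrate correctness and internal consistency of the
pipeline, not clinical performance.

The abstract feature-selection benchmark draws an n × d matrix of unit
Gaussian columns and shifts k recorded "informative" columns by the effect
size in class-1 rows; it exercises the selector against known ground truth
independently of the imaging stages.

## Bilateral filter and resizing

Both kernel forms are Gaussian (spatial scale σ_s in pixels, range scale σ_r
in intensity units); the window is a square of half-width `ceil(3 σ_s)`,
truncated at the image border with weight renormalisation (no padding, so no
border artifacts and the output is always a convex combination of input
values). σ_s = 2 px and σ_r = 0.1 are exposed defaults, not claims. The
implementation is the vectorised offset-loop form and is tested for exact
agreement with a literal double-loop evaluation of the definition, and for
convergence to a truncated Gaussian blur as σ_r → ∞.

Resizing is per-wavelength bilinear interpolation in the **corner-aligned**
convention (output grid `linspace(0, H−1, H′)`), chosen and stated explicitly
because conventions differ between libraries; corners are preserved exactly
and constant images are fixed points. Indexing is 0-based (row, col,
channel).

## Segmenter

A compact encoder–decoder. Encoder: `n_downsamples` stages, each a
downsampling block (3×3 stride-2 convolution concatenated channel-wise with a
2×2 max pool, so output channels = conv channels + input channels) followed
by `n_ssnbt_per_stage` split-shuffle residual units — channels split in half,
each half through factorized 3×1 → ReLU → 1×3 convolutions with the second
half dilated (dilation 1, 2, … per unit), halves concatenated, channel-
shuffled with 2 groups, then added to the input. The shuffle is applied to
the branch output *before* the residual addition so that zero weights give an
exact identity, a property the tests rely on.

Decoder (attention pyramid): linear stride-2 convolutions with kernels 3, 5
and 7 fused coarse-to-fine by bilinear upsampling and addition; the fused map
passes through **tanh** to give a bounded attention gate (zero weights ⇒ zero
attention, and the bounded gate is what keeps plain gradient descent on the
multiplicative path stable — an unbounded gate diverges, a ReLU-gated one
suffers dead units whose gradient never recovers); the gate multiplies a
1×1-projected encoder map pixel-wise, a global-average-pooling branch is
added, and the sum is upsampled to input resolution as per-pixel lesion
logits.

Multispectral stacks enter the 2-D network after uniform band averaging
(Λ → 8 bands by default; the full Λ-channel input is configurable but slow on
CPU) and per-band z-scoring per specimen — the standardisation is essential
for plain gradient descent to converge at a single global learning rate.
Training is full-batch gradient descent on per-pixel binary cross-entropy,
with the step scaled down when the global gradient norm exceeds 5.0 (the
attention path can spike in the first steps). Default lr = 0.5, chosen as the
largest rate stable across seeds at desk scale; channel widths (16/32) and
stage depth are small for CPU trainability and config-exposed. Binary masks
use threshold 0.5; overlap is reported as Dice.

The network and its gradients are an in-repo reverse-mode autodiff over
float64 NumPy arrays (`nn.py`). Gradient correctness is checked against
central finite differences on decoder parameters, which sit behind smooth
operations only; probing parameters upstream of ReLUs with finite
differences is unreliable at kinks and is deliberately avoided.

## Hybrid swarm/colony wavelength selection

The selector couples two population metaheuristics over d features:

- **Particle swarm** in continuous R^d. Velocity update
  `F' = δ·F + l₁·r₁⊙(O−C) + l₂·r₂⊙(P_gbest−C)` with fresh per-dimension
  uniforms r₁, r₂, element-wise clamp |F'| ≤ V_max, position update
  C ← C + F'. A variant with (O−C) in *both* stochastic terms — no social
  pull — is available behind `printed_form=True` for comparison; it is not
  the default because it never communicates the global best to the swarm.
  A particle's position decodes to the subset of its k largest components
  (ties: lowest index). Defaults: l₁ = l₂ = 2, V_max = 4, inertia δ
  annealed linearly 0.9 → 0.4 over the run, N = 20 particles, 30 iterations.
- **Ant colony** over feature indices. Selection probability
  `P_j = μ_j^α φ_j^β / Σ_i μ_i^α φ_i^β` (defaults α = 1, β = 2); the
  heuristic φ_j is the absolute Fisher score of feature j (class-mean
  difference over pooled SD). Ants draw k distinct indices without
  replacement proportional to P. Pheromone update: evaporation
  μ ← (1−ρ)·μ with ρ = 0.1, then the elite solution's features receive its
  fitness as deposit; μ is floor-clamped at 10⁻³ so no feature's probability
  ever vanishes.
- **FinalBest recombination.** Each iteration the colony champion (fitness
  f_best) and swarm champion (f_gbest) are compared:
  `P_best = f_best/(f_best+f_gbest)` (its complement is computed as
  `1 − P_best` so the two probabilities sum to 1 exactly in floating point);
  a uniform draw r selects the colony champion if `r < P_best`, else the
  swarm champion. FinalBest is injected back as the swarm's global best
  (encoded as the subset's indicator vector) and as the colony's deposit
  target. With elitism (default) the best FinalBest so far is retained and
  its fitness history is non-decreasing.

The wrapper fitness is mean stratified k-fold (default 3) cross-validated
accuracy of a Euclidean nearest-centroid classifier on the candidate columns,
minus `λ·|subset|/d` (λ = 0 by default since k is fixed). Nearest-centroid
was chosen as the cheapest classifier consistent with the spectral-shift data
model; the CV inner loop is hand-vectorised because it runs ~10⁴ times per
selection, and is unit-tested for exact agreement with scikit-learn's
`NearestCentroid` on identical folds. Fitness is deterministic given the fold
seed, which is derived once per run.

From images, the per-specimen feature vector is the per-wavelength mean
intensity inside the predicted segmentation mask (d = Λ features); masking
rather than cropping keeps the feature dimension fixed.

## Recurrent classifier

Elman cell, `h_t = tanh(W_ih x_t + W_hh h_{t−1} + b_h)`, h₀ = 0, softmax
readout of the final hidden state; no gating, matching the minimal recurrent
design. The wavelength axis is the time axis — the only ordered axis
available per specimen; each selected wavelength contributes one step with
features (masked mean, masked SD). Inputs are z-scored per feature over the
training set; the scaler is stored with the model.

Training: cross-entropy with backpropagation through time, global
gradient-norm clipping at 5.0, learning rate `lr(t) = lr0 · exp(−γ·t)` with
lr0 = 0.01 and γ = 0.1 per epoch (a multiply-by-γ step schedule is
selectable via `decay_mode="step"`, but it reduces the rate a thousandfold in
three epochs and is not the default). Because this schedule leaves only
~`lr0/γ` of cumulative step size, updates are applied **per example**
(shuffled each epoch, seeded) rather than once per epoch: with n training
sequences each epoch then contributes n steps of progress, which at desk
scale (n ≈ 28) is the difference between converging and remaining at the
initialisation. Ties in the argmax prediction resolve to class 0.

## Evaluation

Stratified splitting allocates `round(n · fraction)` training items by
largest remainder across classes, clamped so both classes appear on both
sides (exactly reproducing an 11/5 → 8+3 / 3+2 allocation at fraction 0.7).
Precision, recall and F-measure are computed per class one-vs-rest from exact
confusion counts and reported in percent; a zero denominator raises (or, in
report building, flags the class) rather than silently reporting 0. Both
macro and support-weighted averages are emitted, since the two differ and
neither is canonically "the" average. ROC-AUC is the threshold-sweep /
Mann–Whitney statistic with ties counted ½ (scikit-learn's `roc_curve` /
`roc_auc_score` underneath, cross-checked against `scipy.stats.mannwhitneyu`
in the tests). Rounding to integer percent happens only at presentation.

## Pipeline and reproducibility

One master seed; each stage's seed is the first four bytes of
SHA-256(`"{master}:{stage}"`) reduced mod 2³¹, so stages re-run independently
and deterministically. Identical config + seed gives byte-identical
serialized reports. Every intermediate (filtered stacks as multi-page TIFF +
JSON sidecars, masks as PNG, selected wavelengths, model containers,
history CSVs, the report, a manifest of seeds and versions) is written to the
run directory. Degenerate predicted masks (no lesion pixel) fall back to the
whole image so feature extraction never sees an empty mask.

## Problem sizes used in the shipped experiments

The end-to-end experiments in the test suite and acceptance script run at
desk scale, chosen so the whole suite completes in minutes on one CPU: 40
specimens of 32 × 32 × 32 (heights drawn from 20–32 before resizing), 8
segmenter bands, 150 segmenter steps, a 15-particle/15-iteration selector
choosing k = 6 of 32 wavelengths, and 150 classifier epochs; feature
recovery uses n = 200, d = 50, k = 5 at effect size 1.5 over 10 seeds; the
segmenter overfit check uses 8 phantoms and 500 steps. The phantom
generator's own defaults remain the full 64 × 64 × 200 geometry.

## Known limitations

- The phantom model is deliberately simple; none of the reported numbers
  transfer to real photoacoustic data.
- The segmenter trains by plain gradient descent and is sensitive to the
  learning rate above ~1; the bounded attention gate and input
  standardisation are required for stability.
- The paper-style decaying schedule freezes the recurrent classifier after
  roughly 50 epochs; longer training does not improve it, only more steps
  per epoch (or a smaller decay) would.
- PSO positions are continuous and decoded by top-k; subsets whose indicator
  vectors are far from the swarm's operating region can be hard for the
  swarm (not the colony) to represent early in a run.
- The full 200-wavelength segmenter input is supported but slow on CPU;
  band averaging is the practical default.
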