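# Methods

## Decay model and time base

The package models each pixel's TCSPC histogram as an instrument-response-
convolved bi-exponential. The time axis is `TimeAxis(n_bins, window_ns)`
with 256 bins over 12.5 ns by default (bin width 12.5 ns/256 ≈ 48.83 ps,
matching an 80 MHz TCSPC configuration). Bin k carries the decay value at
its leading edge t = k·Δt; frame numbers quoted to users are 1-based with
the trailing-edge time convention (frame 65 ↔ 65·Δt ≈ 3.17 ns), which is how
decay-peak positions are conventionally reported.

The expected signal is

    m(t) = A · (IRF ⊛ d)(t) / Σ(IRF ⊛ d) + b,
    d(t) = α₁ e^(−t/τ₁) + (1 − α₁) e^(−t/τ₂),

a discrete causal convolution with zero padding (no incomplete-decay
wrap-around) normalized so the signal photons integrate exactly to the
amplitude A, plus a constant background b per bin (default 0). The
amplitude-weighted mean lifetime is τ_m = α₁τ₁ + (1 − α₁)τ₂. Simulator and
fitter share one implementation of this forward model
(`flimclass.decaymodel.forward_model`), so generator-fitter closure tests
are exact by construction.

**IRF.** Real systems measure their IRF; the package synthesizes a Gaussian
with FWHM 250 ps (typical for multiphoton TCSPC). The default center,
2.975 ns, is a package calibration: it is chosen so that the noiseless decay
peak of every class preset lands at frame 64–65 of the default axis, where
NAD(P)H TPSF peaks are typically observed. (The convolution shifts the peak
roughly 150 ps past the IRF center, so the center itself sits earlier than
the peak.) IRF shift estimation is out of scope; the fitter receives the
kernel as known.

## Synthetic data generator

The generator emulates fields and single cells of metabolically clamped
cells:

* **Class presets.** Glycolysis: α₁ = 0.79, τ₁ = 400 ps, τ₂ = 1800 ps.
  OXPHOS: α₁ = 0.68, same lifetimes. Glutaminolysis: α₁ = 0.68,
  τ₂ = 1900 ps. The α₁ values are the published population-average decay
  fractions for the three pathways; lifetimes sit mid-range of free
  (300–500 ps) and protein-bound (1.5–2 ns) NAD(P)H.
* **Surrogate cues.** Measured average decays do not distinguish OXPHOS
  from glutaminolysis (both α₁ = 0.68); whatever separates them in real
  data is not an established scalar. The generator therefore injects two
  explicit surrogate cues: the +100 ps τ₂ offset above and a spatial
  texture difference — networked cytoplasmic intensity (connected patches,
  ~4 px correlation length) for OXPHOS versus punctate bright puncta for
  glutaminolysis, with diffuse texture for glycolysis. The assignment is
  motivated by mitochondrial morphology differences across metabolic states
  (fused networks under oxidative metabolism, fragmentation under
  glycolysis) but is a modelling choice, not a measured fact. Benchmarks
  that separate all three classes therefore demonstrate that the CNNs can
  exploit joint spatio-temporal structure of this kind — not that real
  OXPHOS/glutaminolysis cells carry exactly these cues.
* **Cell geometry.** Elliptical cells (semi-axes 4.5–8 px, ~1 µm/px) with a
  concentric elliptical nucleus at ~0.4–0.5 of the cell axes. The nucleus is
  dimmer than the cytoplasm by a factor of 2–3 (cytoplasm holds more
  NAD(P)H); textures are normalized to unit mean over the cytoplasm so the
  cytoplasm-to-nucleus intensity ratio is preserved in expectation.
* **Heterogeneity.** Hierarchical jitter: per-cell parameters are drawn
  around the preset means with CV 5% (a realistic cell-to-cell spread for
  NAD(P)H lifetime parameters), then per-pixel parameters jitter around the
  cell means with CV 2%.
* **Noise.** Photon counts are independent Poisson draws of the expected
  stack; `photon_budget` (default 800 expected photons per cytoplasm pixel,
  giving ~10⁵ photons per cell) sets the brightness. A noiseless mode
  returns expectations for oracle tests. Everything is a pure function of
  (inputs, seed).

Not emulated: optical PSF blur, detector afterpulsing, dark counts (offset
defaults to 0 but is supported), IRF drift/shift, multiphoton excitation
physics, NADH/NADPH discrimination, cell-cell contact and overlapping
segmentation errors, and the full morphological diversity of real cells.
Passing benchmarks on this generator shows the pipeline is correct and that
the architectures can learn joint spatio-temporal decay structure at
realistic photon budgets; it does not certify accuracy on real FLIM data.

## Preprocessing

Per-cell extraction crops the tight bounding box of each mask label and
zeroes pixels of other cells inside the box. Quality control computes the
Shannon entropy (256-bin gray-level histogram over [0, max], in bits) of
each cell's peak frame — the frame with maximum summed photons, 1-based,
ties to the earlier frame — and retains cells within μ ± kσ of the entropy
distribution (Gaussian approximation, default k = 2; σ = 0 retains all with
a warning). Cells are zero-padded to 40 × 40 (extra pixel bottom/right when
odd) and center-cropped to 21 × 21; cells larger than 40 px in either
dimension are excluded with a log entry.

Temporal down-sampling applies a window-3 mean (MD) or median (MEDD) filter
along T with edge replication, extracts the 1-based odd frames (output
length ⌈T/2⌉; 256 → 128), and rounds back to integer counts. The operation
is not idempotent. For noiseless decays the peak moves from frame 64–65 to
≈ ⌈peak/2⌉ (31–33); the ±1-frame tolerance used in tests covers the
filter-induced shift.

Dataset assembly uses seeded stratified splitting. Train/val/test tags are
allocated per class by largest-remainder apportionment so the global counts
are exactly round(n·fraction) (100 cells → 70/10/20); folds come from
stratified k-fold (default 5). Every preprocessing step is deterministic
given the seed.

## Classical decay fitting

`BiexponentialDecay(counts, irf, axis).fit()` estimates
(τ₁, τ₂, α₁, A, b) within bounds (τ₁ ∈ [100, 800] ps, τ₂ ∈ [1000, 3000] ps,
α₁ ∈ [0, 1]), initialized at τ₁ = 400 ps, τ₂ = 1800 ps, α₁ = 0.7,
A = total counts. The default objective is the Poisson maximum likelihood,
implemented as signed square-root deviance residuals inside a bounded
trust-region least-squares solver — at photon counts of 10⁴ per decay this
estimator is essentially unbiased (|bias(α₁)| < 0.01), whereas weighted
least squares with data-based Poisson variances (available as
`objective="wls"`) is biased low by ~0.03 because empty tail bins are
over-weighted. Component ordering τ₁ < τ₂ is enforced by swap after the
fit; non-convergence returns best-effort parameters with a flag rather
than raising. A minimum of 500 photons is required.

τ_m images sum each pixel's decay over its 3 × 3 neighborhood ("binning 9",
the convention of standard FLIM software), fit, and store τ_m; background
pixels and pixels below the photon minimum are NaN, exported as float TIFF
alongside a total-intensity image.

## CNN architectures and training

Inputs are per-cell stacks (1 channel, x, y, T), normalized by each cell's
maximum count (alternatives: global scale, log1p). Time is treated as a
third spatial-like dimension.

* **FLI-LeNet**: conv3d(6, 3³, same) → maxpool 2³ → conv3d(16, 3³) →
  maxpool 2³ → flatten → dense(64) → softmax. The 6/16 filter widths are
  the classic LeNet choice; for 21 × 21 × 128 input this is 822,235
  parameters (dominated by the flatten→dense stage).
* **FLI-ResNet**: conv3d(8, 3³, stride 2 along T — a ResNet-style strided
  stem) → maxpool 2³ → residual block (two conv3d(8) with identity skip) →
  maxpool 2³ → residual block → global average pool → dense(64) → softmax;
  7,939 parameters. Pooling between the blocks keeps single-CPU training
  in the minutes range at the default problem sizes.

The engine is plain numpy: convolutions run as im2col + BLAS matmul with
the input gradient scattered back by 27 strided slice-adds; max-pool splits
gradients equally across ties; weights are He-initialized from a seeded
generator. Training minimizes softmax cross-entropy with Adam (lr 10⁻³,
β = 0.9/0.999, batch 8), records a per-epoch train/validation trace, and
restores the weights of the best-validation-loss epoch. No early stopping
is applied by default; an optional `stop_below_val_loss` halts training
once the validation loss crosses a goal. Five-fold cross-validation trains
one model per stratified fold (carving 12.5% of the training folds out as
its validation monitor) and reports mean ± SD metrics.

## Evaluation

Confusion matrices use rows = truth, columns = predicted. Binary reports
treat glycolysis as the positive class and compute accuracy, precision
TP/(TP+FP), recall TP/(TP+FN), and AUC by trapezoidal integration of the
ROC built at unique score thresholds; tie handling is equivalent to the
midrank convention, so the AUC equals the normalized Mann–Whitney U
statistic (used as an independent oracle in tests). Multiclass reports use
one-vs-rest per-class precision/recall/F1 with F1 = 2PR/(P+R) and
unweighted (macro) averaging; a class absent from the truth has undefined
recall and is excluded from the macro averages with a warning, and an
unpredicted-but-present class scores precision 0. Both overall accuracy and
macro scores are always reported, since "accuracy" alone is ambiguous for
3-class problems. Phenotype composition of unlabeled populations is
reported as counts and percentages. t-SNE embedding of penultimate-layer
activations (64 features) wraps scikit-learn's implementation with a fixed
seed and perplexity 30 (reduced automatically for small n).

## Benchmark problem sizes

The surrogate benchmarks in `flimclass.benchmarks` use problem sizes chosen
so the whole suite runs on a single CPU in minutes: 100 replicate decays at
10⁵ photons for the α₁-recovery closure (estimator SD ≈ 0.004, so the mean
pins the preset fraction to well within ±0.02), and 600 cells (200 per
class, 21 × 21 × 128 mean-down-sampled input, up to 30 epochs) for the
3-class FLI-ResNet accuracy benchmark. The 2-class training-dynamics
benchmark (FLI-LeNet, 400 cells) runs until its validation loss first drops
below 0.1, up to a 50-epoch cap.

## Numerical and design notes

* Convolution of IRF and decay is exact discrete convolution truncated to
  the window; normalization after truncation keeps photon conservation
  exact (Σ expected = A + b·T).
* `make_irf` degrades gracefully to a delta kernel when the FWHM is far
  below the bin width.
* Counts are uint16 on disk; values above 65535 are refused rather than
  truncated. HDF5 datasets are written without embedded timestamps so
  identical runs produce bit-identical files (pipeline manifests compare
  SHA-256 checksums).
* Peak-frame ties break to the earlier frame; entropy of an all-zero frame
  is 0 by convention.
* The entropy definition (histogram bin count, the k = 2 threshold) and the
  "odd frames" indexing (1-based) are package choices where conventions
  vary between FLIM processing pipelines.

## Known limitations

The CNNs are compact reference implementations, not tuned architectures;
no GPU path, no data augmentation, no hyperparameter search. The
OXPHOS/glutaminolysis separation rests on documented surrogate cues.
Masks are inputs — segmentation is out of scope. SPCImage-style IRF-shift
fitting and phasor analysis are not implemented.
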