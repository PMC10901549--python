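# flimclass

Single-cell metabolic phenotyping from raw NAD(P)H fluorescence-lifetime
decay data.

## The problem

Fluorescence lifetime imaging (FLIM) of the autofluorescent co-enzyme
NAD(P)H is a label-free window onto cellular metabolism. Time-correlated
single-photon counting (TCSPC) records, for every pixel, a histogram of
photon arrival times after pulsed excitation — the temporal point spread
function (TPSF). Free NAD(P)H decays quickly (τ₁ ≈ 300–500 ps); protein-bound
NAD(P)H decays slowly (τ₂ ≈ 1.5–2 ns), so the measured decay is classically
modelled as an IRF-convolved bi-exponential

    I(t) = IRF ⊛ [α₁ e^(−t/τ₁) + (1 − α₁) e^(−t/τ₂)],
    τ_m = α₁τ₁ + (1 − α₁)τ₂,

where α₁, the short-lifetime fraction, rises when cells rely on glycolysis
(α₁ ≈ 0.79) relative to oxidative phosphorylation (OXPHOS) or glutaminolysis
(α₁ ≈ 0.68). Classical analysis fits these parameters pixel by pixel, which
is slow and discards intracellular spatial patterns. `flimclass` instead
trains compact 3D convolutional networks — **FLI-LeNet** (two conv + two
pooling layers) and **FLI-ResNet** (a conv stem plus two residual blocks) —
directly on per-cell X×Y×T photon-count stacks (21 × 21 × 256, or
21 × 21 × 128 after temporal down-sampling) to predict each cell's dominant
metabolic pathway: glycolysis, OXPHOS or glutaminolysis.

Because curated FLIM datasets of metabolically clamped cells are scarce,
the package ships a fully specified synthetic TCSPC generator (Poisson
photon noise, Gaussian IRF, elliptical cells with dim nuclei, class-specific
decay kinetics and cytoplasmic textures) so every stage — preprocessing,
decay fitting, training, evaluation — is testable end to end with known
ground truth. The classical bi-exponential fitter doubles as an oracle that
must recover the generator's parameters.

## Who it is for

Researchers in optical metabolic imaging who want (a) a reproducible
reference pipeline for cell-level TPSF classification, (b) a synthetic FLIM
benchmark with ground truth, or (c) a plain-numpy reference implementation
of 3D CNN training on volumetric decay data.

## Worked example

```python
import numpy as np
import flimclass as fc
from flimclass import preprocess as pp
from flimclass.models import MetabolicClassifier, ModelConfig

axis = fc.TimeAxis()                      # 256 bins over 12.5 ns (~48.8 ps/bin)
irf  = fc.make_irf(fc.DEFAULT_IRF, axis)  # Gaussian IRF, FWHM 250 ps

# 60 labeled synthetic cells (20 per metabolic class)
cells = fc.simulate_cell_dataset(20, axis, irf, rng=11)

# QC-filter, pad/crop to 21x21, down-sample 256 -> 128 frames (mean filter)
cells, qc = pp.entropy_filter(cells, k_sigma=2.0)
cells = pp.standardize_cells(cells)
cells = pp.downsample_cells(cells, pp.DownsampleSpec("mean"))
print(cells[0].counts.shape)              # (21, 21, 128)
print(pp.peak_frame(cells[0]))            # 33: decay peak after down-sampling

# classical fit of one cell's summed decay
decay = cells[0].counts[cells[0].mask_crop].sum(axis=0)
half_axis = fc.TimeAxis(128, 12.5)
fit = fc.BiexponentialDecay(decay, fc.make_irf(fc.DEFAULT_IRF, half_axis),
                            half_axis).fit()
print(round(fit.params.alpha1, 2), round(fit.tau_m_ps))   # 0.74 808
# (this glycolysis-preset cell drew alpha1 below its class mean of 0.79;
#  cell-to-cell jitter is part of the generator)

# train the 3-class residual CNN
bundle = pp.build_dataset(cells, seed=11)     # stratified 70/10/20 + 5 folds
clf = MetabolicClassifier(ModelConfig(architecture="fli_resnet",
                                      input_shape=(21, 21, 128),
                                      epochs=10, seed=11))
result = clf.fit(bundle)
print(result.summary())
proba, labels = clf.predict(bundle.subset("test"))
```

On a full-size run (200 cells per class, 30 epochs) the held-out accuracy
lands in the mid-90s (%); the peak frame of a noiseless default-IRF decay is
64–65 (≈3.17 ns) before and ~31–33 after down-sampling; the fitted α₁ of
glycolysis-preset decays averages 0.79.

The same workflow is scriptable:

```bash
flimclass simulate --n-cells 12 --seed 1 --out field.h5
flimclass preprocess --in field.h5 --out cells.h5 --downsample mean
flimclass fit --in cells.h5 --out fits.csv
flimclass train --in cells.h5 --arch resnet --epochs 30 --preds-out preds.csv
flimclass evaluate --preds preds.csv --out report.json
flimclass run --config pipeline.yaml       # all stages + checksum manifest
```

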