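"""Surrogate benchmarks: generator-fitter closure and CNN classification.

These routines regenerate synthetic data from the class presets and measure
the package end to end — parameter recovery of the bi-exponential fitter
and held-out classification performance of the 3D CNNs — at problem sizes
a single CPU handles in minutes (see docs/methods.md for the choices).
"""

from __future__ import annotations

import numpy as np

from .models import MetabolicClassifier, ModelConfig
from .preprocess import DownsampleSpec, build_dataset, downsample_cells, entropy_filter, standardize_cells
from .simulate import class_presets, simulate_cell_dataset, simulate_decay
from .timebase import DEFAULT_IRF, TimeAxis, make_irf
from .fitting import fit_biexponential

__all__ = [
    "alpha1_recovery",
    "prepare_training_cells",
    "three_class_resnet_accuracy",
    "two_class_lenet_val_loss",
]


def alpha1_recovery(
    phenotype: str,
    n_replicates: int = 100,
    photons: float = 1e5,
    seed: int = 0,
) -> dict:
    """Mean recovered alpha1 over Poisson replicate decays of one preset.

    Each replicate is a single decay with ``photons`` expected photons,
    fitted with the IRF-convolved bi-exponential model.
    """
    axis = TimeAxis()
    irf = make_irf(DEFAULT_IRF, axis)
    preset = class_presets(amplitude=photons)[phenotype]
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_replicates):
        counts = simulate_decay(preset.mean_params, irf, axis, rng=rng)
        fit = fit_biexponential(counts, irf, axis)
        estimates.append(fit.params.alpha1)
    estimates = np.asarray(estimates)
    return {
        "mean_alpha1": float(estimates.mean()),
        "sd_alpha1": float(estimates.std()),
        "true_alpha1": preset.mean_params.alpha1,
        "n": n_replicates,
    }


def prepare_training_cells(
    n_per_class: int,
    phenotypes: tuple[str, ...],
    seed: int,
    downsample: str = "mean",
):
    """Simulate, QC-filter, standardize and down-sample a labeled cell set."""
    axis = TimeAxis()
    irf = make_irf(DEFAULT_IRF, axis)
    cells = simulate_cell_dataset(
        {p: n_per_class for p in phenotypes}, axis, irf, rng=seed,
        phenotypes=phenotypes,
    )
    cells, _ = entropy_filter(cells, k_sigma=2.0)
    cells = standardize_cells(cells)
    if downsample != "none":
        cells = downsample_cells(cells, DownsampleSpec(method=downsample))
    return cells


def three_class_resnet_accuracy(
    n_per_class: int = 200, epochs: int = 30, seed: int = 0
) -> dict:
    """Held-out test accuracy (%) of FLI-ResNet on 3-class synthetic cells.

    Cells are down-sampled to 21 x 21 x 128 (mean filter) and split
    70/10/20 stratified; training uses Adam (lr 1e-3, batch 8) with
    best-validation-loss checkpointing.
    """
    phenotypes = ("glycolysis", "oxphos", "glutaminolysis")
    cells = prepare_training_cells(n_per_class, phenotypes, seed)
    bundle = build_dataset(cells, seed=seed)
    config = ModelConfig(
        architecture="fli_resnet", n_classes=3, input_shape=(21, 21, 128),
        epochs=epochs, seed=seed,
    )
    clf = MetabolicClassifier(config)
    result = clf.fit(bundle)
    test_cells = bundle.subset("test")
    _, labels = clf.predict(test_cells)
    truth = np.array([c.phenotype for c in test_cells])
    return {
        "accuracy_pct": float(100.0 * (labels == truth).mean()),
        "n_cells": len(cells),
        "n_test": len(test_cells),
        "best_val_loss": result.best_val_loss,
    }


def two_class_lenet_val_loss(
    n_per_class: int = 200, max_epochs: int = 50, seed: int = 0
) -> dict:
    """Minimum validation loss of 2-class FLI-LeNet training.

    Training stops as soon as the per-epoch validation loss drops below
    0.1 (or at ``max_epochs``).
    """
    phenotypes = ("glycolysis", "oxphos")
    cells = prepare_training_cells(n_per_class, phenotypes, seed)
    bundle = build_dataset(cells, seed=seed)
    config = ModelConfig(
        architecture="fli_lenet", n_classes=2, input_shape=(21, 21, 128),
        epochs=max_epochs, seed=seed, stop_below_val_loss=0.1,
    )
    clf = MetabolicClassifier(config)
    result = clf.fit(bundle)
    return {
        "min_val_loss": float(result.trace["val_loss"].min()),
        "epochs_run": int(len(result.trace)),
        "n_cells": len(cells),
    }
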