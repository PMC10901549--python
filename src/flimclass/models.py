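"""3D CNN classifiers for per-cell TPSF stacks: FLI-LeNet and FLI-ResNet.

FLI-LeNet is a volumetric LeNet — two convolutional layers, each followed
by 2x2x2 max pooling, then a 64-unit dense layer and a softmax output.
FLI-ResNet is a convolutional stem (stride 2 along the time axis) followed
by two residual blocks (two 3x3x3 convolutions each with an identity
skip), max pooling between them, global average pooling, a 64-unit dense
layer and a softmax output.

Training minimizes softmax cross-entropy with Adam (learning rate 1e-3,
batch size 8), tracks per-epoch train/validation loss and accuracy, and
keeps the weights from the epoch with the lowest validation loss.  Inputs
are per-cell photon-count stacks normalized by each cell's own maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nn import (
    Adam,
    Conv3D,
    Dense,
    Flatten,
    GlobalAvgPool,
    MaxPool3D,
    Network,
    ReLU,
    ResidualBlock,
    softmax,
    softmax_cross_entropy,
)
from .records import CellRecord, DatasetBundle

__all__ = [
    "ModelConfig",
    "MetabolicClassifier",
    "TrainingResult",
    "build_model",
    "cells_to_array",
    "cross_validate",
    "count_parameters",
]

ARCHITECTURES = ("fli_lenet", "fli_resnet")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for a metabolic-class CNN.

    ``input_shape`` is the per-cell stack shape (x, y, T); standardized
    cells are 21 x 21 with T of 256 (original) or 128 (down-sampled).
    """

    architecture: str = "fli_lenet"
    n_classes: int = 3
    input_shape: tuple[int, int, int] = (21, 21, 128)
    conv_filters: tuple[int, ...] = ()
    penultimate_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 50
    seed: int = 0
    normalization: str = "max"  # {max, global, log1p}
    stop_below_val_loss: float | None = None

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"architecture must be one of {ARCHITECTURES}, got "
                f"{self.architecture!r}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.conv_filters:
            default = (6, 16) if self.architecture == "fli_lenet" else (8,)
            object.__setattr__(self, "conv_filters", default)

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def build_network(config: ModelConfig) -> Network:
    """Construct the layer stack with seed-deterministic initial weights."""
    rng = np.random.default_rng(config.seed)
    x, y, t = config.input_shape
    if config.architecture == "fli_lenet":
        f1, f2 = config.conv_filters
        shape = (x, y, t)
        layers = [Conv3D(1, f1, rng), ReLU(), MaxPool3D()]
        shape = tuple(s // 2 for s in shape)
        layers += [Conv3D(f1, f2, rng), ReLU(), MaxPool3D()]
        shape = tuple(s // 2 for s in shape)
        if min(shape) < 1:
            raise ValueError(
                f"input shape {config.input_shape} too small for two poolings"
            )
        flat = f2 * shape[0] * shape[1] * shape[2]
        layers += [
            Flatten(),
            Dense(flat, config.penultimate_units, rng),
            ReLU(),
            Dense(config.penultimate_units, config.n_classes, rng),
        ]
    else:
        (f1,) = config.conv_filters
        stem = Conv3D(1, f1, rng, stride=(1, 1, 2))
        shape = stem.out_shape((x, y, t))
        shape = tuple(s // 2 for s in shape)  # first pool
        shape2 = tuple(s // 2 for s in shape)  # second pool
        if min(shape2) < 1:
            raise ValueError(
                f"input shape {config.input_shape} too small for the "
                "fli_resnet pooling schedule"
            )
        layers = [
            stem,
            ReLU(),
            MaxPool3D(),
            ResidualBlock(f1, rng),
            MaxPool3D(),
            ResidualBlock(f1, rng),
            GlobalAvgPool(),
            Dense(f1, config.penultimate_units, rng),
            ReLU(),
            Dense(config.penultimate_units, config.n_classes, rng),
        ]
    return Network(layers)


def count_parameters(model: "MetabolicClassifier | Network") -> int:
    """Total trainable scalar parameters."""
    net = model.network if isinstance(model, MetabolicClassifier) else model
    return net.n_parameters()


def cells_to_array(
    cells: list[CellRecord], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack cells into (N, 1, x, y, T) float32 inputs plus label indices.

    Normalization follows ``config.normalization``: per-cell max (default),
    a single global scale, or log1p.
    """
    if not cells:
        raise ValueError("no cells")
    shapes = {c.counts.shape for c in cells}
    if shapes != {config.input_shape}:
        raise ValueError(
            f"cell shapes {sorted(shapes)} do not match model input shape "
            f"{config.input_shape}"
        )
    X = np.stack([c.counts for c in cells]).astype(np.float32)
    if config.normalization == "max":
        scale = X.reshape(len(cells), -1).max(axis=1)
        scale[scale == 0] = 1.0
        X /= scale[:, None, None, None]
    elif config.normalization == "global":
        X /= max(float(X.max()), 1.0)
    elif config.normalization == "log1p":
        X = np.log1p(X)
        X /= max(float(X.max()), 1.0)
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")
    X = X[:, None]
    if any(c.phenotype is None for c in cells):
        return X, None
    classes = sorted({c.phenotype for c in cells})
    y = np.array([classes.index(c.phenotype) for c in cells])
    return X, y


@dataclass
class TrainingResult:
    """Fit diagnostics: per-epoch trace, best epoch and final weights."""

    trace: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    classes: list[str]
    config: ModelConfig
    n_parameters: int

    def summary(self) -> str:
        last = self.trace.iloc[-1]
        lines = [
            f"{self.config.architecture} ({self.n_parameters:,} parameters, "
            f"{self.config.n_classes} classes)",
            "-" * 56,
            f"epochs run          {len(self.trace):6d}",
            f"best epoch          {self.best_epoch:6d} "
            f"(val loss {self.best_val_loss:.4f})",
            f"final train loss    {last['train_loss']:10.4f}",
            f"final train acc     {last['train_acc']:10.4f}",
            f"final val loss      {last['val_loss']:10.4f}",
            f"final val acc       {last['val_acc']:10.4f}",
        ]
        return "\n".join(lines)


class MetabolicClassifier:
    """A 3D CNN predicting metabolic pathway use from TPSF stacks.

    Statsmodels-style usage::

        clf = MetabolicClassifier(ModelConfig(architecture="fli_resnet"))
        result = clf.fit(bundle)       # TrainingResult with trace/summary()
        proba, labels = clf.predict(test_cells)
    """

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        self.network = build_network(config)
        self.classes: list[str] | None = None

    # -- training ---------------------------------------------------------

    def fit(
        self,
        bundle: DatasetBundle | None = None,
        train_cells: list[CellRecord] | None = None,
        val_cells: list[CellRecord] | None = None,
        verbose: bool = False,
    ) -> TrainingResult:
        """Train on the bundle's train split, monitoring its val split.

        Keeps the weights of the epoch with the lowest validation loss.
        """
        if bundle is not None:
            train_cells = bundle.subset("train")
            val_cells = bundle.subset("val")
        if not train_cells:
            raise ValueError("empty training split")
        if not val_cells:
            raise ValueError("empty validation split")
        classes = sorted(
            {c.phenotype for c in train_cells} | {c.phenotype for c in val_cells}
        )
        if len(classes) != self.config.n_classes:
            raise ValueError(
                f"found {len(classes)} classes {classes}, model expects "
                f"{self.config.n_classes}"
            )
        self.classes = classes
        Xtr, ytr = cells_to_array(train_cells, self.config)
        Xva, yva = cells_to_array(val_cells, self.config)
        ytr = np.array([classes.index(c.phenotype) for c in train_cells])
        yva = np.array([classes.index(c.phenotype) for c in val_cells])

        net = self.network
        opt = Adam(net.params(), net.grads(), lr=self.config.learning_rate)
        rng = np.random.default_rng(self.config.seed + 1)
        bs = self.config.batch_size
        rows = []
        best = (np.inf, 0, net.get_weights())
        for epoch in range(1, self.config.epochs + 1):
            order = rng.permutation(len(Xtr))
            losses, correct = [], 0
            for start in range(0, len(order), bs):
                idx = order[start : start + bs]
                logits = net.forward(Xtr[idx])
                loss, grad = softmax_cross_entropy(logits, ytr[idx])
                net.backward(grad)
                opt.step()
                losses.append(loss * len(idx))
                correct += int((logits.argmax(axis=1) == ytr[idx]).sum())
            train_loss = float(np.sum(losses) / len(order))
            train_acc = correct / len(order)
            val_loss, val_acc = self.evaluate_arrays(Xva, yva)
            rows.append(
                {
                    "epoch": epoch,
                    "train_loss": train_loss,
                    "train_acc": train_acc,
                    "val_loss": val_loss,
                    "val_acc": val_acc,
                }
            )
            if verbose:
                print(
                    f"epoch {epoch:3d}  train {train_loss:.4f}/{train_acc:.3f}"
                    f"  val {val_loss:.4f}/{val_acc:.3f}"
                )
            if val_loss < best[0]:
                best = (val_loss, epoch, net.get_weights())
            goal = self.config.stop_below_val_loss
            if goal is not None and val_loss < goal:
                break
        net.set_weights(best[2])
        return TrainingResult(
            trace=pd.DataFrame(rows),
            best_epoch=best[1],
            best_val_loss=float(best[0]),
            classes=classes,
            config=self.config,
            n_parameters=net.n_parameters(),
        )

    # -- inference --------------------------------------------------------

    def _forward_batched(
        self, X: np.ndarray, upto: int | None = None, batch: int = 32
    ) -> np.ndarray:
        outs = [
            self.network.forward(X[i : i + batch], upto=upto)
            for i in range(0, len(X), batch)
        ]
        return np.concatenate(outs)

    def evaluate_arrays(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        logits = self._forward_batched(X)
        loss, _ = softmax_cross_entropy(logits, y)
        acc = float((logits.argmax(axis=1) == y).mean())
        return loss, acc

    def predict(
        self, cells: list[CellRecord]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Class probabilities (N, K) and argmax phenotype labels."""
        if self.classes is None:
            raise ValueError("model is not fitted")
        X, _ = cells_to_array(cells, self.config)
        proba = softmax(self._forward_batched(X))
        labels = np.array([self.classes[i] for i in proba.argmax(axis=1)])
        return proba, labels

    def extract_activations(
        self, cells: list[CellRecord], layer: str = "penultimate"
    ) -> np.ndarray:
        """Feature matrix from the penultimate dense layer (n_cells x 64)."""
        if layer != "penultimate":
            raise ValueError(f"unknown layer {layer!r}; only 'penultimate'")
        X, _ = cells_to_array(cells, self.config)
        # up to and including the ReLU after the penultimate dense layer
        return self._forward_batched(X, upto=len(self.network.layers) - 1)


def build_model(config: ModelConfig) -> MetabolicClassifier:
    """Construct an untrained classifier from a config."""
    return MetabolicClassifier(config)


def cross_validate(
    bundle: DatasetBundle,
    config: ModelConfig,
    folds: int = 5,
    val_fraction: float = 0.125,
) -> tuple[list, pd.DataFrame]:
    """K-fold cross-validation using the bundle's stratified folds.

    For each fold, a fresh model trains on the other folds (with
    ``val_fraction`` of them carved out, stratified, for checkpoint
    monitoring) and is evaluated on the held-out fold.  Returns per-fold
    metric reports and a mean +/- SD summary table.
    """
    from sklearn.model_selection import train_test_split

    from .evaluate import multiclass_metrics

    reports = []
    rows = []
    for k in range(folds):
        train_cells, held = bundle.fold_split(k)
        if not held:
            raise ValueError(f"fold {k} is empty")
        labels = [c.phenotype for c in train_cells]
        tr, va = train_test_split(
            np.arange(len(train_cells)),
            test_size=val_fraction,
            random_state=config.seed + k,
            stratify=labels,
        )
        clf = MetabolicClassifier(config.with_(seed=config.seed + k))
        try:
            clf.fit(
                train_cells=[train_cells[i] for i in tr],
                val_cells=[train_cells[i] for i in va],
            )
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {k}") from exc
        _, pred = clf.predict(held)
        truth = np.array([c.phenotype for c in held])
        report = multiclass_metrics(truth, pred)
        reports.append(report)
        rows.append(
            {
                "fold": k,
                "accuracy": report.accuracy,
                "macro_precision": report.macro_precision,
                "macro_recall": report.macro_recall,
                "macro_f1": report.macro_f1,
                "n_test": len(held),
            }
        )
    df = pd.DataFrame(rows)
    summary = df.drop(columns=["fold", "n_test"]).agg(["mean", "std"])
    return reports, pd.concat([df.set_index("fold"), summary])
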