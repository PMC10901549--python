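"""Shared per-cell and per-field data containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .timebase import TimeAxis

__all__ = ["CellRecord", "FieldStack", "DatasetBundle", "PHENOTYPES"]

PHENOTYPES = ("glycolysis", "oxphos", "glutaminolysis")


@dataclass
class CellRecord:
    """A single cell's cropped TPSF stack.

    ``counts`` is an (x, y, T) photon-count array; ``mask_crop`` the matching
    boolean footprint.  ``truth`` optionally carries the simulator's
    per-pixel ground-truth decay parameters for oracle tests; ``qc`` carries
    entropy-filter results.
    """

    counts: np.ndarray
    mask_crop: np.ndarray
    time_axis: TimeAxis
    phenotype: str | None = None
    cell_id: int = 0
    source_field: str | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mask_crop = np.asarray(self.mask_crop, dtype=bool)
        if self.counts.ndim != 3:
            raise ValueError(f"counts must be 3-D (x, y, T), got {self.counts.shape}")
        if self.mask_crop.shape != self.counts.shape[:2]:
            raise ValueError("mask_crop shape must match counts spatial shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.mask_crop.any():
            raise ValueError("mask_crop is empty")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[2]

    def with_counts(self, counts: np.ndarray, **kwargs) -> "CellRecord":
        """Copy of this record with replaced counts (and optional fields)."""
        return replace(self, counts=counts, **kwargs)


@dataclass
class FieldStack:
    """A full field of view: X x Y x T photon counts plus a cell label mask.

    ``mask`` uses 0 for background and k for cell k; every nonzero label has
    an entry in ``labels`` (cell id -> phenotype).
    """

    counts: np.ndarray
    mask: np.ndarray
    labels: dict[int, str]
    time_axis: TimeAxis
    rng_seed: int = 0
    truth: dict[int, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mask = np.asarray(self.mask)
        if self.counts.ndim != 3:
            raise ValueError("counts must be 3-D (X, Y, T)")
        if self.mask.shape != self.counts.shape[:2]:
            raise ValueError("mask shape must match counts spatial shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        present = set(np.unique(self.mask)) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"mask labels without phenotype entry: {sorted(missing)}")

    @property
    def cell_ids(self) -> list[int]:
        return sorted(set(np.unique(self.mask)) - {0})


@dataclass
class DatasetBundle:
    """An ordered collection of labeled cells with split/fold assignments.

    ``split`` holds one tag per cell in {train, val, test}; ``fold`` one
    integer in [0, n_folds) for cross-validation.  All cells share one
    time axis.
    """

    cells: list[CellRecord]
    split: np.ndarray
    fold: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.split = np.asarray(self.split)
        self.fold = np.asarray(self.fold)
        n = len(self.cells)
        if len(self.split) != n or len(self.fold) != n:
            raise ValueError("split/fold length must match number of cells")
        bad = set(np.unique(self.split)) - {"train", "val", "test"}
        if bad:
            raise ValueError(f"unknown split tags: {bad}")
        axes = {(c.time_axis.n_bins, c.time_axis.window_ns) for c in self.cells}
        if len(axes) > 1:
            raise ValueError(f"cells mix different time axes: {axes}")

    def __len__(self) -> int:
        return len(self.cells)

    def subset(self, tag: str) -> list[CellRecord]:
        """Cells carrying the given split tag."""
        return [c for c, s in zip(self.cells, self.split) if s == tag]

    def fold_split(self, k: int) -> tuple[list[CellRecord], list[CellRecord]]:
        """(training cells, held-out cells) for fold ``k``."""
        train = [c for c, f in zip(self.cells, self.fold) if f != k]
        held = [c for c, f in zip(self.cells, self.fold) if f == k]
        return train, held
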