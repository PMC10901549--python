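"""Per-cell extraction, QC filtering and standardization of TPSF stacks.

The processing chain mirrors standard practice for cell-level FLIM
classification: crop each cell at the bounding box of its mask, reject
poorly segmented or incomplete cells by an entropy threshold at the peak
frame, zero-pad to 40 x 40, center-crop to 21 x 21, and optionally halve
the time dimension (256 -> 128) with a window-3 mean (MD) or median (MEDD)
filter followed by extraction of the odd frames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d
from sklearn.model_selection import StratifiedKFold

from .records import CellRecord, DatasetBundle, FieldStack

__all__ = [
    "DownsampleSpec",
    "extract_cells",
    "peak_frame",
    "frame_entropy",
    "entropy_filter",
    "standardize_spatial",
    "standardize_cells",
    "downsample_time",
    "downsample_cells",
    "temporal_features",
    "build_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DownsampleSpec:
    """Temporal down-sampling: window filter then odd-frame extraction.

    ``method`` is 'mean' (MD) or 'median' (MEDD); ``window`` the odd filter
    length along T (default 3).  Output length is ceil(T / 2).
    """

    method: str = "mean"
    window: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("mean", "median"):
            raise ValueError(f"method must be 'mean' or 'median', got {self.method!r}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")


def extract_cells(field: FieldStack) -> list[CellRecord]:
    """One cropped :class:`CellRecord` per nonzero mask label.

    Crops are the tight bounding box of the label across all frames;
    pixels belonging to other cells inside the box are zeroed.
    """
    records = []
    for cid in field.cell_ids:
        where = field.mask == cid
        if not where.any():
            logger.warning("label %d has no pixels; skipped", cid)
            continue
        rows = np.any(where, axis=1)
        cols = np.any(where, axis=0)
        r0, r1 = np.where(rows)[0][[0, -1]]
        c0, c1 = np.where(cols)[0][[0, -1]]
        crop_mask = where[r0 : r1 + 1, c0 : c1 + 1]
        crop = field.counts[r0 : r1 + 1, c0 : c1 + 1] * crop_mask[:, :, None]
        records.append(
            CellRecord(
                counts=crop,
                mask_crop=crop_mask,
                time_axis=field.time_axis,
                phenotype=field.labels.get(cid),
                cell_id=cid,
                source_field=f"seed{field.rng_seed}",
            )
        )
    return records


def peak_frame(cell: CellRecord) -> int:
    """1-based index of the frame with the maximum summed photon count.

    Ties break toward the earlier frame.  For the default axis and IRF,
    noiseless simulated cells peak at frame 64 or 65 (~3.17 ns).
    """
    totals = cell.counts.sum(axis=(0, 1))
    if totals.sum() == 0:
        raise ValueError("cell has no photons; peak frame undefined")
    return int(np.argmax(totals)) + 1


def frame_entropy(frame: np.ndarray, n_levels: int = 256) -> float:
    """Shannon entropy (bits) of the gray-level histogram of a 2-D frame.

    The histogram uses ``n_levels`` equal-width bins over [0, frame max].
    An all-zero frame has entropy 0 by convention.
    """
    frame = np.asarray(frame)
    if np.any(frame < 0):
        raise ValueError("frame must be non-negative")
    vmax = float(frame.max())
    if vmax == 0:
        return 0.0
    hist, _ = np.histogram(frame, bins=n_levels, range=(0.0, vmax))
    p = hist[hist > 0] / frame.size
    return float(-(p * np.log2(p)).sum())


def entropy_filter(
    cells: list[CellRecord], k_sigma: float = 2.0
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Reject cells whose peak-frame entropy is an outlier.

    Entropies of all cells' peak frames are summarized by a Gaussian
    approximation (mean mu, SD sigma); cells outside
    [mu - k_sigma * sigma, mu + k_sigma * sigma] are removed.  Returns the
    retained cells and a QC table (cell_id, entropy, retained).
    """
    if len(cells) < 2:
        raise ValueError("entropy filtering needs at least 2 cells")
    entropies = np.array(
        [frame_entropy(c.counts[:, :, peak_frame(c) - 1]) for c in cells]
    )
    mu, sigma = float(entropies.mean()), float(entropies.std())
    if sigma == 0:
        logger.warning("entropy SD is 0; retaining all %d cells", len(cells))
        keep = np.ones(len(cells), dtype=bool)
    else:
        lo, hi = mu - k_sigma * sigma, mu + k_sigma * sigma
        keep = (entropies >= lo) & (entropies <= hi)
    qc = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "entropy": entropies,
            "retained": keep,
        }
    )
    retained = []
    for cell, e, k in zip(cells, entropies, keep):
        cell.qc.update(entropy=float(e), retained=bool(k))
        if k:
            retained.append(cell)
    return retained, qc


def standardize_spatial(
    cell: CellRecord, pad_to: int = 40, crop_to: int = 21
) -> CellRecord:
    """Zero-pad a crop to ``pad_to`` square, then center-crop to ``crop_to``.

    Padding is symmetric with the extra pixel on the bottom/right when the
    deficit is odd; T is unchanged.  Cells larger than ``pad_to`` in either
    dimension raise (use :func:`standardize_cells` to skip-and-log).
    """
    nx, ny, _ = cell.counts.shape
    if nx > pad_to or ny > pad_to:
        raise ValueError(
            f"cell {cell.cell_id} ({nx} x {ny}) exceeds pad size {pad_to}"
        )

    def pads(n: int) -> tuple[int, int]:
        deficit = pad_to - n
        return deficit // 2, deficit - deficit // 2

    px, py = pads(nx), pads(ny)
    counts = np.pad(cell.counts, (px, py, (0, 0)))
    mask = np.pad(cell.mask_crop, (px, py))
    start = (pad_to - crop_to) // 2
    sl = slice(start, start + crop_to)
    return cell.with_counts(counts[sl, sl], mask_crop=mask[sl, sl])


def standardize_cells(
    cells: list[CellRecord], pad_to: int = 40, crop_to: int = 21
) -> list[CellRecord]:
    """Standardize a batch, excluding (with a log entry) oversized cells."""
    out = []
    for cell in cells:
        try:
            out.append(standardize_spatial(cell, pad_to, crop_to))
        except ValueError as exc:
            logger.warning("excluding cell: %s", exc)
    return out


def downsample_time(stack: np.ndarray, spec: DownsampleSpec) -> np.ndarray:
    """Window filter along T (edge replication), then keep 1-based odd frames.

    Output length is ceil(T / 2); values are rounded back to integers to
    preserve photon-count semantics.  For the default axis this takes
    21 x 21 x 256 stacks to 21 x 21 x 128 and moves a frame-64/65 peak to
    around frame 31.
    """
    stack = np.asarray(stack)
    T = stack.shape[-1]
    if T < spec.window:
        raise ValueError(f"T={T} shorter than filter window {spec.window}")
    if spec.method == "mean":
        filtered = uniform_filter1d(
            stack.astype(float), size=spec.window, axis=-1, mode="nearest"
        )
    else:
        size = (1,) * (stack.ndim - 1) + (spec.window,)
        filtered = median_filter(stack, size=size, mode="nearest")
    down = np.clip(filtered[..., ::2], 0, None)  # guard float round-off
    if np.issubdtype(stack.dtype, np.integer):
        return np.rint(down).astype(stack.dtype)
    return down


def downsample_cells(
    cells: list[CellRecord], spec: DownsampleSpec
) -> list[CellRecord]:
    """Apply :func:`downsample_time` to every cell, halving the time axis."""
    out = []
    for cell in cells:
        axis = cell.time_axis
        new_axis = type(axis)(
            n_bins=math.ceil(axis.n_bins / 2), window_ns=axis.window_ns
        )
        out.append(
            cell.with_counts(
                downsample_time(cell.counts, spec), time_axis=new_axis
            )
        )
    return out


def temporal_features(cell: CellRecord) -> np.ndarray:
    """Mean photon count over masked pixels at each frame (length T)."""
    if not cell.mask_crop.any():
        raise ValueError("empty mask")
    return cell.counts[cell.mask_crop].mean(axis=0)


def build_dataset(
    cells: list[CellRecord],
    split: tuple[float, float, float] = (0.7, 0.1, 0.2),
    folds: int = 5,
    seed: int = 0,
) -> DatasetBundle:
    """Stratified train/val/test tags plus stratified k-fold assignment.

    Splits are random at fixed seed, stratified by phenotype; folds are
    disjoint, exhaustive and stratified.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    labels = [c.phenotype for c in cells]
    if any(lbl is None for lbl in labels):
        raise ValueError("every cell must be labeled to build a dataset")
    counts = pd.Series(labels).value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"every class needs >= {folds} cells for {folds}-fold CV; got "
            f"{counts.to_dict()}"
        )
    labels = np.asarray(labels)
    idx = np.arange(len(cells))
    _, val_frac, test_frac = split
    n = len(cells)
    quotas = {"test": round(n * test_frac), "val": round(n * val_frac)}
    rng = np.random.default_rng(seed)
    by_class = {
        c: rng.permutation(idx[labels == c]) for c in sorted(set(labels))
    }
    tags = np.full(len(cells), "train", dtype=object)
    for tag in ("test", "val"):
        # largest-remainder apportionment keeps the global tag count exact
        # while staying proportional within each class
        sizes = {c: len(v) for c, v in by_class.items()}
        total = sum(sizes.values())
        raw = {c: quotas[tag] * sizes[c] / total for c in sizes}
        take = {c: int(raw[c]) for c in sizes}
        shortfall = quotas[tag] - sum(take.values())
        for c in sorted(sizes, key=lambda c: raw[c] - take[c], reverse=True):
            if shortfall <= 0:
                break
            take[c] += 1
            shortfall -= 1
        for c, k in take.items():
            chosen, by_class[c] = by_class[c][:k], by_class[c][k:]
            tags[chosen] = tag

    fold = np.empty(len(cells), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (_, held) in enumerate(skf.split(idx, labels)):
        fold[held] = k

    return DatasetBundle(
        cells=list(cells),
        split=tags.astype(str),
        fold=fold,
        provenance={"seed": seed, "split": list(split), "folds": folds},
    )
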