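"""Reading and writing TPSF stacks, masks and per-cell datasets.

Primary container is HDF5:

* field files — ``/tpsf`` (uint16, X x Y x T), ``/mask`` (uint16, X x Y),
  ``/cell_ids`` + ``/phenotypes`` label table, attributes ``n_bins``,
  ``window_ns``, ``seed``;
* dataset files — one group per cell holding the cropped stack, mask,
  phenotype, split tag and fold index, plus shared time-axis attributes.

Multi-frame TIFF import/export (one page per time bin) is provided for
interoperability, with a JSON sidecar for the time-axis metadata.
Counts above the uint16 range are refused rather than silently truncated.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .records import CellRecord, DatasetBundle, FieldStack
from .timebase import TimeAxis

__all__ = [
    "FormatError",
    "write_field",
    "read_field",
    "write_dataset",
    "read_dataset",
    "export_tiff",
    "import_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
]


class FormatError(ValueError):
    """A container file is missing a required dataset or attribute."""


def _as_uint16(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative counts")
    if np.any(arr > np.iinfo(np.uint16).max):
        raise ValueError(
            f"{name} contains counts > 65535; refusing to truncate to uint16"
        )
    return arr.astype(np.uint16)


def write_field(path: str | Path, fs: FieldStack) -> Path:
    """Write a :class:`FieldStack` to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("tpsf", data=_as_uint16(fs.counts, "tpsf"), compression="gzip", track_times=False)
        f.create_dataset("mask", data=_as_uint16(fs.mask, "mask"), compression="gzip", track_times=False)
        ids = sorted(fs.labels)
        f.create_dataset("cell_ids", data=np.asarray(ids, dtype=np.uint16), track_times=False)
        f.create_dataset(
            "phenotypes",
            data=np.asarray([fs.labels[i] for i in ids], dtype="S24"),
            track_times=False,
        )
        f.attrs["n_bins"] = fs.time_axis.n_bins
        f.attrs["window_ns"] = fs.time_axis.window_ns
        f.attrs["seed"] = fs.rng_seed
    return path


def _require(f: h5py.File, member: str):
    if member not in f:
        raise FormatError(f"missing dataset {member!r} in {f.filename}")
    return f[member]


def _require_attr(f: h5py.File, name: str):
    if name not in f.attrs:
        raise FormatError(f"missing attribute {name!r} in {f.filename}")
    return f.attrs[name]


def read_field(path: str | Path) -> FieldStack:
    """Read a :class:`FieldStack` written by :func:`write_field`."""
    with h5py.File(path, "r") as f:
        counts = _require(f, "tpsf")[()]
        mask = _require(f, "mask")[()]
        ids = _require(f, "cell_ids")[()]
        phen = [p.decode() for p in _require(f, "phenotypes")[()]]
        axis = TimeAxis(
            n_bins=int(_require_attr(f, "n_bins")),
            window_ns=float(_require_attr(f, "window_ns")),
        )
        seed = int(_require_attr(f, "seed"))
    return FieldStack(
        counts=counts, mask=mask,
        labels={int(i): p for i, p in zip(ids, phen)},
        time_axis=axis, rng_seed=seed,
    )


def write_dataset(path: str | Path, bundle: DatasetBundle) -> Path:
    """Write a :class:`DatasetBundle` of cropped cells to HDF5."""
    path = Path(path)
    ids = [c.cell_id for c in bundle.cells]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated cell ids in bundle")
    axis = bundle.cells[0].time_axis if bundle.cells else TimeAxis()
    with h5py.File(path, "w") as f:
        f.attrs["n_bins"] = axis.n_bins
        f.attrs["window_ns"] = axis.window_ns
        f.attrs["provenance"] = json.dumps(bundle.provenance)
        for cell, split, fold in zip(bundle.cells, bundle.split, bundle.fold):
            g = f.create_group(f"cells/{cell.cell_id:06d}")
            g.create_dataset(
                "counts", data=_as_uint16(cell.counts, f"cell {cell.cell_id}"),
                compression="gzip", track_times=False,
            )
            g.create_dataset("mask", data=cell.mask_crop.astype(np.uint8), track_times=False)
            g.attrs["cell_id"] = cell.cell_id
            g.attrs["phenotype"] = cell.phenotype or ""
            g.attrs["split"] = str(split)
            g.attrs["fold"] = int(fold)
            g.attrs["source_field"] = cell.source_field or ""
            if cell.qc:
                g.attrs["entropy"] = float(cell.qc.get("entropy", np.nan))
    return path


def read_dataset(path: str | Path) -> DatasetBundle:
    """Read a :class:`DatasetBundle` written by :func:`write_dataset`."""
    cells, split, fold = [], [], []
    with h5py.File(path, "r") as f:
        axis = TimeAxis(
            n_bins=int(_require_attr(f, "n_bins")),
            window_ns=float(_require_attr(f, "window_ns")),
        )
        provenance = json.loads(f.attrs.get("provenance", "{}"))
        group = _require(f, "cells")
        for key in sorted(group):
            g = group[key]
            qc = {}
            if "entropy" in g.attrs:
                qc["entropy"] = float(g.attrs["entropy"])
            cells.append(
                CellRecord(
                    counts=g["counts"][()],
                    mask_crop=g["mask"][()].astype(bool),
                    time_axis=axis,
                    phenotype=str(g.attrs["phenotype"]) or None,
                    cell_id=int(g.attrs["cell_id"]),
                    source_field=str(g.attrs["source_field"]) or None,
                    qc=qc,
                )
            )
            split.append(str(g.attrs["split"]))
            fold.append(int(g.attrs["fold"]))
    return DatasetBundle(
        cells=cells, split=np.asarray(split), fold=np.asarray(fold),
        provenance=provenance,
    )


def export_tiff(path: str | Path, fs: FieldStack) -> Path:
    """Export the TPSF stack as a multi-frame TIFF (page k = frame k) plus a
    JSON metadata sidecar."""
    path = Path(path)
    pages = _as_uint16(fs.counts, "tpsf").transpose(2, 0, 1)
    tifffile.imwrite(path, pages)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "n_bins": fs.time_axis.n_bins,
                "window_ns": fs.time_axis.window_ns,
                "seed": fs.rng_seed,
                "labels": {str(k): v for k, v in fs.labels.items()},
            }
        )
    )
    return path


def import_tiff(
    path: str | Path, mask: np.ndarray, labels: dict[int, str] | None = None
) -> FieldStack:
    """Import a multi-frame TIFF stack written by :func:`export_tiff`.

    The mask is supplied separately (see :func:`read_mask_tiff`); metadata
    comes from the JSON sidecar.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if labels is None:
        labels = {int(k): v for k, v in meta.get("labels", {}).items()}
    return FieldStack(
        counts=pages.transpose(1, 2, 0),
        mask=mask,
        labels=labels,
        time_axis=TimeAxis(int(meta["n_bins"]), float(meta["window_ns"])),
        rng_seed=int(meta.get("seed", 0)),
    )


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> Path:
    """Write a 16-bit label mask as single-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, _as_uint16(mask, "mask"))
    return path


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
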