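"""NIfTI-1 / CSV input-output for volumes, series, masks, ROIs and cohorts."""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dwi_models import DwiSeries
from .ff_quant import RectRoi

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_series",
    "load_series",
    "save_bvals",
    "load_bvals",
    "load_roi_table",
    "save_roi_table",
    "save_cohort",
    "load_cohort",
]


def _affine(voxel_spacing) -> np.ndarray:
    aff = np.diag(list(voxel_spacing) + [1.0])
    return aff


def save_volume(volume: np.ndarray, path, voxel_spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                          _affine(voxel_spacing))
    nib.save(img, os.fspath(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(os.fspath(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), spacing


def save_mask(mask: np.ndarray, path, voxel_spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                          _affine(voxel_spacing))
    nib.save(img, os.fspath(path))


def load_mask(path) -> np.ndarray:
    data, _ = load_volume(path)
    return data > 0.5


def save_bvals(b_values, path) -> None:
    pd.DataFrame({"b_value": np.asarray(b_values, dtype=float)}).to_csv(
        path, index=False)


def load_bvals(path) -> np.ndarray:
    return pd.read_csv(path)["b_value"].to_numpy(dtype=float)


def save_series(series: DwiSeries, path, bvals_path=None) -> None:
    """Write a DWI series as one 4D NIfTI (b along the last axis), with an
    optional b-value sidecar CSV."""
    data = np.moveaxis(series.volumes, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(series.voxel_spacing))
    nib.save(img, os.fspath(path))
    if bvals_path is not None:
        save_bvals(series.b_values, bvals_path)


def load_series(path, bvals) -> DwiSeries:
    """Read a DWI series from a 4D NIfTI (or a list of 3D per-b files)
    plus b-values (array or sidecar CSV path)."""
    if isinstance(bvals, (str, Path)):
        bvals = load_bvals(bvals)
    bvals = np.asarray(bvals, dtype=float)
    if isinstance(path, (list, tuple)):
        vols, spacing = [], None
        for p in path:
            v, spacing = load_volume(p)
            vols.append(v)
        volumes = np.stack(vols)
    else:
        img = nib.load(os.fspath(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 4:
            raise ValueError("expected a 4D NIfTI for a DWI series")
        volumes = np.moveaxis(data, -1, 0)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if volumes.shape[0] != bvals.size:
        raise ValueError("number of volumes does not match number of b-values")
    return DwiSeries(b_values=bvals, volumes=volumes, voxel_spacing=spacing)


_ROI_COLUMNS = ["name", "plane", "slice_index", "corner0", "corner1",
                "extent0", "extent1"]


def save_roi_table(rois: dict[str, RectRoi], path) -> None:
    rows = [
        {"name": name, "plane": r.plane, "slice_index": r.slice_index,
         "corner0": r.corner[0], "corner1": r.corner[1],
         "extent0": r.extent[0], "extent1": r.extent[1]}
        for name, r in rois.items()
    ]
    pd.DataFrame(rows, columns=_ROI_COLUMNS).to_csv(path, index=False)


def load_roi_table(path) -> dict[str, RectRoi]:
    df = pd.read_csv(path)
    missing = set(_ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    return {
        row["name"]: RectRoi(
            plane=row["plane"],
            slice_index=int(row["slice_index"]),
            corner=(int(row["corner0"]), int(row["corner1"])),
            extent=(int(row["extent0"]), int(row["extent1"])),
        )
        for _, row in df.iterrows()
    }


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise ValueError("cohort CSV must have a 'group' column")
    return df
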