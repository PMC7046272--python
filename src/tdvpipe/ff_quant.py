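"""Dixon fat-fraction maps and rectangular-ROI marrow statistics.

The fat fraction is the standard Dixon fat-signal fraction
``FF = 100 * fat / (fat + water)`` computed voxelwise from vendor-style
water-only and fat-only volumes (no raw multi-echo reconstruction here).
ROIs are small declared rectangles on a coronal or sagittal slice —
mirroring manual placement over L1–L3 vertebral marrow — with optional
area validation against protocol bounds (warn, don't fail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dwi_models import DwiSeries

__all__ = [
    "FfMap",
    "RectRoi",
    "compute_ff_map",
    "roi_mean",
    "roi_mean_signal",
    "DIXON_ROI_AREA_BOUNDS_MM2",
    "DWI_ROI_AREA_BOUNDS_MM2",
]

#: protocol bounds for marrow ROI areas (mm^2)
DIXON_ROI_AREA_BOUNDS_MM2 = (282.0, 525.0)
DWI_ROI_AREA_BOUNDS_MM2 = (245.0, 480.0)

_PLANE_AXIS = {"sagittal": 0, "coronal": 1}


@dataclass
class FfMap:
    """Per-voxel fat fraction in percent; NaN where water + fat = 0."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    method: str = "fat/(fat+water)"

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class RectRoi:
    """Axis-aligned rectangle on one coronal or sagittal slice.

    ``corner`` and ``extent`` index the two in-plane axes of the volume
    (for a coronal ROI the in-plane axes are 0 and 2; for sagittal, 1 and
    2), in voxels.
    """

    plane: str
    slice_index: int
    corner: tuple[int, int]
    extent: tuple[int, int]

    def __post_init__(self) -> None:
        if self.plane not in _PLANE_AXIS:
            raise ValueError("plane must be 'coronal' or 'sagittal'")
        if any(e <= 0 for e in self.extent):
            raise ValueError("ROI extent must be positive")
        if any(c < 0 for c in self.corner) or self.slice_index < 0:
            raise ValueError("ROI indices must be non-negative")

    @property
    def axis(self) -> int:
        return _PLANE_AXIS[self.plane]

    def _inplane_axes(self) -> tuple[int, int]:
        return tuple(a for a in range(3) if a != self.axis)  # type: ignore

    def area_mm2(self, voxel_spacing) -> float:
        a0, a1 = self._inplane_axes()
        return (self.extent[0] * voxel_spacing[a0]
                * self.extent[1] * voxel_spacing[a1])

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """2D patch of `volume` covered by the ROI; errors if out of grid."""
        volume = np.asarray(volume)
        if volume.ndim != 3:
            raise ValueError("RectRoi applies to 3D volumes")
        a0, a1 = self._inplane_axes()
        if self.slice_index >= volume.shape[self.axis]:
            raise ValueError("ROI slice index outside grid")
        if (self.corner[0] + self.extent[0] > volume.shape[a0]
                or self.corner[1] + self.extent[1] > volume.shape[a1]):
            raise ValueError("ROI extends outside grid")
        sl = [slice(None)] * 3
        sl[self.axis] = self.slice_index
        sl[a0] = slice(self.corner[0], self.corner[0] + self.extent[0])
        sl[a1] = slice(self.corner[1], self.corner[1] + self.extent[1])
        return volume[tuple(sl)]


def compute_ff_map(
    water_volume: np.ndarray,
    fat_volume: np.ndarray,
    voxel_spacing=(1.0, 1.0, 1.0),
) -> FfMap:
    """FF = 100 * fat / (fat + water); zero-denominator voxels are NaN."""
    water = np.asarray(water_volume, dtype=float)
    fat = np.asarray(fat_volume, dtype=float)
    if water.shape != fat.shape:
        raise ValueError(
            f"grid mismatch: water {water.shape} vs fat {fat.shape}")
    if np.any(water < 0) or np.any(fat < 0):
        raise ValueError("water/fat signals must be non-negative")
    denom = water + fat
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(denom > 0, 100.0 * fat / np.where(denom > 0, denom, 1.0),
                      np.nan)
    return FfMap(values=ff, voxel_spacing=tuple(float(s) for s in voxel_spacing))


def _check_area(roi: RectRoi, spacing, area_bounds) -> None:
    if area_bounds is None:
        return
    area = roi.area_mm2(spacing)
    lo, hi = area_bounds
    if not lo <= area <= hi:
        warnings.warn(
            f"ROI area {area:.0f} mm^2 outside protocol bounds "
            f"[{lo:.0f}, {hi:.0f}] mm^2",
            UserWarning,
            stacklevel=3,
        )


def roi_mean(
    ff_map: FfMap,
    roi: RectRoi,
    area_bounds: tuple[float, float] | None = None,
) -> float:
    """Arithmetic mean FF over in-ROI, defined voxels (percent).

    Warns (does not fail) when the ROI area falls outside `area_bounds`;
    errors when every in-ROI voxel is undefined.
    """
    _check_area(roi, ff_map.voxel_spacing, area_bounds)
    patch = roi.extract(ff_map.values)
    vals = patch[np.isfinite(patch)]
    if vals.size == 0:
        raise ValueError("ROI contains no defined fat-fraction voxels")
    return float(vals.mean())


def roi_mean_signal(
    series: DwiSeries,
    roi: RectRoi,
    area_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Mean DWI signal inside the ROI at every b-value.

    Returns a DataFrame with columns ``b_value`` and ``mean_signal``,
    ready to feed :func:`tdvpipe.dwi_models.fit_ivim`.
    """
    _check_area(roi, series.voxel_spacing, area_bounds)
    means = [float(roi.extract(vol).mean()) for vol in series.volumes]
    return pd.DataFrame({"b_value": series.b_values, "mean_signal": means})
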