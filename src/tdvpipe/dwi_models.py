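"""Diffusion signal models.

This module holds the quantitative DWI primitives used throughout the
pipeline:

* voxelwise monoexponential ADC mapping, ``S(b) = S0 * exp(-b * ADC)``,
  fitted log-linearly so that the two-point case reduces exactly to
  ``ADC = ln(S(b0)/S(b1)) / (b1 - b0)``;
* *computed DWI*: extrapolation of the fitted model to an unacquired
  b-value (clinically, b = 999 s/mm^2 synthesized from a b = 0/1000
  acquisition);
* maximum intensity projection (MIP);
* IVIM biexponential fitting of ROI-mean signal,
  ``S(b)/S(0) = f * exp(-b * D*) + (1 - f) * exp(-b * D)``,
  by the standard segmented strategy (tissue diffusion D from the high-b
  monoexponential tail, then a bounded nonlinear fit of the perfusion
  fraction f and pseudodiffusion coefficient D*).

All diffusion coefficients are stored in mm^2/s (so a typical marrow ADC
is ~1.0e-3); b-values in s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DwiSeries",
    "AdcMap",
    "IvimFit",
    "fit_adc",
    "computed_dwi",
    "mip_project",
    "fit_ivim",
    "ivim_signal",
]

#: default b-value above which the signal is treated as perfusion-free
#: when estimating tissue diffusion in the segmented IVIM fit
IVIM_SPLIT_B = 200.0


def ivim_signal(b, s0, f, dstar, d):
    """Biexponential IVIM signal ``s0*(f*exp(-b*D*) + (1-f)*exp(-b*D))``."""
    b = np.asarray(b, dtype=float)
    return s0 * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * d))


@dataclass
class DwiSeries:
    """A set of co-registered 3D volumes indexed by b-value.

    Parameters
    ----------
    b_values : array of float, shape (nb,)
        Diffusion weightings in s/mm^2; at least two distinct, all >= 0.
    volumes : array, shape (nb, nx, ny, nz)
        One signal volume per b-value, common grid.
    voxel_spacing : 3-tuple of float
        Voxel edge lengths in mm, all > 0.
    """

    b_values: np.ndarray
    volumes: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if self.b_values.ndim != 1:
            raise ValueError("b_values must be a 1D sequence")
        if np.unique(self.b_values).size < 2:
            raise ValueError("a DWI series needs at least two distinct b-values")
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be >= 0")
        if self.volumes.ndim != 4 or self.volumes.shape[0] != self.b_values.size:
            raise ValueError(
                "volumes must have shape (n_b, nx, ny, nz) matching b_values"
            )
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.voxel_spacing)) / 1000.0

    def volume_at(self, b: float) -> np.ndarray:
        """Return the acquired volume at b-value `b` (exact match)."""
        idx = np.flatnonzero(np.isclose(self.b_values, b))
        if idx.size == 0:
            raise KeyError(f"b={b} not in series (have {self.b_values.tolist()})")
        return self.volumes[idx[0]]


@dataclass
class AdcMap:
    """Voxelwise ADC map plus the fitted b=0 signal.

    ``values`` is NaN (and ``valid`` False) where any input signal was
    non-positive; such voxels are excluded from every downstream mask.
    """

    values: np.ndarray  # mm^2/s, NaN where invalid
    s0_map: np.ndarray
    valid: np.ndarray  # bool
    voxel_spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def _select_b(series: DwiSeries, b_subset: Sequence[float] | None) -> np.ndarray:
    if b_subset is None:
        return np.arange(series.b_values.size)
    idx = []
    for b in b_subset:
        hit = np.flatnonzero(np.isclose(series.b_values, b))
        if hit.size == 0:
            raise KeyError(f"b={b} not acquired in this series")
        idx.append(hit[0])
    return np.asarray(idx)


def fit_adc(series: DwiSeries, b_subset: Sequence[float] | None = None) -> AdcMap:
    """Voxelwise log-linear least-squares fit of ``ln S = ln S0 - b*ADC``.

    With exactly two b-values this reduces to the closed form
    ``ADC = ln(S(b0)/S(b1)) / (b1 - b0)``.  Voxels with any non-positive
    signal among the fitted b-values are flagged invalid.  Negative fitted
    slopes (signal increasing with b, possible under noise) are clamped to
    ADC = 0 so the map is non-negative wherever it is defined.
    """
    idx = _select_b(series, b_subset)
    if idx.size < 2:
        raise ValueError("fit_adc needs at least two b-values")
    b = series.b_values[idx]
    sig = series.volumes[idx]  # (k, nx, ny, nz)
    valid = np.all(sig > 0, axis=0)

    k = b.size
    bc = b - b.mean()
    denom = float(np.sum(bc * bc))
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(sig > 0, np.log(np.where(sig > 0, sig, 1.0)), 0.0)
    # slope = sum((b - bbar) * lnS) / sum((b - bbar)^2); ADC = -slope
    slope = np.tensordot(bc, logs, axes=(0, 0)) / denom
    intercept = logs.sum(axis=0) / k - slope * b.mean()
    adc = np.where(valid, np.maximum(-slope, 0.0), np.nan)
    s0 = np.where(valid, np.exp(intercept), np.nan)
    return AdcMap(values=adc, s0_map=s0, valid=valid,
                  voxel_spacing=series.voxel_spacing)


def computed_dwi(
    series: DwiSeries,
    target_b: float,
    b_subset: Sequence[float] | None = None,
) -> np.ndarray:
    """Synthesize a DWI volume at an arbitrary b-value.

    Per voxel, ``S0_fit * exp(-target_b * ADC_fit)`` from the
    monoexponential fit of the acquired b-values; invalid-ADC voxels are
    set to 0.
    """
    if target_b < 0:
        raise ValueError("target_b must be >= 0")
    adc = fit_adc(series, b_subset=b_subset)
    out = adc.s0_map * np.exp(-target_b * adc.values)
    return np.where(adc.valid, out, 0.0)


def mip_project(volume: np.ndarray, axis: int = 1) -> np.ndarray:
    """Maximum intensity projection of a 3D volume along one axis."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("mip_project expects a 3D volume")
    return volume.max(axis=axis)


@dataclass
class IvimFit:
    """Result of an IVIM biexponential fit.

    f is the (unitless) perfusion fraction, dstar and d the pseudo- and
    tissue diffusion coefficients in mm^2/s; ``rss`` is the residual sum
    of squares of the normalized signal S(b)/S(0).
    """

    f: float
    dstar: float
    d: float
    s0: float
    rss: float
    converged: bool
    n_iter: int = 0

    def predict(self, b) -> np.ndarray:
        return ivim_signal(b, self.s0, self.f, self.dstar, self.d)


def fit_ivim(
    b_values: Sequence[float],
    mean_signals: Sequence[float],
    split_b: float = IVIM_SPLIT_B,
    dstar_max: float = 0.5,
    n_refine: int = 3,
) -> IvimFit:
    """Segmented IVIM fit of ROI-mean signal across b-values.

    Step 1 fits tissue diffusion D (and intercept) monoexponentially on
    b >= `split_b`, where the perfusion compartment has mostly decayed
    away.  Step 2 fixes D and fits (f, D*) by bounded nonlinear least
    squares on the normalized signal, bounds f in [0, 1] and D* in
    [D, dstar_max], initialized at f = 0.1, D* = 10 D (tolerance 1e-10,
    max 500 evaluations).  The two steps are then alternated `n_refine`
    times, subtracting the current perfusion component before re-fitting
    D, which removes the small residual-perfusion bias of the plain
    two-step scheme.  Non-convergence is reported via ``converged``
    rather than an exception.

    Requires at least five b-values including b = 0 and at least two
    b >= 500 s/mm^2, with strictly positive signals.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(mean_signals, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("b_values and mean_signals must be equal-length 1D")
    if b.size < 5:
        raise ValueError("IVIM fitting needs at least five b-values")
    if not np.any(b == 0):
        raise ValueError("IVIM fitting needs a b = 0 measurement")
    if np.sum(b >= 500) < 2:
        raise ValueError("IVIM fitting needs at least two b-values >= 500")
    if np.any(s <= 0):
        raise ValueError("IVIM fitting needs strictly positive signals")

    order = np.argsort(b)
    b, s = b[order], s[order]
    s0 = float(np.mean(s[b == 0]))
    y = s / s0

    hi = b >= split_b
    bh = b[hi]
    bc = bh - bh.mean()
    denom = float(np.sum(bc * bc))

    def fit_tail(y_tail) -> float:
        lh = np.log(np.maximum(y_tail, 1e-12))
        slope = float(np.sum(bc * lh) / denom)
        return max(-slope, 1e-7)

    def fit_perfusion(d, x0):
        def resid(p):
            f, dstar = p
            return f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * d) - y

        return least_squares(
            resid,
            x0,
            bounds=([0.0, d], [1.0, dstar_max]),
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=500,
        )

    # -- step 1: tissue diffusion from the high-b tail
    d = fit_tail(y[hi])
    # -- step 2: perfusion fraction and pseudodiffusion, D fixed
    x0 = np.array([0.1, min(max(10.0 * d, d * (1 + 1e-6)), dstar_max)])
    res = fit_perfusion(d, x0)
    # -- alternate: remove the fitted perfusion from the tail, refit D
    for _ in range(max(0, n_refine)):
        f_cur, dstar_cur = res.x
        corrected = (y[hi] - f_cur * np.exp(-bh * dstar_cur)) / (1.0 - f_cur)
        d = fit_tail(corrected)
        x0 = np.array([f_cur, float(np.clip(dstar_cur, d * (1 + 1e-6),
                                            dstar_max))])
        res = fit_perfusion(d, x0)
    f, dstar = (float(v) for v in res.x)
    rss = float(np.sum(res.fun ** 2))
    return IvimFit(
        f=f,
        dstar=dstar,
        d=float(d),
        s0=s0,
        rss=rss,
        converged=bool(res.success),
        n_iter=int(res.nfev),
    )
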