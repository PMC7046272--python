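"""Semi-automatic tumour-burden segmentation (total diffusion volume).

The chain mirrors the clinical workflow for whole-body DWI in myeloma:

1. synthesize a high-b computed DWI volume (default b = 999 s/mm^2) from
   the acquired series and min–max normalize it to a 0–255 scale;
2. remove background with a fixed intensity threshold (default 97 on the
   normalized scale);
3. binarize the remaining voxels into disease / non-disease with Otsu's
   between-class-variance criterion;
4. subtract a user-supplied exclusion mask (brain, nodes, bowel — the
   manual step of the clinical workflow);
5. keep only voxels whose ADC lies in the disease band
   (adc_lower < ADC <= adc_upper; defaults 0.55e-3 and 2.0e-3 mm^2/s, the
   upper cut suppressing T2 shine-through);
6. report tDV (ml) and ADC histogram features of the final mask.

Thresholds in config files are written in the display unit
(x10^-3 mm^2/s) and converted once at parse time; in code everything is
plain mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dwi_models import AdcMap, DwiSeries, computed_dwi, fit_adc, mip_project

__all__ = [
    "SegmentationConfig",
    "TdvResult",
    "HistogramFeatures",
    "PipelineStageError",
    "normalize_intensity",
    "background_mask",
    "otsu_threshold",
    "apply_exclusions",
    "filter_adc_band",
    "compute_tdv",
    "histogram_features",
    "segment_study",
    "threshold_sweep",
    "DEFAULT_LOWER_THRESHOLDS",
]

#: candidate lower ADC cuts for the threshold sweep (mm^2/s)
DEFAULT_LOWER_THRESHOLDS = (0.45e-3, 0.55e-3, 0.65e-3)


class PipelineStageError(RuntimeError):
    """Raised when a segmentation stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation chain.

    ``background_threshold`` lives on the normalized 0..intensity_scale
    axis; ADC bounds are in mm^2/s.  ``otsu_on_mip`` applies the Otsu
    step to the 2D maximum intensity projection instead of the 3D volume
    (both variants exist in practice; 3D is the default here).
    """

    background_threshold: float = 97.0
    adc_upper: float = 2.0e-3
    adc_lower: float = 0.55e-3
    computed_b: float = 999.0
    otsu_bins: int = 256
    intensity_scale: float = 255.0
    otsu_on_mip: bool = False
    mip_axis: int = 1
    adc_b_subset: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.adc_lower < self.adc_upper:
            raise ValueError("need 0 < adc_lower < adc_upper")
        if not 0 <= self.background_threshold <= self.intensity_scale:
            raise ValueError("background_threshold outside intensity range")
        if self.otsu_bins < 2:
            raise ValueError("otsu_bins must be >= 2")

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        """Build from a config mapping; ADC keys are given in the display
        unit x10^-3 mm^2/s (e.g. ``adc_upper: 2.0``) and converted here."""
        d = dict(d)
        for key in ("adc_upper", "adc_lower"):
            if key in d:
                d[key] = float(d[key]) * 1e-3
        return cls(**d)


@dataclass
class HistogramFeatures:
    """ADC summary statistics of the disease mask.

    Kurtosis is Fisher excess (normal = 0).  ``moments_defined`` is False
    when fewer than 4 voxels are available or the variance is zero, in
    which case skewness/kurtosis are NaN.
    """

    mean: float
    p25: float
    p75: float
    skewness: float
    kurtosis: float
    moments_defined: bool


@dataclass
class TdvResult:
    disease_mask: np.ndarray
    tdv_ml: float
    n_voxels: int
    features: HistogramFeatures
    stage_counts: dict[str, int] = field(default_factory=dict)
    otsu_level: float = float("nan")

    @property
    def mean_adc(self) -> float:
        return self.features.mean


def normalize_intensity(volume: np.ndarray, scale: float = 255.0) -> np.ndarray:
    """Min–max rescale a volume to [0, scale]; constant input maps to 0."""
    volume = np.asarray(volume, dtype=float)
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        return np.zeros_like(volume)
    return (volume - lo) / (hi - lo) * scale


def background_mask(
    computed_volume: np.ndarray,
    threshold: float = 97.0,
    scale: float = 255.0,
) -> np.ndarray:
    """Voxels whose normalized intensity exceeds the background threshold."""
    return normalize_intensity(computed_volume, scale) > threshold


def otsu_threshold(intensities: np.ndarray, bins: int = 256) -> float:
    """Otsu's discriminant threshold.

    Candidate levels are the interior edges of a `bins`-bin uniform grid
    over the data range; the returned level maximizes the between-class
    variance ``w0 * w1 * (mu0 - mu1)^2`` of the two classes (values <=
    level vs > level), with class moments computed from the data values
    themselves.  Ties break toward the lower level.  Constant input has
    no threshold and raises ``ValueError``.
    """
    v = np.asarray(intensities, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("otsu_threshold needs at least two values")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("otsu_threshold undefined for constant input")
    edges = np.linspace(lo, hi, bins + 1)[1:-1]
    order = np.sort(v)
    csum = np.cumsum(order)
    n = order.size
    total = csum[-1]
    k = np.searchsorted(order, edges, side="right")  # values <= edge
    valid = (k > 0) & (k < n)
    k_safe = np.clip(k, 1, n - 1)
    mu0 = csum[k_safe - 1] / k_safe
    mu1 = (total - csum[k_safe - 1]) / (n - k_safe)
    w0 = k_safe / n
    var_b = np.where(valid, w0 * (1.0 - w0) * (mu0 - mu1) ** 2, -np.inf)
    if not np.any(np.isfinite(var_b)):
        raise ValueError("no interior threshold separates the data")
    return float(edges[int(np.argmax(var_b))])  # argmax takes first -> lower


def apply_exclusions(mask: np.ndarray, exclusion_mask: np.ndarray) -> np.ndarray:
    """Set-difference: drop manually/ground-truth flagged non-skeletal voxels."""
    mask = np.asarray(mask, dtype=bool)
    exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
    if mask.shape != exclusion_mask.shape:
        raise ValueError(
            f"grid mismatch: mask {mask.shape} vs exclusion {exclusion_mask.shape}"
        )
    return mask & ~exclusion_mask


def filter_adc_band(
    mask: np.ndarray,
    adc_map: AdcMap | np.ndarray,
    adc_lower: float,
    adc_upper: float,
) -> np.ndarray:
    """Retain voxels with adc_lower < ADC <= adc_upper (strict lower,
    inclusive upper); invalid-ADC voxels are dropped."""
    if adc_lower >= adc_upper:
        raise ValueError("need adc_lower < adc_upper")
    values = adc_map.values if isinstance(adc_map, AdcMap) else np.asarray(adc_map)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("grid mismatch between mask and ADC map")
    with np.errstate(invalid="ignore"):
        band = (values > adc_lower) & (values <= adc_upper)
    return mask & band & np.isfinite(values)


def compute_tdv(mask: np.ndarray, voxel_spacing: Sequence[float]) -> float:
    """Total diffusion volume in millilitres: voxel count x voxel volume."""
    spacing = tuple(float(s) for s in voxel_spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be > 0")
    voxvol_ml = float(np.prod(spacing)) / 1000.0
    return float(np.count_nonzero(mask)) * voxvol_ml


def histogram_features(adc_values: np.ndarray) -> HistogramFeatures:
    """Mean, 25th/75th percentiles (linear interpolation), moment-based
    skewness and Fisher excess kurtosis of in-mask ADC values."""
    v = np.asarray(adc_values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        return HistogramFeatures(*(float("nan"),) * 5, moments_defined=False)
    mean = float(np.mean(v))
    p25 = float(np.percentile(v, 25))
    p75 = float(np.percentile(v, 75))
    # near-constant data (relative std below float precision) has no
    # meaningful shape moments
    if v.size < 4 or np.std(v) <= 1e-9 * max(abs(mean), np.finfo(float).tiny):
        return HistogramFeatures(mean, p25, p75, float("nan"), float("nan"),
                                 moments_defined=False)
    skew = float(sps.skew(v, bias=True))
    kurt = float(sps.kurtosis(v, fisher=True, bias=True))
    return HistogramFeatures(mean, p25, p75, skew, kurt, moments_defined=True)


def _resolve_series(study) -> tuple[DwiSeries, np.ndarray | None]:
    """Accept a DwiSeries or anything exposing .dwi (e.g. PhantomStudy)."""
    if isinstance(study, DwiSeries):
        return study, None
    series = getattr(study, "dwi", None)
    if not isinstance(series, DwiSeries):
        raise TypeError("segment_study expects a DwiSeries or a study with .dwi")
    return series, getattr(study, "truth_exclusion_mask", None)


def segment_study(
    study,
    config: SegmentationConfig | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> TdvResult:
    """Run the full segmentation chain and return the tDV result.

    `study` is a :class:`DwiSeries` or an object with a ``dwi`` attribute
    (a phantom study also supplies its ground-truth exclusion mask when
    none is given explicitly).  The result records per-stage voxel counts
    so runs are auditable.
    """
    config = config or SegmentationConfig()
    series, default_excl = _resolve_series(study)
    if exclusion_mask is None:
        exclusion_mask = default_excl
    counts: dict[str, int] = {}

    try:
        cdwi = computed_dwi(series, config.computed_b,
                            b_subset=config.adc_b_subset)
        adc = fit_adc(series, b_subset=config.adc_b_subset)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage identity
        raise PipelineStageError("computed_dwi", str(exc)) from exc

    norm = normalize_intensity(cdwi, config.intensity_scale)
    bg = norm > config.background_threshold
    counts["background"] = int(bg.sum())
    if counts["background"] == 0:
        raise PipelineStageError("background_mask",
                                 "no voxels above the background threshold")

    try:
        if config.otsu_on_mip:
            mip = mip_project(norm, axis=config.mip_axis)
            bg_mip = mip_project(bg.astype(float), axis=config.mip_axis) > 0
            level = otsu_threshold(mip[bg_mip], bins=config.otsu_bins)
        else:
            level = otsu_threshold(norm[bg], bins=config.otsu_bins)
    except ValueError as exc:
        raise PipelineStageError("otsu_threshold", str(exc)) from exc
    disease = bg & (norm > level)
    counts["otsu"] = int(disease.sum())

    try:
        if exclusion_mask is not None:
            disease = apply_exclusions(disease, exclusion_mask)
    except ValueError as exc:
        raise PipelineStageError("apply_exclusions", str(exc)) from exc
    counts["exclusions"] = int(disease.sum())

    try:
        disease = filter_adc_band(disease, adc, config.adc_lower,
                                  config.adc_upper)
    except ValueError as exc:
        raise PipelineStageError("filter_adc_band", str(exc)) from exc
    counts["adc_band"] = int(disease.sum())

    tdv_ml = compute_tdv(disease, series.voxel_spacing)
    feats = histogram_features(adc.values[disease])
    return TdvResult(
        disease_mask=disease,
        tdv_ml=tdv_ml,
        n_voxels=int(disease.sum()),
        features=feats,
        stage_counts=counts,
        otsu_level=level,
    )


def threshold_sweep(
    studies: Iterable,
    lower_list: Sequence[float] = DEFAULT_LOWER_THRESHOLDS,
    config: SegmentationConfig | None = None,
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """tDV per study per candidate lower ADC threshold.

    Returns a tidy DataFrame (study, adc_lower, tdv_ml).  When binary
    `labels` are supplied (one per study), a per-threshold ROC AUC of tDV
    against the label is appended as an ``auc`` column (constant within
    threshold).
    """
    if len(lower_list) == 0:
        raise ValueError("lower_list must be nonempty")
    config = config or SegmentationConfig()
    studies = list(studies)
    rows = []
    for i, study in enumerate(studies):
        for lower in lower_list:
            cfg = SegmentationConfig(
                background_threshold=config.background_threshold,
                adc_upper=config.adc_upper,
                adc_lower=lower,
                computed_b=config.computed_b,
                otsu_bins=config.otsu_bins,
                intensity_scale=config.intensity_scale,
                otsu_on_mip=config.otsu_on_mip,
                mip_axis=config.mip_axis,
                adc_b_subset=config.adc_b_subset,
            )
            res = segment_study(study, cfg)
            rows.append({"study": i, "adc_lower": lower, "tdv_ml": res.tdv_ml})
    table = pd.DataFrame(rows)
    if labels is not None:
        from .response_stats import roc_analysis

        labels = np.asarray(labels)
        aucs = {}
        for lower in lower_list:
            sub = table[table.adc_lower == lower].sort_values("study")
            aucs[lower] = roc_analysis(sub.tdv_ml.to_numpy(), labels,
                                       direction="higher").auc
        table["auc"] = table.adc_lower.map(aucs)
    return table
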