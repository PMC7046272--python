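"""Synthetic phantoms and cohorts with exact ground truth.

Every downstream stage of the pipeline (ADC mapping, computed DWI, the
tumour-burden segmentation chain, IVIM, Dixon fat fraction, cohort
statistics) is exercised on data produced here, so all of it is testable
without any image download.

Two generators are provided:

* :func:`generate_phantom` builds a desk-scale whole-body study — a
  skeletal marrow compartment (spine, pelvis, femora), focal / diffuse /
  combined myelomatous involvement, a high-ADC organ (T2 shine-through
  stand-in) and a non-skeletal bright structure (brain stand-in that only
  the exclusion mask can remove) — as a multi-b-value DWI series plus a
  Dixon water/fat pair, with the lesion voxel set recorded exactly so the
  true tumour volume is known to voxel precision.
* :func:`generate_cohort` draws a two-group patient table (responders vs
  non-responders) whose per-variable percentage changes follow configured
  Gaussian group distributions.

Noiseless phantoms reproduce the generating IVIM signal equation
``S(b) = s0 * (f*exp(-b*D*) + (1-f)*exp(-b*D))`` exactly at every voxel;
noise, when requested, is Rician.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dwi_models import DwiSeries, ivim_signal

__all__ = [
    "IvimParams",
    "Lesion",
    "Organ",
    "PhantomSpec",
    "PhantomStudy",
    "CohortSpec",
    "generate_phantom",
    "add_rician_noise",
    "generate_cohort",
    "simulate_logistic_cohort",
    "diffuse_spec_for_volume",
    "SPINAL_B_VALUES",
    "WHOLE_BODY_B_VALUES",
    "DEFAULT_PCT_CHANGE_PARAMS",
    "DEFAULT_BASELINE_PARAMS",
    "DEFAULT_COHORT_VARIABLES",
]

#: b-values of the 9-point lumbar spinal DWI protocol (s/mm^2)
SPINAL_B_VALUES = (0.0, 40.0, 80.0, 140.0, 200.0, 500.0, 1000.0, 1500.0, 2000.0)
#: b-values of the whole-body DWIBS protocol (s/mm^2)
WHOLE_BODY_B_VALUES = (0.0, 1000.0)

PATTERNS = ("normal", "focal_dominant", "combined", "diffuse_dominant")


@dataclass(frozen=True)
class IvimParams:
    """Perfusion parameters of normal marrow: fraction f, D* and D (mm^2/s)."""

    f: float = 0.247
    dstar: float = 20.0e-3
    d: float | None = None  # None -> use the spec's marrow_adc

    def validate(self, marrow_adc: float) -> None:
        d = self.d if self.d is not None else marrow_adc
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("IVIM perfusion fraction f must lie in [0, 1]")
        if d <= 0:
            raise ValueError("IVIM tissue diffusion must be > 0")
        if self.dstar <= d:
            raise ValueError("IVIM pseudodiffusion D* must exceed tissue D")


@dataclass(frozen=True)
class Lesion:
    """Spherical focal lesion: center voxel, radius in mm, tissue values."""

    center: tuple[int, int, int]
    radius_mm: float = 8.0
    adc: float = 1.0e-3  # mm^2/s, inside the disease ADC band
    ff_percent: float = 5.0
    s0: float = 1000.0


@dataclass(frozen=True)
class Organ:
    """Non-marrow bright structure.

    ``kind='shine_through'`` gets an ADC above the upper disease cut so
    only the ADC filter removes it; ``kind='non_skeletal'`` carries an
    ADC inside the disease band so only the exclusion mask removes it.
    """

    center: tuple[int, int, int]
    radius_mm: float
    adc: float
    s0: float
    ff_percent: float = 10.0
    kind: str = "shine_through"  # or "non_skeletal"


def _default_organs() -> list[Organ]:
    return [
        Organ(center=(14, 32, 60), radius_mm=9.0, adc=2.5e-3, s0=4500.0,
              kind="shine_through"),
        Organ(center=(32, 32, 4), radius_mm=6.0, adc=0.8e-3, s0=800.0,
              kind="non_skeletal"),
    ]


def _default_lesions() -> list[Lesion]:
    return [
        Lesion(center=(32, 32, 30)),
        Lesion(center=(32, 32, 60)),
        Lesion(center=(32, 32, 90)),
    ]


@dataclass
class PhantomSpec:
    """Declarative description of a phantom study.

    The default grid is 64 x 64 x 128 voxels at 2 mm isotropic — a
    whole-spine field of view scaled to desk size.  ``noise_sigma`` is the
    Rician noise scale in the same arbitrary signal units as ``s0``
    (lesion s0 defaults to 1000, so sigma = 20 corresponds to SNR 50 at
    b = 0 in a lesion).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 128)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    pattern: str = "focal_dominant"
    lesions: list[Lesion] = field(default_factory=_default_lesions)
    organs: list[Organ] = field(default_factory=_default_organs)
    marrow_adc: float = 0.35e-3
    marrow_ff_percent: float = 40.0
    marrow_s0: float = 300.0
    diffuse_adc: float = 1.0e-3
    diffuse_s0: float = 1000.0
    diffuse_ff_percent: float = 5.0
    diffuse_involved_ml: float | None = None  # None -> 60% of marrow
    noise_sigma: float = 0.0
    ivim: IvimParams = field(default_factory=IvimParams)
    b_values: tuple[float, ...] = WHOLE_BODY_B_VALUES
    dixon_total: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be > 0")
        if self.marrow_adc <= 0 or self.diffuse_adc <= 0:
            raise ValueError("ADC values must be > 0")
        for frac in (self.marrow_ff_percent, self.diffuse_ff_percent):
            if not 0.0 <= frac <= 100.0:
                raise ValueError("fat fractions must lie in [0, 100] percent")
        for les in self.lesions:
            if les.adc <= 0:
                raise ValueError("lesion ADC must be > 0")
            if not 0.0 <= les.ff_percent <= 100.0:
                raise ValueError("lesion fat fraction must lie in [0, 100]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.ivim.validate(self.marrow_adc)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing)) / 1000.0

    def with_pattern(self, pattern: str, **overrides) -> "PhantomSpec":
        lesions = overrides.pop("lesions", None)
        if lesions is None:
            lesions = [] if pattern in ("normal", "diffuse_dominant") else _default_lesions()
        return replace(self, pattern=pattern, lesions=lesions, **overrides)


@dataclass
class PhantomStudy:
    """A generated phantom: DWI series, Dixon pair, and exact ground truth."""

    dwi: DwiSeries
    dixon_water: np.ndarray
    dixon_fat: np.ndarray
    truth_lesion_mask: np.ndarray  # bool; focal + diffuse involvement
    truth_exclusion_mask: np.ndarray  # bool; non-skeletal bright structures
    truth_marrow_mask: np.ndarray  # bool; uninvolved marrow
    truth_tdv_ml: float
    truth_ff_by_roi: dict[str, float]
    spec: PhantomSpec


def _sphere_mask(shape, center, radius_mm, spacing) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return r2 <= radius_mm ** 2


def _marrow_mask(shape) -> np.ndarray:
    """Skeleton stand-in: spine column + pelvis slab + two femora.

    Proportions are fixed to the default 64 x 64 x 128 layout and scaled
    with the grid.
    """
    nx, ny, nz = shape
    m = np.zeros(shape, dtype=bool)
    cx, cy = nx // 2, ny // 2
    # spine: 14 x 14 column through most of the z extent
    hw = max(1, round(7 * nx / 64))
    z0, z1 = round(8 * nz / 128), round(120 * nz / 128)
    m[cx - hw:cx + hw, cy - hw:cy + hw, z0:z1] = True
    # pelvis slab
    m[round(12 * nx / 64):round(52 * nx / 64),
      round(24 * ny / 64):round(40 * ny / 64),
      round(88 * nz / 128):round(98 * nz / 128)] = True
    # femora
    for x0 in (round(16 * nx / 64), round(42 * nx / 64)):
        m[x0:x0 + max(1, round(6 * nx / 64)),
          round(28 * ny / 64):round(34 * ny / 64),
          round(98 * nz / 128):round(126 * nz / 128)] = True
    return m


def add_rician_noise(volume: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Corrupt a magnitude image with Rician noise.

    Each voxel value m is replaced by sqrt((m + g1)^2 + g2^2) with g1, g2
    independent zero-mean Gaussians of scale `sigma`.  sigma = 0 returns
    the input unchanged; the result is deterministic given `seed`.
    """
    volume = np.asarray(volume, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, volume.shape)
    g2 = rng.normal(0.0, sigma, volume.shape)
    return np.sqrt((volume + g1) ** 2 + g2 ** 2)


def generate_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Rasterize a phantom study from its spec.

    Tissue maps are painted in the order marrow -> diffuse involvement ->
    focal lesions -> organs; lesion voxel sets are recorded exactly so
    ``truth_tdv_ml`` equals voxel count x voxel volume.  Overlapping
    focal lesions with conflicting ADC are rejected.
    """
    shape = tuple(spec.grid_shape)
    spacing = spec.voxel_spacing
    voxvol = spec.voxel_volume_ml

    s0 = np.zeros(shape)
    adc = np.full(shape, np.nan)
    fmap = np.zeros(shape)
    ff = np.full(shape, np.nan)
    tissue = np.zeros(shape, dtype=bool)

    marrow = _marrow_mask(shape)
    ivim_d = spec.ivim.d if spec.ivim.d is not None else spec.marrow_adc
    s0[marrow] = spec.marrow_s0
    adc[marrow] = ivim_d
    fmap[marrow] = spec.ivim.f
    ff[marrow] = spec.marrow_ff_percent
    tissue |= marrow

    # diffuse involvement: a contiguous run of marrow voxels (flat order)
    diffuse = np.zeros(shape, dtype=bool)
    if spec.pattern in ("combined", "diffuse_dominant"):
        target_ml = spec.diffuse_involved_ml
        n_marrow = int(marrow.sum())
        if target_ml is None:
            n_inv = int(round(0.6 * n_marrow))
        else:
            n_inv = int(round(target_ml / voxvol))
        if n_inv > n_marrow:
            raise ValueError(
                f"diffuse_involved_ml={target_ml} exceeds marrow capacity "
                f"({n_marrow * voxvol:.1f} ml)"
            )
        flat = np.flatnonzero(marrow.ravel())[:n_inv]
        diffuse.ravel()[flat] = True
        s0[diffuse] = spec.diffuse_s0
        adc[diffuse] = spec.diffuse_adc
        fmap[diffuse] = 0.0
        ff[diffuse] = spec.diffuse_ff_percent

    # focal lesions (monoexponential, f = 0)
    lesion_mask = np.zeros(shape, dtype=bool)
    lesions = spec.lesions if spec.pattern != "normal" else []
    if spec.pattern == "diffuse_dominant":
        lesions = []
    painted_adc = np.full(shape, np.nan)
    for les in lesions:
        sm = _sphere_mask(shape, les.center, les.radius_mm, spacing)
        clash = sm & ~np.isnan(painted_adc) & (painted_adc != les.adc)
        if np.any(clash):
            raise ValueError("overlapping lesions assigned conflicting ADC")
        painted_adc[sm] = les.adc
        lesion_mask |= sm
        s0[sm] = les.s0
        adc[sm] = les.adc
        fmap[sm] = 0.0
        ff[sm] = les.ff_percent
    tissue |= lesion_mask
    lesion_mask |= diffuse

    exclusion = np.zeros(shape, dtype=bool)
    for org in spec.organs:
        sm = _sphere_mask(shape, org.center, org.radius_mm, spacing)
        if np.any(sm & lesion_mask):
            raise ValueError("organ overlaps a lesion; move it")
        s0[sm] = org.s0
        adc[sm] = org.adc
        fmap[sm] = 0.0
        ff[sm] = org.ff_percent
        tissue |= sm
        if org.kind == "non_skeletal":
            exclusion |= sm

    # DWI volumes from the generating IVIM equation (air stays at 0)
    b_values = np.asarray(spec.b_values, dtype=float)
    adc_safe = np.where(np.isnan(adc), 1.0, adc)
    vols = np.stack([
        np.where(tissue,
                 ivim_signal(b, s0, fmap, spec.ivim.dstar, adc_safe), 0.0)
        for b in b_values
    ])

    # Dixon pair: fat/(fat+water) = ff/100 per tissue
    total = np.where(tissue, spec.dixon_total, 0.0)
    ff_safe = np.where(np.isnan(ff), 0.0, ff)
    dixon_fat = total * ff_safe / 100.0
    dixon_water = total - dixon_fat

    if spec.noise_sigma > 0:
        ss = np.random.SeedSequence(spec.seed)
        seeds = ss.generate_state(len(b_values) + 2)
        vols = np.stack([
            add_rician_noise(v, spec.noise_sigma, int(s))
            for v, s in zip(vols, seeds[:-2])
        ])
        dixon_water = add_rician_noise(dixon_water, spec.noise_sigma, int(seeds[-2]))
        dixon_fat = add_rician_noise(dixon_fat, spec.noise_sigma, int(seeds[-1]))

    dwi = DwiSeries(b_values=b_values, volumes=vols, voxel_spacing=spacing)
    return PhantomStudy(
        dwi=dwi,
        dixon_water=dixon_water,
        dixon_fat=dixon_fat,
        truth_lesion_mask=lesion_mask,
        truth_exclusion_mask=exclusion,
        truth_marrow_mask=marrow & ~lesion_mask,
        truth_tdv_ml=float(lesion_mask.sum()) * voxvol,
        truth_ff_by_roi={
            "marrow": spec.marrow_ff_percent,
            "lesion": (lesions[0].ff_percent if lesions
                       else spec.diffuse_ff_percent),
        },
        spec=spec,
    )


def diffuse_spec_for_volume(target_ml: float, **overrides) -> PhantomSpec:
    """Spec for a diffuse-dominant phantom with an exact target tumour volume."""
    return PhantomSpec(pattern="diffuse_dominant", lesions=[],
                       diffuse_involved_ml=target_ml, **overrides)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

DEFAULT_COHORT_VARIABLES = (
    "m_protein", "b2_microglobulin", "hemoglobin", "tdv", "mean_adc", "ff",
)

#: default percentage-change distributions, (mean, SD) per group: the
#: study conditions this generator emulates (responders show falling
#: tumour burden / M protein and rising fat fraction, ADC, haemoglobin)
DEFAULT_PCT_CHANGE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "m_protein": {"responder": (-46.2, 40.6), "non-responder": (93.2, 180.7)},
    "b2_microglobulin": {"responder": (-24.6, 32.3), "non-responder": (13.0, 36.1)},
    "hemoglobin": {"responder": (12.0, 8.4), "non-responder": (-0.61, 17.8)},
    "tdv": {"responder": (-54.6, 32.1), "non-responder": (45.7, 45.5)},
    "mean_adc": {"responder": (25.5, 32.7), "non-responder": (1.46, 7.9)},
    "ff": {"responder": (94.3, 45.5), "non-responder": (24.7, 34.1)},
}

#: default baseline distributions, (mean, SD) per group
DEFAULT_BASELINE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "m_protein": {"responder": (1546.0, 722.0), "non-responder": (1987.0, 652.0)},
    "b2_microglobulin": {"responder": (4.50, 1.47), "non-responder": (3.52, 2.02)},
    "hemoglobin": {"responder": (10.5, 2.2), "non-responder": (11.5, 1.5)},
    "tdv": {"responder": (111.4, 75.2), "non-responder": (64.3, 15.2)},
    "mean_adc": {"responder": (1.076, 0.312), "non-responder": (1.130, 0.242)},
    "ff": {"responder": (32.2, 24.7), "non-responder": (44.2, 22.4)},
}


@dataclass
class CohortSpec:
    """Two-group cohort: group sizes and per-variable Gaussian parameters."""

    n_responders: int = 15
    n_nonresponders: int = 35
    change_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_PCT_CHANGE_PARAMS)
    baseline_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_BASELINE_PARAMS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders + self.n_nonresponders < 2:
            raise ValueError("cohort needs at least two patients")
        for params in (self.change_params, self.baseline_params):
            for var, groups in params.items():
                for grp, (_, sd) in groups.items():
                    if sd < 0:
                        raise ValueError(f"SD for {var}/{grp} must be >= 0")


def _positive_normal(rng, mean, sd, n):
    """Gaussian draws truncated to > 0 by rejection (baselines feed
    percentage changes, which require positive denominators)."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("zero-SD baseline must have positive mean")
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, n)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    out[out <= 0] = mean if mean > 0 else sd  # pathological specs
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic two-group cohort table.

    Returns a DataFrame with one row per patient: ``patient_id``,
    ``group`` (responder / non-responder) and, for every configured
    variable, ``<var>_baseline``, ``<var>_followup`` and
    ``<var>_pct_change`` (followup = baseline * (1 + pct/100)).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows: dict[str, np.ndarray | list] = {}
    groups = (["responder"] * spec.n_responders
              + ["non-responder"] * spec.n_nonresponders)
    n = len(groups)
    rows["patient_id"] = [f"P{i:04d}" for i in range(n)]
    rows["group"] = groups
    garr = np.asarray(groups)
    for var in spec.change_params:
        base = np.empty(n)
        pct = np.empty(n)
        for grp in ("responder", "non-responder"):
            sel = garr == grp
            bmean, bsd = spec.baseline_params.get(var, {}).get(grp, (100.0, 0.0))
            base[sel] = _positive_normal(rng, bmean, bsd, int(sel.sum()))
            cmean, csd = spec.change_params[var][grp]
            pct[sel] = (rng.normal(cmean, csd, int(sel.sum()))
                        if csd > 0 else cmean)
        rows[f"{var}_baseline"] = base
        rows[f"{var}_pct_change"] = pct
        rows[f"{var}_followup"] = base * (1.0 + pct / 100.0)
    return pd.DataFrame(rows)


def simulate_logistic_cohort(
    betas: Mapping[str, float],
    intercept: float,
    n: int,
    seed: int,
    predictor_sds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate predictors and a Bernoulli outcome from a known logistic model.

    Predictors are independent zero-mean Gaussians (SD 1 unless given);
    the outcome column is ``response``.  Used for parameter-recovery
    checks of the logistic response model.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    eta = np.full(n, float(intercept))
    for name, beta in betas.items():
        sd = 1.0 if predictor_sds is None else predictor_sds.get(name, 1.0)
        x = rng.normal(0.0, sd, n)
        cols[name] = x
        eta += beta * x
    p = 1.0 / (1.0 + np.exp(-eta))
    cols["response"] = (rng.uniform(size=n) < p).astype(int)
    return pd.DataFrame(cols)
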