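"""Run orchestration: hermetic per-patient and cohort runs from a config.

A :class:`RunConfig` names every input (paths only; nothing outside it is
read), the segmentation/IVIM/FF settings and an output directory.
:func:`run_patient` executes the whole image-analysis chain for one
study — tDV segmentation, ROI IVIM fit, ROI fat fraction — writing all
intermediates plus a :class:`RunReport` (JSON) with per-stage counts,
parameters and wall-clock, so a run is reproducible from its report.
:func:`run_cohort` maps that over a patient list (baseline + follow-up
studies), derives percentage changes and hands the table to
:func:`tdvpipe.response_stats.cohort_report`; per-patient failures are
recorded and skipped rather than aborting the cohort.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from ._version import __version__
from .dwi_models import fit_ivim
from .ff_quant import (DIXON_ROI_AREA_BOUNDS_MM2, DWI_ROI_AREA_BOUNDS_MM2,
                       compute_ff_map, roi_mean, roi_mean_signal)
from .response_stats import cohort_report, percentage_change
from .tdv_pipeline import SegmentationConfig, segment_study

__all__ = ["RunConfig", "RunReport", "run_patient", "run_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one patient run."""

    dwi: str
    bvals: str
    output_dir: str
    exclusion_mask: str | None = None
    dixon_water: str | None = None
    dixon_fat: str | None = None
    roi_table: str | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    ivim_split_b: float = 200.0
    validate_roi_areas: bool = True
    seed: int = 0

    REQUIRED = ("dwi", "bvals")

    def validate_paths(self) -> None:
        for name in ("dwi", "bvals", "exclusion_mask", "dixon_water",
                     "dixon_fat", "roi_table"):
            value = getattr(self, name)
            if value is None:
                continue
            if not Path(value).exists():
                raise FileNotFoundError(
                    f"RunConfig.{name}: path does not exist: {value}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seg = d.pop("segmentation", None)
        cfg = cls(**d)
        if seg is not None:
            cfg.segmentation = SegmentationConfig.from_dict(seg)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunReport:
    """Audit trail of a run: parameters, per-stage counts and timings."""

    version: str
    seed: int
    parameters: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, seconds: float, **info) -> None:
        if stage in self.stages:
            raise ValueError(f"stage {stage!r} recorded twice")
        self.stages[stage] = {"wall_clock_s": round(seconds, 4), **info}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "seed": self.seed,
                 "parameters": self.parameters, "stages": self.stages},
                fh, indent=2, default=str)


def run_patient(config: RunConfig) -> dict:
    """Execute the image-analysis chain for one study.

    Returns the per-patient indices (tdv_ml, mean_adc, percentiles,
    skewness/kurtosis, ivim f/D*/D per ROI, FF per ROI) and writes the
    disease mask (NIfTI), a features CSV and the run report JSON into
    ``config.output_dir``.  Deterministic given inputs and seed.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg = config.segmentation
    report = RunReport(
        version=__version__,
        seed=config.seed,
        parameters={
            "segmentation": vars(seg).copy(),
            "ivim_split_b": config.ivim_split_b,
            "inputs": {k: getattr(config, k) for k in
                       ("dwi", "bvals", "exclusion_mask", "dixon_water",
                        "dixon_fat", "roi_table")},
        },
    )
    indices: dict = {}

    t0 = time.perf_counter()
    series = tio.load_series(config.dwi, config.bvals)
    exclusion = (tio.load_mask(config.exclusion_mask)
                 if config.exclusion_mask else None)
    report.record("load", time.perf_counter() - t0,
                  n_b_values=int(series.b_values.size),
                  grid=list(series.shape))

    t0 = time.perf_counter()
    res = segment_study(series, seg, exclusion_mask=exclusion)
    report.record("segment", time.perf_counter() - t0,
                  **res.stage_counts, otsu_level=res.otsu_level,
                  n_voxels=res.n_voxels)
    indices.update(
        tdv_ml=res.tdv_ml,
        mean_adc=res.features.mean,
        adc_p25=res.features.p25,
        adc_p75=res.features.p75,
        adc_skewness=res.features.skewness,
        adc_kurtosis=res.features.kurtosis,
    )
    tio.save_mask(res.disease_mask, out / "disease_mask.nii.gz",
                  series.voxel_spacing)

    rois = tio.load_roi_table(config.roi_table) if config.roi_table else {}

    if rois:
        t0 = time.perf_counter()
        bounds = DWI_ROI_AREA_BOUNDS_MM2 if config.validate_roi_areas else None
        for name, roi in rois.items():
            sig = roi_mean_signal(series, roi, area_bounds=bounds)
            try:
                fit = fit_ivim(sig.b_value.to_numpy(),
                               sig.mean_signal.to_numpy(),
                               split_b=config.ivim_split_b)
                indices[f"ivim_f_{name}"] = fit.f
                indices[f"ivim_dstar_{name}"] = fit.dstar
                indices[f"ivim_d_{name}"] = fit.d
            except ValueError as exc:
                logger.warning("IVIM fit skipped for ROI %s: %s", name, exc)
        report.record("ivim", time.perf_counter() - t0, n_rois=len(rois))

    if config.dixon_water and config.dixon_fat:
        t0 = time.perf_counter()
        water, spacing = tio.load_volume(config.dixon_water)
        fat, _ = tio.load_volume(config.dixon_fat)
        ffmap = compute_ff_map(water, fat, spacing)
        tio.save_volume(ffmap.values, out / "ff_map.nii.gz", spacing)
        bounds = DIXON_ROI_AREA_BOUNDS_MM2 if config.validate_roi_areas else None
        for name, roi in rois.items():
            indices[f"ff_{name}"] = roi_mean(ffmap, roi, area_bounds=bounds)
        report.record("fat_fraction", time.perf_counter() - t0,
                      n_rois=len(rois))

    pd.DataFrame([indices]).to_csv(out / "indices.csv", index=False)
    report.to_json(out / "run_report.json")
    return indices


def run_cohort(
    patients: list[dict],
    output_dir,
    variables: list[str] | None = None,
) -> dict:
    """Run baseline + follow-up studies for a patient list and report.

    Each entry of `patients` is ``{"id": ..., "group": "responder" |
    "non-responder", "baseline": RunConfig-dict, "followup":
    RunConfig-dict}``.  Patients whose runs fail are listed in the
    report and skipped; the cohort statistics use the survivors.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, failures = [], []
    for pat in patients:
        pid = pat.get("id", f"patient{len(rows)}")
        try:
            base = run_patient(RunConfig.from_dict(
                {**pat["baseline"], "output_dir": str(out / pid / "baseline")}))
            fup = run_patient(RunConfig.from_dict(
                {**pat["followup"], "output_dir": str(out / pid / "followup")}))
        except Exception as exc:  # noqa: BLE001 - error isolation contract
            logger.warning("patient %s failed: %s", pid, exc)
            failures.append({"id": pid, "error": str(exc)})
            continue
        row = {"patient_id": pid, "group": pat["group"]}
        for key in set(base) & set(fup):
            row[f"{key}_baseline"] = base[key]
            row[f"{key}_followup"] = fup[key]
            row[f"{key}_pct_change"] = percentage_change(base[key], fup[key])
        rows.append(row)
    if len(rows) < 2:
        raise RuntimeError("run_cohort: fewer than two patients succeeded")
    table = pd.DataFrame(rows)
    table.to_csv(out / "cohort_indices.csv", index=False)

    report = cohort_report(table, variables=variables)
    report.group_changes.to_csv(out / "group_changes.csv")
    report.roc.to_csv(out / "roc.csv")
    if report.glm is not None:
        report.glm.table.to_csv(out / "glm.csv")
    with open(out / "cohort_report.json", "w") as fh:
        json.dump(
            {"n_patients": len(rows), "failures": failures,
             "selected_predictors": report.selected_predictors,
             "notes": report.notes},
            fh, indent=2, default=str)
    return {"table": table, "report": report, "failures": failures}
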