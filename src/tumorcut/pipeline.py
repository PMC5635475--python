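"""End-to-end pipeline: preprocessing -> tumor VOI extraction ->
KFCMS + graph-cuts segmentation -> postprocessing, with an optional
evaluation against ground truth.

The run report captures everything needed to reproduce a run: the
fully resolved configuration, the seed before/after correction, the
VOI bounds, KFCMS diagnostics, and the cut energy.  Stage timings are
recorded only on request so that default reports are byte-for-byte
deterministic.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import graphcut, postprocess, preprocess, voi
from .core_types import LabelMask, PipelineConfig, SeedPoint, Volume
from .metrics import MetricsReport, evaluate_masks

__all__ = ["RunReport", "StageError", "segment_volume", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    config: dict
    seed_input: tuple[int, int, int]
    seed_corrected: tuple[int, int, int] = (0, 0, 0)
    seed_intensity: float = float("nan")
    voi_offset: tuple[int, int, int] = (0, 0, 0)
    voi_size: tuple[int, int, int] = (0, 0, 0)
    kfcms_centers: list[float] = field(default_factory=list)
    kfcms_iterations: int = 0
    cut_energy: float = float("nan")
    stage_voxels: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings_s: dict | None = None
    metrics: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "config": self.config,
            "seed_input": list(self.seed_input),
            "seed_corrected": list(self.seed_corrected),
            "seed_intensity": self.seed_intensity,
            "voi_offset": list(self.voi_offset),
            "voi_size": list(self.voi_size),
            "kfcms_centers": self.kfcms_centers,
            "kfcms_iterations": self.kfcms_iterations,
            "cut_energy": self.cut_energy,
            "stage_voxels": self.stage_voxels,
            "warnings": self.warnings,
        }
        if self.timings_s is not None:
            out["timings_s"] = self.timings_s
        if self.metrics is not None:
            out["metrics"] = self.metrics
        return out

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def segment_volume(
    ct: Volume,
    liver: LabelMask,
    seed_index: tuple[int, int, int],
    cfg: PipelineConfig | None = None,
    truth: LabelMask | None = None,
    collect_timings: bool = False,
) -> tuple[LabelMask, RunReport]:
    """Segment one tumor; returns the mask on the original CT grid.

    ``seed_index`` is a voxel index in the *original* grid; it is
    mapped to the isotropic grid, auto-corrected to the darkest voxel
    in its 5x5x3 neighborhood, and must land inside the liver.
    """
    cfg = cfg or PipelineConfig()
    report = RunReport(config=cfg.to_dict(), seed_input=tuple(seed_index))
    timings: dict[str, float] = {}

    def tick(stage, t0):
        timings[stage] = round(time.perf_counter() - t0, 3)

    if ct.size != liver.size:
        raise StageError("preprocess", f"grid mismatch: ct {ct.size} vs liver {liver.size}")

    # --- preprocessing -------------------------------------------------
    t0 = time.perf_counter()
    try:
        masked = preprocess.apply_liver_mask(ct, liver, cfg.fill_value_hu)
        den = preprocess.median_denoise(masked, cfg.median_radius_vox)
        iso = preprocess.resample_isotropic(den, cfg.target_spacing_mm, "linear")
        liver_iso = preprocess.resample_isotropic(
            liver, cfg.target_spacing_mm, "nearest"
        )
        # map the seed index into the isotropic grid (voxel-center convention)
        seed_iso_idx = tuple(
            int(np.clip(round(i * s / cfg.target_spacing_mm), 0, n - 1))
            for i, s, n in zip(seed_index, ct.spacing, iso.size)
        )
        seed = preprocess.correct_seed(iso, SeedPoint(index=seed_iso_idx))
        if liver_iso.data[seed.index] == 0:
            raise StageError("preprocess", f"corrected seed {seed.index} outside the liver")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    tick("preprocess", t0)
    report.seed_corrected = seed.index
    report.seed_intensity = float(seed.intensity)
    report.stage_voxels["isotropic_grid"] = int(np.prod(iso.size))

    # --- VOI extraction ------------------------------------------------
    t0 = time.perf_counter()
    try:
        tvoi, plane_masks = voi.extract_tumor_voi(iso, liver_iso, seed, cfg)
    except voi.EmptyRegionError as exc:
        raise StageError("voi", f"segmentation failed: {exc}") from exc
    tick("voi", t0)
    report.voi_offset = tvoi.parent_offset
    report.voi_size = tvoi.volume.size
    report.stage_voxels["voi"] = int(np.prod(tvoi.volume.size))

    # --- KFCMS + graph cuts --------------------------------------------
    t0 = time.perf_counter()
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            voi_mask, info = graphcut.segment_voi(tvoi, cfg, plane_masks)
        report.warnings.extend(str(w.message) for w in wlist)
    except (graphcut.SeedingError, voi.EmptyRegionError) as exc:
        raise StageError("graphcut", f"segmentation failed: {exc}") from exc
    tick("graphcut", t0)
    report.kfcms_centers = info["centers"]
    report.kfcms_iterations = info["kfcms_iterations"]
    report.cut_energy = info["cut_energy"]
    report.stage_voxels["cut_foreground"] = int(voi_mask.data.sum())

    # --- postprocessing ------------------------------------------------
    t0 = time.perf_counter()
    try:
        comp = postprocess.select_seed_component(voi_mask, tvoi.seed_local)
        refined = postprocess.refine_mask(
            comp, cfg.post_median_radius_vox, cfg.dilation_radius_vox
        )
    except postprocess.EmptySegmentationError as exc:
        raise StageError("postprocess", f"segmentation failed: {exc}") from exc
    # paste the VOI result into the full isotropic grid, then resample
    full_iso = np.zeros(iso.size, dtype=np.uint8)
    sl = tuple(
        slice(o, o + n) for o, n in zip(tvoi.parent_offset, refined.size)
    )
    full_iso[sl] = refined.data
    mask_iso = LabelMask(full_iso, spacing=iso.spacing, origin=iso.origin)
    final = postprocess.resample_to_original(mask_iso, ct)
    tick("postprocess", t0)
    report.stage_voxels["final"] = int(final.data.sum())

    if truth is not None:
        rep = evaluate_masks(final, truth, spacing=ct.spacing)
        report.metrics = rep.to_dict()
    if collect_timings:
        report.timings_s = timings
    return final, report


def run_pipeline(
    ct_path: str | Path,
    liver_path: str | Path,
    seed: tuple[int, int, int],
    out_path: str | Path,
    config_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    report_path: str | Path | None = None,
    collect_timings: bool = False,
) -> RunReport:
    """File-level driver: read inputs, segment, write the mask and report."""
    from .core_types import read_volume, write_volume

    ct = read_volume(ct_path)
    liver = read_volume(liver_path, as_mask=True)
    truth = read_volume(truth_path, as_mask=True) if truth_path else None
    cfg = PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    mask, report = segment_volume(
        ct, liver, seed, cfg, truth=truth, collect_timings=collect_timings
    )
    write_volume(mask, out_path)
    if report_path:
        report.write_json(report_path)
    return report
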