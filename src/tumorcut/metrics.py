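"""Segmentation evaluation: overlap and surface-distance metrics with the
MICCAI 2008 liver-tumor challenge (LTSC08) 0-100 scoring.

Metrics, segmentation A against ground truth B:

* VOE  = 100 * (1 - |A∩B| / |A∪B|)          volumetric overlap error, %
* RVD  = 100 * (|A| - |B|) / |B|             signed; negative = undersegmentation
* DICE = 2|A∩B| / (|A| + |B|)
* ASD / RMSD / MaxD: average / root-mean-square / maximum symmetric
  distance (mm) between the border voxels of A and B.  A border voxel
  is a mask voxel with at least one face-neighbor outside the mask.

Scoring: each metric m maps to max(0, 100 - 10*|m|/ref), where ref is
the error of an average-quality manual segmentation; zero error scores
100 and manual quality scores 90.  The overall score is the mean of
the five per-metric scores (DICE is reported but not scored).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_types import LabelMask

__all__ = [
    "MANUAL_REFERENCE",
    "MetricsReport",
    "overlap_metrics",
    "surface_distances",
    "ltsc08_score",
    "evaluate_masks",
]

#: Average manual-segmentation quality: the per-metric errors worth a score of 90.
MANUAL_REFERENCE = {
    "voe_pct": 12.94,
    "rvd_pct": 9.64,
    "asd_mm": 0.40,
    "rmsd_mm": 0.72,
    "maxd_mm": 4.0,
}

_FACE = ndimage.generate_binary_structure(3, 1)


@dataclass
class MetricsReport:
    voe_pct: float
    rvd_pct: float
    asd_mm: float
    rmsd_mm: float
    maxd_mm: float
    dice: float
    scores: dict[str, float] = field(default_factory=dict)
    overall_score: float = 0.0

    def to_dict(self) -> dict:
        return {
            "voe_pct": self.voe_pct,
            "rvd_pct": self.rvd_pct,
            "asd_mm": self.asd_mm,
            "rmsd_mm": self.rmsd_mm,
            "maxd_mm": self.maxd_mm,
            "dice": self.dice,
            "scores": dict(self.scores),
            "overall_score": self.overall_score,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_csv(self, path: str | Path) -> None:
        d = self.to_dict()
        scores = d.pop("scores")
        d.update({f"score_{k}": v for k, v in scores.items()})
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(d))
            w.writeheader()
            w.writerow(d)


def _as_bool(mask: LabelMask | np.ndarray) -> np.ndarray:
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    return data.astype(bool)


def overlap_metrics(A: LabelMask, B: LabelMask) -> tuple[float, float, float]:
    """(VOE %, RVD %, DICE) of segmentation A against ground truth B."""
    if isinstance(A, LabelMask) and isinstance(B, LabelMask) and A.size != B.size:
        raise ValueError(f"grid mismatch: {A.size} vs {B.size}")
    a, b = _as_bool(A), _as_bool(B)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("ground truth mask is empty")
    na = int(a.sum())
    inter = int((a & b).sum())
    union = na + nb - inter
    voe = 100.0 * (1.0 - inter / union) if union else 0.0
    rvd = 100.0 * (na - nb) / nb
    dice = 2.0 * inter / (na + nb)
    return voe, rvd, dice


def _border(mask: np.ndarray) -> np.ndarray:
    # voxels with >= 1 face-neighbor outside the mask (grid edge counts as outside)
    eroded = ndimage.binary_erosion(mask, _FACE, border_value=0)
    return mask & ~eroded


def surface_distances(
    A: LabelMask, B: LabelMask, spacing: tuple[float, float, float] | None = None
) -> tuple[float, float, float]:
    """(ASD, RMSD, MaxD) in mm between the borders of A and B; symmetric."""
    a, b = _as_bool(A), _as_bool(B)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("surface distances need two non-empty masks")
    if spacing is None:
        spacing = A.spacing if isinstance(A, LabelMask) else (1.0, 1.0, 1.0)
    ba, bb = _border(a), _border(b)
    # distance maps to the nearest border voxel of the other mask
    d_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    da, db = d_to_b[ba], d_to_a[bb]
    # aggregate per direction, then combine commutatively so the result
    # is bitwise symmetric in (A, B)
    n = da.size + db.size
    asd = (float(da.sum()) + float(db.sum())) / n
    rmsd = np.sqrt((float((da**2).sum()) + float((db**2).sum())) / n)
    maxd = max(float(da.max()), float(db.max()))
    return float(asd), float(rmsd), maxd


def ltsc08_score(m: float, ref: float) -> float:
    """Score in [0, 100]: 100 at zero error, 90 at manual quality."""
    if ref <= 0:
        raise ValueError("reference value must be positive")
    return max(0.0, 100.0 - 10.0 * abs(m) / ref)


def evaluate_masks(
    A: LabelMask,
    B: LabelMask,
    spacing: tuple[float, float, float] | None = None,
    reference: dict[str, float] = MANUAL_REFERENCE,
) -> MetricsReport:
    """Full metrics report of segmentation A against ground truth B."""
    voe, rvd, dice = overlap_metrics(A, B)
    if _as_bool(A).any():
        asd, rmsd, maxd = surface_distances(A, B, spacing)
    else:  # empty segmentation: surface distances undefined, report inf
        asd = rmsd = maxd = float("inf")
    values = {
        "voe_pct": voe, "rvd_pct": rvd,
        "asd_mm": asd, "rmsd_mm": rmsd, "maxd_mm": maxd,
    }
    scores = {k: ltsc08_score(values[k], reference[k]) for k in reference}
    overall = float(np.mean(list(scores.values())))
    return MetricsReport(
        voe_pct=voe, rvd_pct=rvd, asd_mm=asd, rmsd_mm=rmsd, maxd_mm=maxd,
        dice=dice, scores=scores, overall_score=overall,
    )
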