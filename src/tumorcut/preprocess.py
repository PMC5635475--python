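"""Preprocessing: liver masking, median denoising, isotropic resampling,
and seed auto-correction.

The liver mask is an input (the pipeline assumes a presegmented liver);
non-liver voxels are replaced by a constant fill value well above
liver/tumor HU so that region growing never leaks outside the liver.
All later geometric rules (20 mm centroid stop, 15 mm margin) operate on
the 1 mm isotropic grid produced here.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core_types import LabelMask, SeedPoint, Volume

__all__ = [
    "apply_liver_mask",
    "median_denoise",
    "resample_isotropic",
    "correct_seed",
]


def apply_liver_mask(ct: Volume, liver: LabelMask, fill_value: float = 200.0) -> Volume:
    """Replace voxels outside the liver mask by ``fill_value`` (HU)."""
    if ct.size != liver.size:
        raise ValueError(f"grid mismatch: ct {ct.size} vs liver {liver.size}")
    out = np.where(liver.data > 0, ct.data, fill_value)
    return ct.with_data(out.astype(np.float64))


def median_denoise(v: Volume, radius_vox: tuple[int, int, int] = (1, 1, 1)) -> Volume:
    """Median filter with a (2r+1) window per axis, edge-replicated borders."""
    if any(r < 0 for r in radius_vox):
        raise ValueError(f"radius must be non-negative, got {radius_vox}")
    if all(r == 0 for r in radius_vox):
        return v.with_data(v.data.copy())
    size = tuple(2 * r + 1 for r in radius_vox)
    out = ndimage.median_filter(v.data, size=size, mode="nearest")
    return v.with_data(out)


def _resampled_size(size: tuple[int, ...], spacing: tuple[float, ...], t: float):
    return tuple(max(1, int(round(n * s / t))) for n, s in zip(size, spacing))


def resample_isotropic(
    v: Volume | LabelMask,
    target_spacing_mm: float = 1.0,
    interpolation: str = "linear",
) -> Volume | LabelMask:
    """Resample onto an isotropic grid of ``target_spacing_mm``.

    The output grid keeps the input origin; output size is
    ``round(size * spacing / t)`` per axis (minimum 1).  Intensities are
    sampled under the voxel-center convention with trilinear
    interpolation (``"linear"``) or nearest neighbor (``"nearest"``,
    mandatory for masks).  Already-isotropic inputs pass through
    unchanged.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    t = float(target_spacing_mm)
    if np.allclose(v.spacing, (t, t, t)):
        return v.with_data(v.data.copy())
    new_size = _resampled_size(v.size, v.spacing, t)
    # fractional source index of each output voxel center
    grids = [
        np.arange(n) * t / s for n, s in zip(new_size, v.spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        v.data.astype(np.float64), np.stack(coords), order=order, mode="nearest"
    )
    if isinstance(v, LabelMask):
        out = np.round(out).astype(v.data.dtype)
    result = type(v)(data=out, spacing=(t, t, t), origin=v.origin)
    return result


def correct_seed(v: Volume, seed: SeedPoint) -> SeedPoint:
    """Move the seed to the darkest voxel in a 5x5x3 box around it.

    The box spans 5 voxels in x and y and 3 in z (mirroring thick-slice
    acquisition geometry), clipped at the volume borders.  If the
    original seed ties for the minimum it is kept (determinism across
    operators); other ties resolve to the smallest (k, j, i) index.
    """
    if not seed.inside(v):
        raise ValueError(f"seed {seed.index} outside grid {v.size}")
    i, j, k = seed.index
    lo = (max(0, i - 2), max(0, j - 2), max(0, k - 1))
    hi = (min(v.size[0], i + 3), min(v.size[1], j + 3), min(v.size[2], k + 2))
    box = v.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    vmin = box.min()
    if v.data[i, j, k] == vmin:
        return SeedPoint(index=(i, j, k), intensity=float(vmin))
    cand = np.argwhere(box == vmin)
    # prefer smallest (k, j, i): sort on reversed axes
    order = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))
    bi, bj, bk = cand[order[0]]
    idx = (int(lo[0] + bi), int(lo[1] + bj), int(lo[2] + bk))
    return SeedPoint(index=idx, intensity=float(vmin))
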