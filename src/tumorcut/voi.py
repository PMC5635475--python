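"""Tumor VOI extraction with confidence-connected region growing (CCRG).

A seeded region grows on each of the three orthogonal slices through
the seed.  Each iteration recomputes the region mean ``m_c`` and
standard deviation ``sigma_c`` and admits all 4-connected neighbor
pixels with intensity in ``[m_c - l*sigma_c, m_c + l*sigma_c]``.  A
single multiplicative factor ``l`` under- or over-segments depending on
lesion size, so the growth is swept over l in [1.5, 2.5] and the binary
masks summed into an integration image; the tumor mask is the pixels
reaching at least half of the integration maximum.  The 3D bounding box
of the three plane masks, padded by a 15 mm safety margin, defines the
tumor VOI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_types import LabelMask, PipelineConfig, SeedPoint, TumorVOI, Volume

__all__ = [
    "CCRGState",
    "EmptyRegionError",
    "ccrg_slice",
    "extract_planes",
    "ccrg_sweep",
    "tumor_mask_from_integration",
    "compute_voi",
    "extract_tumor_voi",
]

_CROSS_2D = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

#: the three orthogonal planes through the seed, as (fixed axis, in-plane axes)
PLANES = {"axial": (2, (0, 1)), "coronal": (1, (0, 2)), "sagittal": (0, (1, 2))}


class EmptyRegionError(RuntimeError):
    """CCRG produced no usable tumor region."""


@dataclass
class CCRGState:
    """Diagnostic snapshot of one confidence-connected growth."""

    region: np.ndarray
    m_c: float
    sigma_c: float
    l: float
    iteration: int


def _initial_disk(shape: tuple[int, int], seed2d: tuple[int, int], radius: float = 2.0):
    ii, jj = np.ogrid[: shape[0], : shape[1]]
    return (ii - seed2d[0]) ** 2 + (jj - seed2d[1]) ** 2 <= radius**2


def ccrg_slice(
    slice_img: np.ndarray,
    seed2d: tuple[int, int],
    l: float,
    max_iter: int = 100,
    sigma_min: float = 1.0,
    return_state: bool = False,
):
    """Confidence-connected region growing on a single 2D slice.

    Starts from a disk of radius 2 pixels around the seed.  Each
    iteration recomputes the region statistics, then adds every
    4-connected neighbor inside ``[m_c - l*sigma_c, m_c + l*sigma_c]``;
    growth stops when no pixel is added or ``max_iter`` is reached.
    ``sigma_min`` floors the standard deviation so a constant initial
    region still has a usable inclusion range.
    """
    slice_img = np.asarray(slice_img, dtype=np.float64)
    if slice_img.ndim != 2:
        raise ValueError("ccrg_slice expects a 2D image")
    if not (0 <= seed2d[0] < slice_img.shape[0] and 0 <= seed2d[1] < slice_img.shape[1]):
        raise ValueError(f"seed {seed2d} outside slice {slice_img.shape}")
    if l <= 0:
        raise ValueError("multiplicative factor l must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")

    region = _initial_disk(slice_img.shape, seed2d)
    m_c = sigma_c = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        vals = slice_img[region]
        m_c = float(vals.mean())
        sigma_c = max(float(vals.std()), sigma_min)
        lo, hi = m_c - l * sigma_c, m_c + l * sigma_c
        frontier = ndimage.binary_dilation(region, _CROSS_2D) & ~region
        add = frontier & (slice_img >= lo) & (slice_img <= hi)
        if not add.any():
            break
        region |= add
    mask = region.astype(np.uint8)
    if return_state:
        return mask, CCRGState(region=mask, m_c=m_c, sigma_c=sigma_c, l=l, iteration=it)
    return mask


def extract_planes(vol: Volume, seed: SeedPoint) -> dict[str, np.ndarray]:
    """The axial/coronal/sagittal slices of ``vol`` through ``seed``."""
    i, j, k = seed.index
    return {
        "axial": vol.data[:, :, k],
        "coronal": vol.data[:, j, :],
        "sagittal": vol.data[i, :, :],
    }


def _plane_seed(seed: SeedPoint, plane: str) -> tuple[int, int]:
    ax_fixed, (a0, a1) = PLANES[plane]
    return (seed.index[a0], seed.index[a1])


def ccrg_sweep(
    planes: dict[str, np.ndarray],
    seed: SeedPoint,
    cfg: PipelineConfig,
    liver: LabelMask,
) -> dict[str, np.ndarray]:
    """Run the l-sweep on each orthogonal plane; return integration images.

    For each plane, `ccrg_slice` runs for each l in ``cfg.l_values``
    (ascending) and the binary masks are summed into the integration
    image.  The sweep for a plane stops early — the offending mask
    excluded and no further l run — when the grown region's area
    reaches ``liver_area_stop_frac`` of the liver area on that slice,
    or when the region centroid drifts more than ``centroid_stop_mm``
    from the seed (distances in mm through the spacing).
    """
    if not cfg.l_values:
        raise ValueError("l_values must be non-empty")
    liver_planes = extract_planes(liver, seed)
    out: dict[str, np.ndarray] = {}
    for plane, img in planes.items():
        _, (a0, a1) = PLANES[plane]
        sp = (liver.spacing[a0], liver.spacing[a1])
        seed2d = _plane_seed(seed, plane)
        liver_area = int((liver_planes[plane] > 0).sum())
        confi = np.zeros(img.shape, dtype=np.int32)
        for l in cfg.l_values:
            mask = ccrg_slice(
                img, seed2d, l, max_iter=cfg.ccrg_max_iter, sigma_min=cfg.sigma_min_hu
            )
            area = int(mask.sum())
            if liver_area > 0 and area >= cfg.liver_area_stop_frac * liver_area:
                break
            com = ndimage.center_of_mass(mask)
            drift = np.hypot((com[0] - seed2d[0]) * sp[0], (com[1] - seed2d[1]) * sp[1])
            if drift > cfg.centroid_stop_mm:
                break
            confi += mask
        out[plane] = confi
    return out


def tumor_mask_from_integration(confi: np.ndarray) -> np.ndarray:
    """Threshold an integration image at half its maximum (inclusive)."""
    confi = np.asarray(confi)
    vmax = confi.max()
    if vmax <= 0:
        raise EmptyRegionError("integration image is empty: CCRG found no region")
    return (confi >= vmax / 2).astype(np.uint8)


def _extent(mask: np.ndarray, axis: int) -> tuple[int, int] | None:
    idx = np.flatnonzero(mask.any(axis=1 - axis))
    if idx.size == 0:
        return None
    return int(idx[0]), int(idx[-1])


def compute_voi(
    masks3: dict[str, np.ndarray],
    seed: SeedPoint,
    parent: Volume,
    liver: LabelMask,
    margin_mm: float = 15.0,
) -> TumorVOI:
    """Crop the tumor VOI: 3D bounding box of the plane masks + margin.

    The box gathers x/y extents from the axial mask, x/z from the
    coronal mask, and y/z from the sagittal mask, then grows by
    ``round(margin_mm / spacing)`` voxels per axis, clipped to the
    grid.
    """
    lo = [None, None, None]
    hi = [None, None, None]

    def fold(axis3d: int, rng: tuple[int, int] | None) -> None:
        if rng is None:
            return
        lo[axis3d] = rng[0] if lo[axis3d] is None else min(lo[axis3d], rng[0])
        hi[axis3d] = rng[1] if hi[axis3d] is None else max(hi[axis3d], rng[1])

    any_mask = False
    for plane, mask in masks3.items():
        if mask is None or not np.any(mask):
            continue
        any_mask = True
        _, (a0, a1) = PLANES[plane]
        fold(a0, _extent(mask, 0))
        fold(a1, _extent(mask, 1))
    if not any_mask:
        raise EmptyRegionError("all plane masks empty: cannot place a bounding box")

    lo_v, hi_v = [], []
    for ax in range(3):
        m = int(round(margin_mm / parent.spacing[ax]))
        a = seed.index[ax] if lo[ax] is None else lo[ax]
        b = seed.index[ax] if hi[ax] is None else hi[ax]
        lo_v.append(max(0, a - m))
        hi_v.append(min(parent.size[ax], b + m + 1))
    sl = tuple(slice(a, b) for a, b in zip(lo_v, hi_v))
    offset = tuple(lo_v)
    origin = tuple(
        o + a * s for o, a, s in zip(parent.origin, lo_v, parent.spacing)
    )
    crop = Volume(parent.data[sl].copy(), spacing=parent.spacing, origin=origin)
    liver_crop = LabelMask(liver.data[sl].copy(), spacing=parent.spacing, origin=origin)
    seed_local = SeedPoint(
        index=tuple(s - o for s, o in zip(seed.index, offset)),
        intensity=seed.intensity,
    )
    return TumorVOI(
        parent_offset=offset,
        volume=crop,
        liver_mask_crop=liver_crop,
        seed_local=seed_local,
    )


def extract_tumor_voi(
    vol: Volume, liver: LabelMask, seed: SeedPoint, cfg: PipelineConfig
) -> tuple[TumorVOI, dict[str, np.ndarray]]:
    """Full VOI stage: sweep, integrate, threshold, crop.

    Returns the VOI and the per-plane tumor masks in *crop* coordinates
    (needed later as foreground seeds).
    """
    planes = extract_planes(vol, seed)
    confi = ccrg_sweep(planes, seed, cfg, liver)
    masks3 = {}
    for plane, c in confi.items():
        try:
            masks3[plane] = tumor_mask_from_integration(c)
        except EmptyRegionError:
            masks3[plane] = None
    if all(m is None for m in masks3.values()):
        raise EmptyRegionError("CCRG failed on all three planes")
    tvoi = compute_voi(masks3, seed, vol, liver, margin_mm=cfg.margin_mm)
    local_masks = {}
    for plane, mask in masks3.items():
        if mask is None:
            local_masks[plane] = None
            continue
        _, (a0, a1) = PLANES[plane]
        o0, o1 = tvoi.parent_offset[a0], tvoi.parent_offset[a1]
        n0, n1 = tvoi.volume.size[a0], tvoi.volume.size[a1]
        local_masks[plane] = mask[o0 : o0 + n0, o1 : o1 + n1]
    return tvoi, local_masks
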