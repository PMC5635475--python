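"""Postprocessing: seeded component selection, smoothing, dilation, and
resampling the final mask back to the original CT grid."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core_types import LabelMask, SeedPoint, Volume

__all__ = [
    "EmptySegmentationError",
    "select_seed_component",
    "refine_mask",
    "resample_to_original",
]

_CONN26 = ndimage.generate_binary_structure(3, 3)


class EmptySegmentationError(RuntimeError):
    """No tumor component near the seed survived segmentation."""


def select_seed_component(
    mask: LabelMask, seed: SeedPoint, search_radius_vox: int = 3
) -> LabelMask:
    """Keep only the 26-connected component containing the seed.

    If the seed voxel itself is off, the component nearest the seed
    within ``search_radius_vox`` voxels is used instead; with none in
    range the segmentation is declared empty.
    """
    data = mask.data.astype(bool)
    labels, n = ndimage.label(data, structure=_CONN26)
    if n == 0:
        raise EmptySegmentationError("segmentation mask is empty")
    target = labels[seed.index]
    if target == 0:
        on = np.argwhere(data)
        d2 = ((on - np.asarray(seed.index)) ** 2).sum(axis=1)
        if d2.min() > search_radius_vox**2:
            raise EmptySegmentationError(
                f"no tumor component within {search_radius_vox} voxels of the seed"
            )
        target = labels[tuple(on[np.argmin(d2)])]
    return mask.with_data((labels == target).astype(np.uint8))


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return xx**2 + yy**2 + zz**2 <= r**2


def refine_mask(
    mask: LabelMask, median_radius: int = 1, dilation_radius: int = 1
) -> LabelMask:
    """Binary median filter, then morphological dilation with a ball.

    Dilation compensates the min-cut's bias toward short boundaries
    (slight undersegmentation); the output always contains the
    median-filtered mask.
    """
    data = mask.data.astype(np.uint8)
    if median_radius > 0:
        size = 2 * median_radius + 1
        data = ndimage.median_filter(data, size=size, mode="constant", cval=0)
    if dilation_radius > 0:
        data = ndimage.binary_dilation(data, _ball(dilation_radius)).astype(np.uint8)
    return mask.with_data(data)


def resample_to_original(mask: LabelMask, reference: Volume) -> LabelMask:
    """Nearest-neighbor resampling of a mask onto the reference grid.

    Each reference voxel center is mapped into the mask's grid under
    the voxel-center convention; positions outside the mask grid are
    background.
    """
    grids = [
        (ref_o + np.arange(n) * ref_s - o) / s
        for n, ref_s, ref_o, s, o in zip(
            reference.size, reference.spacing, reference.origin,
            mask.spacing, mask.origin,
        )
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(
        mask.data.astype(np.float32), np.stack(coords),
        order=0, mode="constant", cval=0,
    )
    return LabelMask(
        out.astype(np.uint8), spacing=reference.spacing, origin=reference.origin
    )
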