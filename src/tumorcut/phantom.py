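"""Synthetic CT phantoms with ground-truth lesions.

Emulates the features of contrast-enhanced abdominal CT that the
pipeline exercises: a liver-like ellipsoid of moderate intensity,
hypo-intense ellipsoidal lesions with Gaussian-blurred boundaries,
additive Gaussian noise, and anisotropic voxel spacing (thick slices).
It does not model parenchymal texture, vessels, or neighboring organs.

Ground truth is the set of voxels inside the unblurred lesion
ellipsoids and is independent of the noise realization; only the CT
intensities vary with the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_types import LabelMask, SeedPoint, Volume

__all__ = ["PhantomSpec", "generate_phantom", "phantom_suite"]


@dataclass
class PhantomSpec:
    """Recipe for one synthetic CT volume.

    Lesion entries are ``(center_mm, radii_mm)`` with center relative
    to the volume origin; lesions must lie fully inside the liver.
    HU defaults follow contrast-enhanced values: liver parenchyma
    ~100 HU, hypo-intense lesions ~40 HU, and a bright out-of-liver
    background consistent with the preprocessing fill policy.
    """

    size: tuple[int, int, int] = (128, 112, 40)
    spacing: tuple[float, float, float] = (0.7, 0.7, 2.0)
    liver_hu: float = 100.0
    lesion_hu: float = 40.0
    background_hu: float = 200.0
    liver_center_mm: tuple[float, float, float] | None = None
    liver_radii_mm: tuple[float, float, float] | None = None
    lesions: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=list
    )
    edge_blur_sigma_mm: float = 1.0
    noise_sigma_hu: float = 10.0
    rng_seed: int = 0
    name: str = "phantom"

    def __post_init__(self) -> None:
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be non-negative")
        extent = tuple((n - 1) * s for n, s in zip(self.size, self.spacing))
        if self.liver_center_mm is None:
            self.liver_center_mm = tuple(e / 2 for e in extent)
        if self.liver_radii_mm is None:
            self.liver_radii_mm = tuple(0.42 * e for e in extent)
        if not self.lesions:
            self.lesions = [(self.liver_center_mm, (10.0, 10.0, 10.0))]


def _ellipsoid(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center_mm, radii_mm):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[Volume, LabelMask, LabelMask, SeedPoint]:
    """Render a phantom: (ct, liver mask, ground-truth lesion mask, seed).

    The piecewise-constant scene (background / liver / lesions) is
    blurred by a Gaussian of ``edge_blur_sigma_mm`` (softening all
    boundaries) and Gaussian noise is added.  The seed sits at the
    first lesion's center.  Deterministic for a fixed ``rng_seed``.
    """
    shape, sp = spec.size, spec.spacing
    liver = _ellipsoid(shape, sp, spec.liver_center_mm, spec.liver_radii_mm)
    ct = np.full(shape, spec.background_hu, dtype=np.float64)
    ct[liver] = spec.liver_hu
    truth = np.zeros(shape, dtype=bool)
    for center, radii in spec.lesions:
        les = _ellipsoid(shape, sp, center, radii)
        if (les & ~liver).any():
            raise ValueError(f"lesion at {center} mm extends outside the liver")
        ct[les] = spec.lesion_hu
        truth |= les
    if spec.edge_blur_sigma_mm > 0:
        sigma_vox = [spec.edge_blur_sigma_mm / s for s in sp]
        ct = ndimage.gaussian_filter(ct, sigma_vox)
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.rng_seed)
        ct = ct + rng.normal(0.0, spec.noise_sigma_hu, size=shape)
    seed_idx = tuple(
        int(np.clip(round(c / s), 0, n - 1))
        for c, s, n in zip(spec.lesions[0][0], sp, shape)
    )
    seed = SeedPoint(index=seed_idx, intensity=float(ct[seed_idx]))
    return (
        Volume(ct, spacing=sp),
        LabelMask(liver.astype(np.uint8), spacing=sp),
        LabelMask(truth.astype(np.uint8), spacing=sp),
        seed,
    )


def phantom_suite(difficulty: str = "easy") -> list[PhantomSpec]:
    """Graded test cases spanning lesion size, contrast, blur, and position.

    ``easy``: high lesion/liver contrast (60 HU), mild blur, lesions
    10-30 mm in diameter.  ``medium``: moderate contrast (40 HU), blur
    1.5-2 mm.  ``hard``: low contrast (<= 20 HU), heavy blur (>= 3 mm),
    including a lesion tangent to the liver border — the failure modes
    of low contrast and weak boundaries.
    """
    base = dict(size=(128, 112, 40), spacing=(0.7, 0.7, 2.0))
    center = tuple((n - 1) * s / 2 for n, s in zip(base["size"], base["spacing"]))
    cx, cy, cz = center

    def les(d_mm, center_mm=None):
        r = d_mm / 2.0
        return [((center_mm or center), (r, r, r))]

    if difficulty == "easy":
        return [
            PhantomSpec(**base, name="easy_d10", lesion_hu=40, liver_hu=100,
                        edge_blur_sigma_mm=0.8, noise_sigma_hu=8,
                        lesions=les(10), rng_seed=11),
            PhantomSpec(**base, name="easy_d20", lesion_hu=40, liver_hu=100,
                        edge_blur_sigma_mm=1.0, noise_sigma_hu=10,
                        lesions=les(20), rng_seed=12),
            PhantomSpec(**base, name="easy_d30", lesion_hu=35, liver_hu=100,
                        edge_blur_sigma_mm=1.0, noise_sigma_hu=10,
                        lesions=les(30), rng_seed=13),
        ]
    if difficulty == "medium":
        return [
            PhantomSpec(**base, name="medium_d15", lesion_hu=60, liver_hu=100,
                        edge_blur_sigma_mm=1.5, noise_sigma_hu=10,
                        lesions=les(15), rng_seed=21),
            PhantomSpec(**base, name="medium_d25_off", lesion_hu=60, liver_hu=100,
                        edge_blur_sigma_mm=2.0, noise_sigma_hu=10,
                        lesions=les(25, (cx - 10, cy + 8, cz)), rng_seed=22),
        ]
    if difficulty == "hard":
        # lesion tangent to the liver border along +x
        radii = tuple(0.42 * (n - 1) * s for n, s in zip(base["size"], base["spacing"]))
        tangent_center = (cx + radii[0] - 6.0, cy, cz)
        return [
            PhantomSpec(**base, name="hard_lowcontrast", lesion_hu=82, liver_hu=100,
                        edge_blur_sigma_mm=3.0, noise_sigma_hu=12,
                        lesions=les(20), rng_seed=31),
            PhantomSpec(**base, name="hard_tangent", lesion_hu=80, liver_hu=100,
                        edge_blur_sigma_mm=3.0, noise_sigma_hu=12,
                        lesions=[(tangent_center, (6.0, 6.0, 6.0))], rng_seed=32),
        ]
    raise ValueError(f"unknown difficulty {difficulty!r}")
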