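"""Shared domain types, grid conventions, and volume I/O.

Conventions used throughout the package:

* Arrays are indexed ``data[i, j, k]`` with 0-based voxel indices, ``i``
  along x (fastest), ``j`` along y, ``k`` along z.  Axial slices fix k,
  coronal slices fix j, sagittal slices fix i.
* Physical position of a voxel center is ``origin + index * spacing``
  (voxel-center convention); all distances in mm are computed through
  the spacing.
* Region masks are binary {0, 1}.  The {0, 128, 255} encoding
  (background seed / unknown / foreground seed) is confined to the
  seed-label mask consumed by the graph-cuts stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
import yaml

__all__ = [
    "Volume",
    "LabelMask",
    "SeedPoint",
    "TumorVOI",
    "PipelineConfig",
    "SEED_BACKGROUND",
    "SEED_UNKNOWN",
    "SEED_FOREGROUND",
    "read_volume",
    "write_volume",
]

#: Seed-label mask codes for the graph-cuts initialization.
SEED_BACKGROUND = 0
SEED_UNKNOWN = 128
SEED_FOREGROUND = 255

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class Volume:
    """A 3D scalar image with grid metadata.

    Parameters
    ----------
    data
        3D array, shape ``(nx, ny, nz)``.  CT intensity in HU, or
        unitless for derived maps (gradients, probabilities).
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm/voxel, strictly positive.
    origin
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def size(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume | LabelMask") -> bool:
        return (
            self.size == other.size
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        """A new Volume on the same grid carrying ``data``."""
        return Volume(data=data, spacing=self.spacing, origin=self.origin)


@dataclass
class LabelMask(Volume):
    """An integer mask on the same grid as its associated :class:`Volume`.

    Binary masks hold {0, 1}; seed-label masks hold {0, 128, 255}.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("mask data must be integer-valued")
            self.data = self.data.astype(np.uint8)

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def with_data(self, data: np.ndarray) -> "LabelMask":
        return LabelMask(data=data, spacing=self.spacing, origin=self.origin)


@dataclass(frozen=True)
class SeedPoint:
    """A user-supplied (or auto-corrected) seed voxel near the tumor center."""

    index: tuple[int, int, int]
    intensity: float = float("nan")

    def inside(self, vol: Volume) -> bool:
        return all(0 <= idx < n for idx, n in zip(self.index, vol.size))


@dataclass
class TumorVOI:
    """A cropped sub-grid around the tumor with its offset into the parent.

    ``seed_local`` maps back to the parent-grid seed under
    ``parent_offset``: ``seed_parent = seed_local + parent_offset``.
    """

    parent_offset: tuple[int, int, int]
    volume: Volume
    liver_mask_crop: LabelMask
    seed_local: SeedPoint

    def __post_init__(self) -> None:
        if not self.seed_local.inside(self.volume):
            raise ValueError("seed_local outside the cropped grid")
        if self.volume.size != self.liver_mask_crop.size:
            raise ValueError("liver_mask_crop grid differs from the cropped volume")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults.

    The defaults reflect hypo-intense lesions in contrast-enhanced CT:
    the confidence-growing sweep covers l in [1.5, 2.5], the VOI margin
    is 15 mm, the centroid drift stop is 20 mm, and the clustering
    initializes the lesion center low in the intensity distribution.
    """

    # preprocessing
    target_spacing_mm: float = 1.0
    median_radius_vox: tuple[int, int, int] = (1, 1, 1)
    fill_value_hu: float = 200.0

    # VOI extraction (confidence-connected region growing sweep)
    l_values: tuple[float, ...] = (1.5, 1.75, 2.0, 2.25, 2.5)
    ccrg_max_iter: int = 100
    centroid_stop_mm: float = 20.0
    liver_area_stop_frac: float = 0.8
    sigma_min_hu: float = 1.0
    margin_mm: float = 15.0

    # kernelized fuzzy C-means with spatial constraints
    n_clusters: int = 2
    m_f: float = 2.0
    sigma_f: float | None = None  # None -> std of VOI intensities
    p: float = 1.0
    q: float = 1.0
    nb_radius: int = 1
    kfcms_tol: float = 0.01
    kfcms_max_iter: int = 100

    # graph cuts
    gamma: float = 1.0
    lambda_: float = 0.5
    alpha_s: float = -10.0
    beta_s: float | None = None  # None -> 90th percentile of |grad|
    boundary_model: str = "additive"  # or "multiplicative"

    # postprocessing
    post_median_radius_vox: int = 1
    dilation_radius_vox: int = 1

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.l_values = tuple(sorted(float(l) for l in self.l_values))
        if not self.l_values:
            raise ValueError("l_values must be non-empty")
        if any(l < 1.5 or l > 2.5 for l in self.l_values):
            raise ValueError("l_values must lie in [1.5, 2.5]")
        if self.m_f <= 1:
            raise ValueError("fuzzifier m_f must exceed 1")
        if self.sigma_f is not None and self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.gamma < 0 or self.lambda_ < 0:
            raise ValueError("gamma and lambda must be non-negative")
        if self.boundary_model not in ("additive", "multiplicative"):
            raise ValueError(f"unknown boundary_model {self.boundary_model!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from JSON or YAML; unset fields keep defaults."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("median_radius_vox", "l_values"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            val = getattr(self, name)
            out[name] = list(val) if isinstance(val, tuple) else val
        return out

    def updated(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise IOError(
            f"unsupported image format for {path}: expected one of {_SUPPORTED_SUFFIXES}"
        )
    return path


def read_volume(path: str | Path, as_mask: bool = False) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Spacing and origin are taken from the file header; intensities are
    not modified.  With ``as_mask=True`` the result is a
    :class:`LabelMask` (integer data).
    """
    path = _check_path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
    # sitk arrays come out (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    cls = LabelMask if as_mask else Volume
    return cls(
        data=data.astype(np.uint8) if as_mask else data,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume or mask; masks are stored as 8-bit integers."""
    path = _check_path(path)
    if not path.parent.exists():
        raise IOError(f"cannot write image: no such directory {path.parent}")
    data = vol.data
    if isinstance(vol, LabelMask):
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))
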