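"""Kernelized fuzzy C-means with spatial constraints (KFCMS).

Fuzzy C-means assigns each voxel a membership in every cluster by
minimizing  J = sum_j sum_i u_ij^m ||I_j - c_i||^2.  Two modifications
make the clustering robust on noisy CT:

* the Euclidean distance is replaced by a Gaussian kernel-induced
  distance, 1 - K(I, c) with K(I, c) = exp(-(I - c)^2 / (2 sigma_f^2));
* memberships are refined by the spatial function
  h_ij = sum over the neighborhood of voxel j of u_ik, blended as
  u'_ij = u_ij^p h_ij^q / sum_k u_kj^p h_kj^q,
  which pulls isolated noisy voxels toward their neighborhood's tissue.

Cluster centers are then re-estimated with kernel weighting,
c_i = sum_j u'_ij^m K(I_j, c_i) I_j / sum_j u'_ij^m K(I_j, c_i),
and the loop (memberships -> spatial refinement -> centers) repeats
until the largest center movement falls below a tolerance.

The resulting per-cluster memberships act as the probabilistic models
of lesion and liver tissue consumed by the graph-cuts region term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_types import SeedPoint, TumorVOI, Volume

__all__ = [
    "KFCMSParams",
    "MembershipMatrix",
    "DegenerateModelError",
    "gaussian_kernel",
    "kernel_membership",
    "spatial_function",
    "spatial_refine",
    "update_centers",
    "kfcms_fit",
    "kfcms_run",
    "probability_maps",
]


class DegenerateModelError(RuntimeError):
    """The clustering problem is degenerate (e.g. constant intensities)."""


@dataclass
class KFCMSParams:
    """Tunable parameters of the KFCMS loop.

    ``sigma_f=None`` adapts the kernel width to the data (standard
    deviation of the VOI intensities).  The percentile initialization
    places the lesion center low in the intensity distribution,
    matching hypo-intense tumors; ``rng_seed`` is consumed only when
    ``init='random'``.
    """

    n_clusters: int = 2
    m_f: float = 2.0
    sigma_f: float | None = None
    p: float = 1.0
    q: float = 1.0
    nb_radius: int = 1
    tol: float = 0.01
    max_iter: int = 100
    init: str = "percentile"  # or "random"
    init_centers: tuple[float, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.m_f <= 1:
            raise ValueError("m_f must exceed 1")
        if self.sigma_f is not None and self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        if self.p < 0 or self.q < 0:
            raise ValueError("p and q must be non-negative")
        if self.nb_radius < 0:
            raise ValueError("nb_radius must be non-negative")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")


@dataclass
class MembershipMatrix:
    """Per-voxel, per-cluster fuzzy memberships plus the cluster centers.

    ``u`` has shape (n_clusters, *grid_shape); each voxel's memberships
    sum to 1.  Centers are sorted ascending in HU.
    """

    u: np.ndarray
    centers: np.ndarray
    n_iter: int = 0
    converged: bool = True
    grid_shape: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.grid_shape is None:
            self.grid_shape = self.u.shape[1:]


def gaussian_kernel(I, c, sigma_f: float):
    """Gaussian similarity K(I, c) = exp(-(I - c)^2 / (2 sigma_f^2)), in (0, 1]."""
    if sigma_f <= 0:
        raise ValueError("sigma_f must be positive")
    I = np.asarray(I, dtype=np.float64)
    return np.exp(-((I - c) ** 2) / (2.0 * sigma_f**2))


def kernel_membership(I, centers, m_f: float, sigma_f: float) -> np.ndarray:
    """Kernel-distance memberships, shape (n_clusters,) + I.shape.

    u_ij = (1 - K(I_j, c_i))^(-1/(m_f-1)) / sum_k (1 - K(I_j, c_k))^(-1/(m_f-1)).

    A voxel whose intensity equals a center exactly gets crisp
    membership in that cluster (the limit of the formula as the kernel
    distance vanishes).
    """
    centers = np.asarray(centers, dtype=np.float64)
    if centers.size < 2 or np.unique(centers).size < 2:
        raise DegenerateModelError(f"need >= 2 distinct centers, got {centers}")
    I = np.asarray(I, dtype=np.float64)
    d = np.stack([1.0 - gaussian_kernel(I, c, sigma_f) for c in centers])
    exact = d <= 0.0
    any_exact = exact.any(axis=0)
    with np.errstate(divide="ignore", over="ignore"):
        w = d ** (-1.0 / (m_f - 1.0))
    u = np.empty_like(d)
    np.divide(w, w.sum(axis=0), out=u, where=~any_exact)
    if any_exact.any():
        crisp = exact[:, any_exact]
        u[:, any_exact] = crisp / crisp.sum(axis=0)
    return u


def spatial_function(u: np.ndarray, nb_radius: int) -> np.ndarray:
    """h_ij: sum of cluster-i memberships over each voxel's neighborhood.

    The window is the (2r+1)^d box around each voxel, clipped at the
    grid border.  ``u`` has shape (n_clusters, *grid_shape).
    """
    if nb_radius == 0:
        return u.copy()
    size = (1,) + (2 * nb_radius + 1,) * (u.ndim - 1)
    kernel = np.ones(size)
    return ndimage.convolve(u, kernel, mode="constant", cval=0.0)


def spatial_refine(u: np.ndarray, h: np.ndarray, p: float, q: float) -> np.ndarray:
    """Blend memberships with the spatial function:
    u'_ij = u_ij^p h_ij^q / sum_k u_kj^p h_kj^q.

    With p=1, q=0 the refinement is the identity.
    """
    with np.errstate(invalid="ignore"):
        num = u**p * h**q
    den = num.sum(axis=0)
    bad = ~(den > 0)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise DegenerateModelError(
            f"zero spatial-refinement denominator at voxel {tuple(int(x) for x in idx)}"
        )
    return num / den


def update_centers(
    u_ref: np.ndarray, I: np.ndarray, centers: np.ndarray, m_f: float, sigma_f: float
) -> np.ndarray:
    """Kernel-weighted center update (convex combination of intensities)."""
    I = np.asarray(I, dtype=np.float64)
    new = np.empty(len(centers))
    for i, c in enumerate(centers):
        w = u_ref[i] ** m_f * gaussian_kernel(I, c, sigma_f)
        den = w.sum()
        if den <= 0:
            raise DegenerateModelError(f"cluster {i} has zero total weight")
        new[i] = float((w * I).sum() / den)
    return new


def _init_centers(I: np.ndarray, params: KFCMSParams) -> np.ndarray:
    if params.init_centers is not None:
        if len(params.init_centers) != params.n_clusters:
            raise ValueError("init_centers length must equal n_clusters")
        return np.asarray(params.init_centers, dtype=np.float64)
    if params.init == "random":
        rng = np.random.default_rng(params.rng_seed)
        return np.sort(rng.choice(I.ravel(), size=params.n_clusters, replace=False))
    # percentile init: lesion low, parenchyma mid, optional bright cluster
    if params.n_clusters == 2:
        pct = [10, 60]
    else:
        pct = list(np.linspace(10, 90, params.n_clusters))
    return np.percentile(I, pct)


def kfcms_fit(data: np.ndarray, params: KFCMSParams) -> MembershipMatrix:
    """Run the KFCMS loop on an intensity array of any shape.

    Iterates kernel memberships -> spatial function -> spatial
    refinement -> center update until the largest center movement is
    below ``params.tol`` (HU) or ``params.max_iter`` is reached.
    Centers (and membership rows) are returned sorted ascending.
    """
    I = np.asarray(data, dtype=np.float64)
    if np.unique(I).size < params.n_clusters:
        raise DegenerateModelError(
            f"fewer distinct intensities than clusters ({params.n_clusters})"
        )
    sigma_f = params.sigma_f if params.sigma_f is not None else float(I.std())
    if sigma_f <= 0:
        raise DegenerateModelError("zero intensity spread")
    centers = np.asarray(_init_centers(I, params), dtype=np.float64)
    if np.unique(centers).size < params.n_clusters:
        # percentiles collapsed (heavily quantized data): spread them
        lo, hi = I.min(), I.max()
        centers = np.linspace(lo, hi, params.n_clusters)
    u_ref = None
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        u = kernel_membership(I, centers, params.m_f, sigma_f)
        h = spatial_function(u, params.nb_radius)
        u_ref = spatial_refine(u, h, params.p, params.q)
        new_centers = update_centers(u_ref, I, centers, params.m_f, sigma_f)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"KFCMS did not converge in {params.max_iter} iterations", RuntimeWarning
        )
    order = np.argsort(centers)
    return MembershipMatrix(
        u=u_ref[order], centers=centers[order], n_iter=it, converged=converged
    )


def kfcms_run(voi: TumorVOI, params: KFCMSParams) -> MembershipMatrix:
    """KFCMS over the tumor VOI intensities (3D neighborhoods)."""
    return kfcms_fit(voi.volume.data, params)


def probability_maps(
    m: MembershipMatrix, seed: SeedPoint, seed_intensity: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split memberships into lesion / background probability maps.

    The lesion cluster is the one whose center is closest to the
    (corrected) seed intensity; all other clusters pool into the
    background.  P_fg + P_bkg = 1 voxelwise.
    """
    si = seed_intensity if seed_intensity is not None else seed.intensity
    if not np.isfinite(si):
        raise ValueError("seed intensity unknown; pass seed_intensity")
    lesion = int(np.argmin(np.abs(m.centers - si)))
    p_fg = m.u[lesion]
    p_bkg = np.delete(m.u, lesion, axis=0).sum(axis=0)
    return p_fg, p_bkg
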