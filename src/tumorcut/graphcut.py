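"""Graph-cuts segmentation of the tumor VOI.

The VOI is mapped onto a flow network: every voxel is a node, plus two
terminals — the sink T standing for the foreground (tumor) seeds and
the source S for the background seeds.  t-links encode the region term
(seed hard constraints and the KFCMS probability maps), n-links between
6-connected neighbors encode the boundary term, which combines the
inverse squared intensity difference with a sigmoid-mapped gradient
magnitude.  The minimum s-t cut yields the labeling minimizing

    E(f) = sum_v R(f_v) + gamma * sum_(v,u) B(f_v, f_u) * [f_v != f_u].

Infinite seed capacities are encoded as a finite LARGE constant
exceeding the sum of all finite capacities, so no minimum cut ever
severs a seed t-link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .core_types import (
    SEED_BACKGROUND,
    SEED_FOREGROUND,
    SEED_UNKNOWN,
    LabelMask,
    PipelineConfig,
    SeedPoint,
    TumorVOI,
    Volume,
)

__all__ = [
    "SigmoidParams",
    "GraphSpec",
    "SeedingError",
    "sigmoid_gradient",
    "build_seed_mask",
    "region_capacities",
    "boundary_capacity",
    "build_graph",
    "mincut_segment",
    "labeling_energy",
    "segment_voi",
]


class SeedingError(RuntimeError):
    """Seed-mask construction produced no usable foreground/background."""


@dataclass(frozen=True)
class SigmoidParams:
    """Window of the sigmoid gradient map: alpha_s is the width (sign
    meaningful: negative maps strong edges toward 0), beta_s the center."""

    alpha_s: float
    beta_s: float

    def __post_init__(self) -> None:
        if self.alpha_s == 0:
            raise ValueError("alpha_s must be nonzero")


@dataclass
class GraphSpec:
    """A flat description of the segmentation flow network.

    Voxels are flattened in C order over the VOI grid.  ``np.inf``
    entries in the t-link capacities mark seed hard constraints; they
    are replaced by a finite LARGE constant when the solver graph is
    assembled.
    """

    shape: tuple[int, int, int]
    cap_sink: np.ndarray  # (N,) voxel -> T (foreground terminal)
    cap_source: np.ndarray  # (N,) S -> voxel (background terminal)
    n_edges: np.ndarray  # (M, 2) flat voxel index pairs
    n_caps: np.ndarray  # (M,) symmetric n-link capacities (gamma applied)

    def __post_init__(self) -> None:
        n = int(np.prod(self.shape))
        if self.cap_sink.shape != (n,) or self.cap_source.shape != (n,):
            raise ValueError("t-link capacity arrays must have one entry per voxel")
        if (self.n_caps < 0).any():
            raise ValueError("n-link capacities must be non-negative")
        finite = np.concatenate(
            [
                self.cap_sink[np.isfinite(self.cap_sink)],
                self.cap_source[np.isfinite(self.cap_source)],
                self.n_caps,
            ]
        )
        self.large = float(finite.sum()) + 1.0


def sigmoid_gradient(voi: Volume, params: SigmoidParams) -> Volume:
    """Sigmoid-mapped gradient magnitude, I_sg in (0, 1).

    The gradient is the spacing-aware central difference; its Euclidean
    norm I_g is passed through
    ``I_sg = (1 + exp(-(I_g - beta_s)/alpha_s))^{-1}``.
    """
    grads = np.gradient(voi.data.astype(np.float64), *voi.spacing)
    ig_mag = np.sqrt(sum(g**2 for g in grads))
    isg = 1.0 / (1.0 + np.exp(-(ig_mag - params.beta_s) / params.alpha_s))
    return voi.with_data(isg)


def gradient_magnitude(voi: Volume) -> np.ndarray:
    grads = np.gradient(voi.data.astype(np.float64), *voi.spacing)
    return np.sqrt(sum(g**2 for g in grads))


def build_seed_mask(
    voi: TumorVOI, ccrg_masks: dict[str, np.ndarray | None], liver_crop: LabelMask
) -> LabelMask:
    """Foreground/background seed labels {255, 0} over the VOI, 128 elsewhere.

    Foreground (255): voxels covered by a plane's CCRG tumor mask on
    that plane's slice through the seed.  Background (0): voxels
    outside the liver or lying on a face of the VOI box.  Conflicts
    resolve to background, so the two seed sets stay disjoint.
    """
    shape = voi.volume.size
    labels = np.full(shape, SEED_UNKNOWN, dtype=np.uint8)
    i, j, k = voi.seed_local.index
    fg = np.zeros(shape, dtype=bool)
    placements = {"axial": (slice(None), slice(None), k),
                  "coronal": (slice(None), j, slice(None)),
                  "sagittal": (i, slice(None), slice(None))}
    for plane, sl in placements.items():
        mask = ccrg_masks.get(plane)
        if mask is not None:
            fg[sl] |= mask.astype(bool)
    labels[fg] = SEED_FOREGROUND
    bg = liver_crop.data == 0
    face = np.zeros(shape, dtype=bool)
    for ax in range(3):
        face[tuple(0 if a == ax else slice(None) for a in range(3))] = True
        face[tuple(-1 if a == ax else slice(None) for a in range(3))] = True
    bg |= face
    labels[bg] = SEED_BACKGROUND  # background wins conflicts
    if not (labels == SEED_FOREGROUND).any():
        raise SeedingError("no foreground seed voxel")
    if not (labels == SEED_BACKGROUND).any():
        raise SeedingError("no background seed voxel")
    return LabelMask(
        labels, spacing=voi.volume.spacing, origin=voi.volume.origin
    )


def region_capacities(
    seed_labels: np.ndarray, p_fg: np.ndarray, p_bkg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Region-term t-link capacities.

    Returns ``(cap_to_T, cap_to_S)``: infinite toward the matching
    terminal for seeds, and the probability maps for unknown voxels.
    Cutting the T-link of a voxel assigns it to the background, so its
    price is P_fg (and symmetrically for the S-link).
    """
    cap_t = np.where(
        seed_labels == SEED_FOREGROUND,
        np.inf,
        np.where(seed_labels == SEED_BACKGROUND, 0.0, p_fg),
    )
    cap_s = np.where(
        seed_labels == SEED_BACKGROUND,
        np.inf,
        np.where(seed_labels == SEED_FOREGROUND, 0.0, p_bkg),
    )
    return cap_t, cap_s


def boundary_capacity(
    I_v, I_u, I_sg_edge, lambda_: float, model: str = "additive"
):
    """Boundary penalty between neighboring voxels.

    ``additive``:        ((I_v - I_u)^2 + 1)^-1 + lambda * I_sg
    ``multiplicative``:  ((I_v - I_u)^2 + 1)^-1 * (1 + lambda * I_sg)^-1

    ``I_sg_edge`` is the sigmoid gradient evaluated at the edge (mean
    of the two endpoint values).  With a negative sigmoid width,
    strong edges carry a small I_sg, making additive capacities cheap
    to cut across true boundaries.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    base = 1.0 / ((np.asarray(I_v, dtype=np.float64) - np.asarray(I_u)) ** 2 + 1.0)
    if model == "additive":
        return base + lambda_ * np.asarray(I_sg_edge, dtype=np.float64)
    if model == "multiplicative":
        return base / (1.0 + lambda_ * np.asarray(I_sg_edge, dtype=np.float64))
    raise ValueError(f"unknown boundary model {model!r}")


def _neighbor_pairs(shape: tuple[int, int, int]) -> np.ndarray:
    """(M, 2) flat-index pairs of all 6-connected neighbors (each once)."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    pairs = []
    for ax in range(3):
        a = np.moveaxis(idx, ax, 0)
        pairs.append(np.stack([a[:-1].ravel(), a[1:].ravel()], axis=1))
    return np.concatenate(pairs, axis=0)


def build_graph(
    voi: Volume,
    seed_labels: LabelMask,
    p_fg: np.ndarray,
    p_bkg: np.ndarray,
    isg: Volume,
    cfg: PipelineConfig,
) -> GraphSpec:
    """Assemble t-link and n-link capacities for the VOI."""
    shape = voi.size
    cap_t, cap_s = region_capacities(
        seed_labels.data.ravel(), p_fg.ravel(), p_bkg.ravel()
    )
    pairs = _neighbor_pairs(shape)
    I = voi.data.astype(np.float64).ravel()
    sg = isg.data.ravel()
    sg_edge = 0.5 * (sg[pairs[:, 0]] + sg[pairs[:, 1]])
    caps = cfg.gamma * boundary_capacity(
        I[pairs[:, 0]], I[pairs[:, 1]], sg_edge, cfg.lambda_, cfg.boundary_model
    )
    return GraphSpec(
        shape=shape, cap_sink=cap_t, cap_source=cap_s, n_edges=pairs, n_caps=caps
    )


def mincut_segment(graph: GraphSpec) -> tuple[np.ndarray, float]:
    """Solve the min-cut; returns (binary labeling on the grid, cut value).

    Label 1 = foreground (sink side), 0 = background (source side).
    The reported cut value excludes any LARGE seed placeholders (a
    valid cut never severs one).
    """
    n = int(np.prod(graph.shape))
    if n == 0:
        raise ValueError("empty graph")
    src, snk = n, n + 1
    cap_t = np.where(np.isfinite(graph.cap_sink), graph.cap_sink, graph.large)
    cap_s = np.where(np.isfinite(graph.cap_source), graph.cap_source, graph.large)
    edges = np.concatenate(
        [
            graph.n_edges,
            np.stack([np.full(n, src), np.arange(n)], axis=1),
            np.stack([np.arange(n), np.full(n, snk)], axis=1),
        ]
    )
    caps = np.concatenate([graph.n_caps, cap_s, cap_t])
    keep = caps > 0
    g = ig.Graph(n + 2, list(map(tuple, edges[keep])))
    cut = g.st_mincut(src, snk, capacity=list(caps[keep]))
    labels = np.zeros(n, dtype=np.uint8)
    sink_side = [v for v in cut.partition[1] if v < n]
    if snk in cut.partition[0]:
        sink_side = [v for v in cut.partition[0] if v < n]
    labels[sink_side] = 1
    return labels.reshape(graph.shape), float(cut.value)


def labeling_energy(graph: GraphSpec, labels: np.ndarray) -> float:
    """Energy of a labeling under the region + boundary terms.

    Independent of the solver: sums the severed t-link capacities (a
    foreground voxel pays its S-link, a background voxel its T-link)
    and the n-link capacities between differently labeled neighbors.
    Infinite if a seed constraint is violated.
    """
    lab = labels.ravel().astype(bool)
    e_t = np.where(lab, graph.cap_source, graph.cap_sink)
    cut_n = lab[graph.n_edges[:, 0]] != lab[graph.n_edges[:, 1]]
    return float(e_t.sum() + graph.n_caps[cut_n].sum())


def segment_voi(
    voi: TumorVOI,
    cfg: PipelineConfig,
    ccrg_masks: dict[str, np.ndarray | None] | None = None,
) -> tuple[LabelMask, dict]:
    """Full graph-cuts stage on a tumor VOI.

    Composes seed-mask construction, KFCMS probability maps, the
    sigmoid gradient, graph assembly (6-connectivity), and the min-cut.
    ``ccrg_masks`` are the per-plane tumor masks in VOI coordinates; if
    omitted, the confidence-connected sweep is re-run inside the VOI.
    Returns the binary tumor mask on the VOI grid and a diagnostics
    dict (centers, iterations, cut energy).
    """
    from . import kfcms as _kfcms
    from . import voi as _voi

    if ccrg_masks is None:
        planes = _voi.extract_planes(voi.volume, voi.seed_local)
        confi = _voi.ccrg_sweep(planes, voi.seed_local, cfg, voi.liver_mask_crop)
        ccrg_masks = {}
        for plane, c in confi.items():
            try:
                ccrg_masks[plane] = _voi.tumor_mask_from_integration(c)
            except _voi.EmptyRegionError:
                ccrg_masks[plane] = None

    seed_labels = build_seed_mask(voi, ccrg_masks, voi.liver_mask_crop)
    # seed-informed initialization: the lesion center starts at the
    # (corrected, hence locally darkest) seed intensity, the parenchyma
    # center at the median of liver voxels in the VOI; extra clusters
    # start high to absorb bright/partial-volume voxels.
    seed_int = float(voi.volume.data[voi.seed_local.index])
    in_liver = voi.volume.data[voi.liver_mask_crop.data > 0]
    liver_med = float(np.median(in_liver)) if in_liver.size else float(
        np.median(voi.volume.data)
    )
    init = [seed_int, liver_med]
    if cfg.n_clusters > 2:
        extra = np.linspace(liver_med, float(voi.volume.data.max()), cfg.n_clusters)[2:]
        init += [float(x) for x in extra]
    params = _kfcms.KFCMSParams(
        n_clusters=cfg.n_clusters,
        m_f=cfg.m_f,
        sigma_f=cfg.sigma_f,
        p=cfg.p,
        q=cfg.q,
        nb_radius=cfg.nb_radius,
        tol=cfg.kfcms_tol,
        max_iter=cfg.kfcms_max_iter,
        init_centers=tuple(init),
        rng_seed=cfg.rng_seed,
    )
    membership = _kfcms.kfcms_run(voi, params)
    p_fg, p_bkg = _kfcms.probability_maps(
        membership, voi.seed_local, seed_intensity=seed_int
    )
    grad = gradient_magnitude(voi.volume)
    beta = cfg.beta_s if cfg.beta_s is not None else float(np.percentile(grad, 90))
    isg = sigmoid_gradient(voi.volume, SigmoidParams(cfg.alpha_s, beta))
    graph = build_graph(voi.volume, seed_labels, p_fg, p_bkg, isg, cfg)
    labels, cut_value = mincut_segment(graph)
    mask = LabelMask(labels, spacing=voi.volume.spacing, origin=voi.volume.origin)
    info = {
        "centers": membership.centers.tolist(),
        "kfcms_iterations": membership.n_iter,
        "kfcms_converged": membership.converged,
        "cut_energy": cut_value,
        "beta_s": beta,
        "n_foreground_seeds": int((seed_labels.data == SEED_FOREGROUND).sum()),
        "n_background_seeds": int((seed_labels.data == SEED_BACKGROUND).sum()),
    }
    return mask, info
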