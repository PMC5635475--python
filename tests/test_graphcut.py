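import itertools

import numpy as np
import pytest

from tumorcut.core_types import (
    SEED_BACKGROUND,
    SEED_FOREGROUND,
    SEED_UNKNOWN,
    LabelMask,
    PipelineConfig,
    SeedPoint,
    TumorVOI,
    Volume,
)
from tumorcut.graphcut import (
    GraphSpec,
    SeedingError,
    SigmoidParams,
    _neighbor_pairs,
    boundary_capacity,
    build_seed_mask,
    labeling_energy,
    mincut_segment,
    region_capacities,
    segment_voi,
    sigmoid_gradient,
)


def brute_force_mincut(graph: GraphSpec):
    """Independent oracle: exhaustive enumeration over unknown voxels."""
    n = int(np.prod(graph.shape))
    fg_seed = np.isinf(graph.cap_sink)
    bg_seed = np.isinf(graph.cap_source)
    free = np.flatnonzero(~fg_seed & ~bg_seed)
    best_e, best_lab = np.inf, None
    for bits in itertools.product([0, 1], repeat=len(free)):
        lab = fg_seed.astype(np.uint8).copy()
        lab[free] = bits
        e = finite_energy(graph, lab)
        if e < best_e:
            best_e, best_lab = e, lab
    return best_e, best_lab.reshape(graph.shape)


def finite_energy(graph: GraphSpec, flat_labels):
    lab = np.asarray(flat_labels).ravel().astype(bool)
    e_t = np.where(lab, graph.cap_source, graph.cap_sink)
    e_t = np.where(np.isinf(e_t), 0.0, e_t)  # seeds respect their side
    cut = lab[graph.n_edges[:, 0]] != lab[graph.n_edges[:, 1]]
    return float(e_t.sum() + graph.n_caps[cut].sum())


def random_graph(rng, shape=(3, 3, 1), n_fg=1, n_bg=1, dyadic=True):
    n = int(np.prod(shape))
    def caps(size):
        c = rng.integers(0, 64, size) / 64.0 if dyadic else rng.random(size)
        return c.astype(np.float64)
    cap_t, cap_s = caps(n), caps(n)
    picks = rng.choice(n, size=n_fg + n_bg, replace=False)
    cap_t[picks[:n_fg]] = np.inf
    cap_s[picks[:n_fg]] = 0.0
    cap_s[picks[n_fg:]] = np.inf
    cap_t[picks[n_fg:]] = 0.0
    pairs = _neighbor_pairs(shape)
    return GraphSpec(shape, cap_t, cap_s, pairs, caps(len(pairs)))


class TestSigmoid:
    def test_midpoint_width_and_asymptote(self):
        vol = Volume(np.zeros((5, 5, 5)))
        # gradient of a constant volume is 0 everywhere
        params = SigmoidParams(alpha_s=-10.0, beta_s=0.0)
        out = sigmoid_gradient(vol, params)
        np.testing.assert_allclose(out.data, 0.5)
        # closed forms on the scalar map
        s = lambda g, a, b: 1.0 / (1.0 + np.exp(-(g - b) / a))
        assert s(20.0, 10.0, 10.0) == pytest.approx(1 / (1 + np.exp(-1)))
        assert s(1e4, -10.0, 50.0) < 1e-6  # strong edges -> 0 for alpha<0
        with pytest.raises(ValueError):
            SigmoidParams(alpha_s=0.0, beta_s=1.0)

    def test_gradient_is_spacing_aware(self):
        # ramp along z with value = 3 * z_mm: gradient magnitude 3 everywhere
        nz = 10
        data = np.broadcast_to(np.arange(nz) * 6.0, (4, 4, nz)).copy()
        vol = Volume(data, spacing=(1.0, 1.0, 2.0))
        out = sigmoid_gradient(vol, SigmoidParams(alpha_s=1.0, beta_s=3.0))
        np.testing.assert_allclose(out.data, 0.5, atol=1e-12)


class TestSeedMask:
    def _voi(self, shape=(8, 8, 8), liver=None):
        vol = Volume(np.zeros(shape))
        if liver is None:
            liver = np.ones(shape, dtype=np.uint8)
        mask = LabelMask(liver)
        return TumorVOI((0, 0, 0), vol, mask, SeedPoint(index=(4, 4, 4)))

    def test_interior_lesion_layout(self):
        voi = self._voi()
        ax = np.zeros((8, 8), dtype=np.uint8)
        ax[3:6, 3:6] = 1
        labels = build_seed_mask(voi, {"axial": ax}, voi.liver_mask_crop).data
        assert (labels[3:6, 3:6, 4] == SEED_FOREGROUND).all()
        assert (labels[0, :, :] == SEED_BACKGROUND).all()  # VOI face
        assert labels[3, 3, 2] == SEED_UNKNOWN
        # foreground and background sets disjoint by construction
        assert ((labels == SEED_FOREGROUND) & (labels == SEED_BACKGROUND)).sum() == 0

    def test_face_conflict_resolves_to_background(self):
        voi = self._voi()
        ax = np.ones((8, 8), dtype=np.uint8)  # CCRG mask touching the faces
        labels = build_seed_mask(voi, {"axial": ax}, voi.liver_mask_crop).data
        assert labels[0, 4, 4] == SEED_BACKGROUND
        assert labels[4, 4, 4] == SEED_FOREGROUND

    def test_outside_liver_is_background(self):
        liver = np.ones((8, 8, 8), dtype=np.uint8)
        liver[:, :, 6:] = 0
        voi = self._voi(liver=liver)
        ax = np.zeros((8, 8), dtype=np.uint8)
        ax[3:6, 3:6] = 1
        labels = build_seed_mask(voi, {"axial": ax}, voi.liver_mask_crop).data
        assert (labels[:, :, 6:] == SEED_BACKGROUND).all()

    def test_empty_ccrg_masks_error(self):
        voi = self._voi()
        with pytest.raises(SeedingError):
            build_seed_mask(
                voi, {"axial": np.zeros((8, 8), dtype=np.uint8)}, voi.liver_mask_crop
            )


class TestCapacities:
    def test_region_seed_rows_and_passthrough(self):
        labels = np.array([SEED_FOREGROUND, SEED_BACKGROUND, SEED_UNKNOWN])
        p_fg = np.array([0.9, 0.9, 0.7])
        p_bkg = np.array([0.1, 0.1, 0.3])
        cap_t, cap_s = region_capacities(labels, p_fg, p_bkg)
        assert np.isinf(cap_t[0]) and cap_s[0] == 0.0
        assert cap_t[1] == 0.0 and np.isinf(cap_s[1])
        assert cap_t[2] == 0.7 and cap_s[2] == 0.3

    def test_boundary_closed_forms(self):
        assert boundary_capacity(5.0, 5.0, 0.0, 0.5) == 1.0
        assert boundary_capacity(3.0, 0.0, 0.7, 0.0) == pytest.approx(1 / 10)
        assert boundary_capacity(50.0, 52.0, 0.2, 0.5) == pytest.approx(0.3)
        assert boundary_capacity(50.0, 52.0, 0.2, 0.5, "multiplicative") == pytest.approx(
            (1 / 5) / 1.1
        )
        with pytest.raises(ValueError):
            boundary_capacity(1.0, 2.0, 0.1, -1.0)
        with pytest.raises(ValueError):
            boundary_capacity(1.0, 2.0, 0.1, 1.0, "nope")


class TestMinCut:
    def test_single_unknown_voxel_dominant_tlink(self):
        g = GraphSpec(
            (1, 1, 1),
            cap_sink=np.array([0.9]),
            cap_source=np.array([0.1]),
            n_edges=np.empty((0, 2), dtype=int),
            n_caps=np.empty(0),
        )
        labels, value = mincut_segment(g)
        assert labels[0, 0, 0] == 1  # cheaper to cut the source link
        assert value == pytest.approx(0.1)

    def test_chain_flips_with_nlink_strength(self):
        # fg seed - unknown - bg seed; the unknown follows the stronger pull
        # labeling the unknown fg costs cap_s + 0.01; labeling it bg costs
        # cap_t + w -> flips to fg once w exceeds cap_s - cap_t + 0.01
        for w, expect in [(0.05, 0), (2.0, 1), (0.0, 0)]:
            cap_t = np.array([np.inf, 0.1, 0.0])
            cap_s = np.array([0.0, 0.6, np.inf])
            pairs = np.array([[0, 1], [1, 2]])
            g = GraphSpec((3, 1, 1), cap_t, cap_s, pairs, np.array([w, 0.01]))
            labels, value = mincut_segment(g)
            ref_e, ref_lab = brute_force_mincut(g)
            assert value == pytest.approx(ref_e, abs=1e-12)
            assert labels[1, 0, 0] == ref_lab[1, 0, 0] == expect

    @pytest.mark.parametrize("shape,n_seeds", [((3, 3, 1), (1, 1)), ((4, 2, 2), (1, 1)),
                                               ((3, 3, 2), (2, 2))])
    def test_matches_bruteforce_on_random_graphs(self, shape, n_seeds):
        rng = np.random.default_rng(123)
        for _ in range(8):
            g = random_graph(rng, shape, *n_seeds)
            labels, value = mincut_segment(g)
            ref_e, _ = brute_force_mincut(g)
            assert value == pytest.approx(ref_e, abs=1e-9)
            assert finite_energy(g, labels) == pytest.approx(ref_e, abs=1e-9)

    def test_cut_value_equals_labeling_energy(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, (4, 3, 2), 2, 2, dyadic=False)
        labels, value = mincut_segment(g)
        assert labeling_energy(g, labels) == pytest.approx(value, abs=1e-9)

    def test_hard_constraints_respected(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, (3, 3, 3), 3, 3)
        labels, _ = mincut_segment(g)
        flat = labels.ravel()
        assert (flat[np.isinf(g.cap_sink)] == 1).all()
        assert (flat[np.isinf(g.cap_source)] == 0).all()

    def test_monotone_in_sink_capacity(self):
        # raising an unknown voxel's T-link never flips it fg -> bg
        rng = np.random.default_rng(11)
        g = random_graph(rng, (3, 3, 1), 1, 1)
        free = np.flatnonzero(~np.isinf(g.cap_sink) & ~np.isinf(g.cap_source))
        v = int(free[0])
        prev = None
        for boost in [0.0, 0.3, 0.8, 2.0]:
            g2 = GraphSpec(g.shape, g.cap_sink.copy(), g.cap_source.copy(),
                           g.n_edges, g.n_caps.copy())
            g2.cap_sink[v] += boost
            lab, _ = mincut_segment(g2)
            cur = int(lab.ravel()[v])
            if prev is not None:
                assert cur >= prev
            prev = cur


class TestSegmentVOI:
    def _lesion_voi(self, rng_seed=0):
        shape = (24, 24, 24)
        rng = np.random.default_rng(rng_seed)
        ii, jj, kk = np.ogrid[:24, :24, :24]
        inside = (ii - 12) ** 2 + (jj - 12) ** 2 + (kk - 12) ** 2 <= 36
        data = np.where(inside, 40.0, 100.0) + rng.normal(0, 4, shape)
        voi = TumorVOI(
            (0, 0, 0),
            Volume(data),
            LabelMask(np.ones(shape, dtype=np.uint8)),
            SeedPoint(index=(12, 12, 12), intensity=40.0),
        )
        return voi, inside

    def test_mask_contains_fg_seeds_excludes_bg(self):
        voi, inside = self._lesion_voi()
        cfg = PipelineConfig()
        mask, info = segment_voi(voi, cfg)
        assert info["n_foreground_seeds"] > 0
        data = mask.data.astype(bool)
        assert data[12, 12, 12]
        assert not data[0, 0, 0]  # VOI face is a background seed
        # close to the true sphere
        dice = 2 * (data & inside).sum() / (data.sum() + inside.sum())
        assert dice > 0.85

    def test_deterministic_rerun(self):
        voi, _ = self._lesion_voi()
        cfg = PipelineConfig()
        m1, i1 = segment_voi(voi, cfg)
        m2, i2 = segment_voi(voi, cfg)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert i1["cut_energy"] == i2["cut_energy"]

    def test_both_boundary_models_run(self):
        voi, inside = self._lesion_voi()
        for model in ("additive", "multiplicative"):
            mask, _ = segment_voi(voi, PipelineConfig(boundary_model=model))
            data = mask.data.astype(bool)
            dice = 2 * (data & inside).sum() / (data.sum() + inside.sum())
            assert dice > 0.8
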