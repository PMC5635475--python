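import numpy as np
import pytest

from tumorcut.core_types import LabelMask, SeedPoint, TumorVOI, Volume
from tumorcut.kfcms import (
    DegenerateModelError,
    KFCMSParams,
    gaussian_kernel,
    kernel_membership,
    kfcms_fit,
    kfcms_run,
    probability_maps,
    spatial_function,
    spatial_refine,
    update_centers,
)


class TestKernel:
    def test_closed_forms(self):
        assert gaussian_kernel(50.0, 50.0, 30.0) == 1.0
        assert gaussian_kernel(80.0, 50.0, 30.0) == pytest.approx(np.exp(-0.5))
        assert gaussian_kernel(40.0, 100.0, 30.0) == pytest.approx(np.exp(-2.0))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        I, c = rng.normal(0, 100, 50), 12.0
        k = gaussian_kernel(I, c, 25.0)
        assert ((0 < k) & (k <= 1)).all()
        np.testing.assert_allclose(k, gaussian_kernel(np.full(50, c), I, 25.0))
        with pytest.raises(ValueError):
            gaussian_kernel(1.0, 2.0, 0.0)


class TestKernelMembership:
    def test_exact_hit_is_crisp(self):
        u = kernel_membership(np.array([40.0]), [40.0, 100.0], 2.0, 30.0)
        np.testing.assert_allclose(u[:, 0], [1.0, 0.0])

    def test_equidistant_is_half_half(self):
        u = kernel_membership(np.array([70.0]), [40.0, 100.0], 2.0, 30.0)
        np.testing.assert_allclose(u[:, 0], [0.5, 0.5], atol=1e-12)

    def test_matches_direct_formula(self):
        I = np.array([55.0, 91.0, 20.0])
        centers, m_f, sf = [40.0, 100.0], 2.0, 30.0
        u = kernel_membership(I, centers, m_f, sf)
        d = np.stack([1 - np.exp(-((I - c) ** 2) / (2 * sf**2)) for c in centers])
        w = d ** (-1 / (m_f - 1))
        np.testing.assert_allclose(u, w / w.sum(axis=0), rtol=1e-12)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-12)

    def test_identical_centers_rejected(self):
        with pytest.raises(DegenerateModelError):
            kernel_membership(np.array([1.0]), [5.0, 5.0], 2.0, 10.0)


class TestSpatialFunction:
    def test_radius_zero_is_identity(self):
        u = np.random.default_rng(0).random((2, 3, 3, 3))
        np.testing.assert_array_equal(spatial_function(u, 0), u)

    def test_uniform_field_interior_sum(self):
        m = np.array([0.3, 0.7])
        u = np.broadcast_to(m[:, None, None, None], (2, 5, 5, 5)).copy()
        h = spatial_function(u, 1)
        np.testing.assert_allclose(h[:, 2, 2, 2], 27 * m)

    def test_matches_bruteforce_triple_loop(self):
        rng = np.random.default_rng(1)
        u = rng.random((2, 3, 4, 3))
        h = spatial_function(u, 1)
        for c in range(2):
            for i in range(3):
                for j in range(4):
                    for k in range(3):
                        s = u[c, max(0, i - 1) : i + 2, max(0, j - 1) : j + 2,
                              max(0, k - 1) : k + 2].sum()
                        assert h[c, i, j, k] == pytest.approx(s, rel=1e-12)


class TestSpatialRefine:
    def test_identity_and_h_only_limits(self):
        rng = np.random.default_rng(2)
        u = rng.dirichlet(np.ones(3), size=10).T.reshape(3, 10)
        h = rng.random((3, 10)) + 0.1
        np.testing.assert_allclose(spatial_refine(u, h, 1.0, 0.0), u, rtol=1e-12)
        np.testing.assert_allclose(
            spatial_refine(u, h, 0.0, 1.0), h / h.sum(axis=0), rtol=1e-12
        )

    def test_hand_arithmetic(self):
        u = np.array([[0.8], [0.2]])
        h = np.array([[1.0], [3.0]])
        out = spatial_refine(u, h, 1.0, 1.0)
        np.testing.assert_allclose(out[:, 0], [4 / 7, 3 / 7], rtol=1e-12)

    def test_zero_denominator_reports_voxel(self):
        u = np.zeros((2, 2))
        h = np.ones((2, 2))
        with pytest.raises(DegenerateModelError, match="voxel"):
            spatial_refine(u, h, 1.0, 0.0)


class TestUpdateCenters:
    def test_constant_data_collapses_to_value(self):
        I = np.full(10, 55.0)
        u = np.vstack([np.full(10, 0.6), np.full(10, 0.4)])
        out = update_centers(u, I, np.array([40.0, 80.0]), 2.0, 30.0)
        np.testing.assert_allclose(out, [55.0, 55.0])

    def test_crisp_wide_kernel_gives_cluster_means(self):
        I = np.array([10.0, 12.0, 14.0, 90.0, 92.0])
        u = np.zeros((2, 5))
        u[0, :3] = 1.0
        u[1, 3:] = 1.0
        out = update_centers(u, I, np.array([12.0, 91.0]), 2.0, 1e6)
        np.testing.assert_allclose(out, [12.0, 91.0], rtol=1e-9)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        I = rng.normal(60, 25, 6)
        u = rng.dirichlet(np.ones(2), size=6).T
        centers = np.array([30.0, 90.0])
        m_f, sf = 2.0, 20.0
        out = update_centers(u, I, centers, m_f, sf)
        for i, c in enumerate(centers):
            K = np.exp(-((I - c) ** 2) / (2 * sf**2))
            w = u[i] ** m_f * K
            assert out[i] == pytest.approx((w * I).sum() / w.sum(), rel=1e-12)
        assert I.min() <= out.min() and out.max() <= I.max()


class TestKFCMSFit:
    def test_two_blob_center_recovery(self):
        rng = np.random.default_rng(0)
        lab = rng.random((20, 20, 25)) < 0.5
        I = np.where(lab, 0.0, 100.0) + rng.normal(0, 1, (20, 20, 25))
        m = kfcms_fit(I, KFCMSParams())
        assert abs(m.centers[0] - 0.0) < 2.0
        assert abs(m.centers[1] - 100.0) < 2.0
        assert m.converged

    def test_normalization_and_center_range_every_iteration(self):
        rng = np.random.default_rng(1)
        I = rng.normal(50, 30, (10, 10, 10))
        for it in range(1, 6):
            m = kfcms_fit(I, KFCMSParams(max_iter=it, tol=0.0))
            np.testing.assert_allclose(m.u.sum(axis=0), 1.0, atol=1e-9)
            assert I.min() <= m.centers.min() <= m.centers.max() <= I.max()

    def test_determinism(self):
        rng = np.random.default_rng(2)
        I = rng.normal(50, 30, (8, 8, 8))
        p = KFCMSParams(init="random", rng_seed=42)
        m1, m2 = kfcms_fit(I, p), kfcms_fit(I, p)
        np.testing.assert_array_equal(m1.u, m2.u)
        np.testing.assert_array_equal(m1.centers, m2.centers)

    def test_constant_volume_degenerate(self):
        with pytest.raises(DegenerateModelError):
            kfcms_fit(np.full((5, 5, 5), 10.0), KFCMSParams())

    def test_reduces_to_crisp_fcm_partition_on_separable_data(self):
        # p=1, q=0, no neighborhood, huge kernel width: same crisp split
        # as plain FCM on two well-separated groups
        I = np.concatenate([np.full(50, 10.0), np.full(50, 90.0)])
        I = I + np.random.default_rng(3).normal(0, 1, 100)
        I = I.reshape(4, 5, 5)
        m = kfcms_fit(I, KFCMSParams(p=1.0, q=0.0, nb_radius=0, sigma_f=1e4))
        crisp = m.u.argmax(axis=0)
        assert np.array_equal(crisp, (I > 50).astype(int))


class TestProbabilityMaps:
    def _voi(self, data):
        vol = Volume(np.asarray(data, dtype=float))
        mask = LabelMask(np.ones(vol.size, dtype=np.uint8))
        return TumorVOI((0, 0, 0), vol, mask, SeedPoint(index=(0, 0, 0), intensity=float(vol.data[0, 0, 0])))

    def test_complement_and_lesion_selection(self):
        rng = np.random.default_rng(4)
        lab = rng.random((6, 6, 6)) < 0.5
        data = np.where(lab, 40.0, 100.0) + rng.normal(0, 2, (6, 6, 6))
        data[0, 0, 0] = 41.0  # seed voxel in the dark blob
        voi = self._voi(data)
        m = kfcms_run(voi, KFCMSParams())
        p_fg, p_bkg = probability_maps(m, voi.seed_local)
        np.testing.assert_allclose(p_fg + p_bkg, 1.0, atol=1e-9)
        # lesion cluster must be the darker center
        assert abs(m.centers[0] - 40) < 5
        assert p_fg[lab].mean() > 0.8 > 0.2 > p_fg[~lab].mean()

    def test_three_cluster_background_pooling(self):
        rng = np.random.default_rng(5)
        choice = rng.integers(0, 3, (8, 8, 8))
        data = np.choose(choice, [30.0, 90.0, 150.0]) + rng.normal(0, 2, (8, 8, 8))
        data[0, 0, 0] = 30.0
        voi = self._voi(data)
        m = kfcms_run(voi, KFCMSParams(n_clusters=3))
        p_fg, p_bkg = probability_maps(m, voi.seed_local)
        np.testing.assert_allclose(p_fg + p_bkg, 1.0, atol=1e-9)
        assert p_fg[choice == 0].mean() > 0.7
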