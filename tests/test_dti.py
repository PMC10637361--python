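import numpy as np
import pytest

from tfusplan.dti import (
    TensorField,
    color_direction_map,
    components_to_matrices,
    fa_from_eigenvalues,
    fa_map,
    fit_tensors,
    gaussian_smooth,
    lanczos3_kernel,
    lanczos3_resample,
    load_tensorfield,
    matrices_to_components,
    save_tensorfield,
)
from tfusplan.errors import DesignMatrixRankError, ValidationError
from tfusplan.volumes import DiffusionScheme, Volume


def forward_signals(D, scheme, s0=1000.0):
    quad = np.einsum("...ij,kj,ki->...k", D, scheme.bvecs, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * quad)


def random_spd_tensors(n, rng):
    """Random SPD tensors with diffusivities in the physiological range."""
    A = rng.normal(size=(n, 3, 3))
    Q, _ = np.linalg.qr(A)
    lam = rng.uniform(0.1e-3, 2.5e-3, size=(n, 3))
    return np.einsum("nij,nj,nkj->nik", Q, lam, Q)


class TestLanczosResample:
    def test_kernel_interpolates_at_integers(self):
        assert lanczos3_kernel(0.0) == pytest.approx(1.0)
        np.testing.assert_allclose(lanczos3_kernel([-2, -1, 1, 2]), 0.0, atol=1e-15)
        np.testing.assert_allclose(lanczos3_kernel([3.0, -3.0, 4.0]), 0.0)

    def test_constant_field_stays_constant(self):
        v = Volume(np.full((10, 10, 10), 3.7), np.diag([2.0, 2.0, 2.0, 1.0]))
        out = lanczos3_resample(v, 1.0)
        assert out.spatial_shape == (20, 20, 20)
        np.testing.assert_allclose(out.data, 3.7, atol=1e-9)

    def test_band_limited_sinusoid_reproduced(self):
        """A sinusoid well below Nyquist survives 2 mm -> 1 mm supersampling
        to better than 1e-2, checked against the analytic signal."""
        n = 32
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        idx = np.indices((n, 8, 8), dtype=float)
        world = idx[0] * 2.0
        k = 2 * np.pi / 16.0  # 16 mm wavelength, Nyquist at 4 mm
        v = Volume(np.sin(k * world), aff)
        out = lanczos3_resample(v, 1.0)
        idx_out = np.indices(out.spatial_shape, dtype=float)
        world_out = out.voxel_to_world(np.moveaxis(idx_out, 0, -1))[..., 0]
        interior = (world_out > 8) & (world_out < 2 * n - 8)
        err = np.abs(out.data - np.sin(k * world_out))[interior]
        assert err.max() < 1e-2

    def test_world_extent_preserved(self):
        v = Volume(np.zeros((10, 10, 10)), np.diag([2.0, 2.0, 2.0, 1.0]))
        out = lanczos3_resample(v, 1.0)
        # first/last voxel centers: extent [-1, 19] mm both before and after
        np.testing.assert_allclose(out.voxel_to_world([0, 0, 0]), -0.5)
        np.testing.assert_allclose(out.voxel_to_world([19, 19, 19]), 18.5)

    def test_nonpositive_spacing_rejected(self):
        v = Volume(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(ValidationError):
            lanczos3_resample(v, 0.0)


class TestGaussianSmooth:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(8, 8, 8)), np.eye(4))
        np.testing.assert_array_equal(gaussian_smooth(v, 0.0).data, v.data)

    def test_impulse_mass_preserved(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        out = gaussian_smooth(Volume(data, np.eye(4)), 2.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_semigroup_property(self):
        """Smoothing by sigma1 then sigma2 equals one smooth by
        sqrt(sigma1^2 + sigma2^2)."""
        rng = np.random.default_rng(1)
        v = Volume(rng.normal(size=(24, 24, 24)), np.eye(4))
        twice = gaussian_smooth(gaussian_smooth(v, 1.5), 2.0)
        once = gaussian_smooth(v, np.hypot(1.5, 2.0))
        core = (slice(6, -6),) * 3
        np.testing.assert_allclose(twice.data[core], once.data[core], atol=1e-3)

    def test_sigma_in_world_mm(self):
        data = np.zeros((21, 11, 11))
        data[10, 5, 5] = 1.0
        v = Volume(data, np.diag([0.5, 1.0, 1.0, 1.0]))  # anisotropic voxels
        out = gaussian_smooth(v, 1.0)
        # spread along x (0.5 mm voxels) must cover twice as many voxels
        px = out.data[:, 5, 5]
        py = out.data[10, :, 5]
        sx = np.sqrt(np.sum(px * (np.arange(21) - 10) ** 2) / px.sum())
        sy = np.sqrt(np.sum(py * (np.arange(11) - 5) ** 2) / py.sum())
        assert sx == pytest.approx(2 * sy, rel=0.05)


class TestTensorFit:
    def test_noise_free_recovery_of_single_tensor(self, scheme):
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        sig = forward_signals(D, scheme)
        dwi = Volume(np.tile(sig, (3, 3, 3, 1)), np.eye(4))
        tf = fit_tensors(dwi, scheme)
        Dhat = components_to_matrices(tf.tensors[1, 1, 1])
        assert np.abs(Dhat - D).max() / np.abs(D).max() < 1e-9

    def test_isotropic_signals_give_zero_fa(self, scheme):
        D = np.eye(3) * 0.7e-3
        sig = forward_signals(D, scheme)
        dwi = Volume(np.tile(sig, (2, 2, 2, 1)), np.eye(4))
        fa = fa_map(fit_tensors(dwi, scheme))
        np.testing.assert_allclose(fa.data, 0.0, atol=1e-9)

    def test_500_random_spd_tensors_recovered(self, scheme):
        rng = np.random.default_rng(3)
        Ds = random_spd_tensors(500, rng).reshape(10, 10, 5, 3, 3)
        sig = forward_signals(Ds, scheme)
        tf = fit_tensors(Volume(sig, np.eye(4)), scheme)
        Dhat = components_to_matrices(tf.tensors)
        rel = np.abs(Dhat - Ds).max(axis=(-1, -2)) / np.abs(Ds).max(axis=(-1, -2))
        assert rel.max() < 1e-8

    def test_noisy_fit_eigenvalue_error_bounded(self, scheme):
        """At a per-measurement SNR of 20 (Gaussian noise with sigma
        proportional to each signal) the median relative eigenvalue error
        of the log-linear fit stays below 5%.  With b0-referenced
        additive noise of the same nominal SNR, strongly attenuated
        frames carry much lower per-sample SNR and the unweighted
        log-linear estimator is noisier (see the methods note)."""
        rng = np.random.default_rng(4)
        Ds = random_spd_tensors(500, rng).reshape(10, 10, 5, 3, 3)
        sig = forward_signals(Ds, scheme, 1000.0)
        sig = np.maximum(sig * (1 + rng.normal(0, 1 / 20.0, sig.shape)), 1e-3)
        tf = fit_tensors(Volume(sig, np.eye(4)), scheme)
        lam_true = np.sort(np.linalg.eigvalsh(Ds), axis=-1)[..., ::-1]
        lam_hat, _ = tf.eigensystem()
        rel = np.abs(lam_hat - lam_true) / lam_true
        assert np.median(rel) < 0.05

    def test_weighted_rows_used(self, scheme):
        """With the S0 frame first, the fit uses exactly the 56 weighted
        frames: corrupting the S0 frame moves every estimate."""
        D = np.diag([1.0e-3, 0.5e-3, 0.5e-3])
        sig = forward_signals(D, scheme)
        dwi = np.tile(sig, (2, 2, 2, 1))
        tf1 = fit_tensors(Volume(dwi, np.eye(4)), scheme)
        dwi2 = dwi.copy()
        dwi2[..., 0] *= 2.0
        tf2 = fit_tensors(Volume(dwi2, np.eye(4)), scheme)
        assert not np.allclose(tf1.tensors, tf2.tensors)
        assert sig.shape[-1] - scheme.b0_mask.sum() == 56

    def test_too_few_directions_rejected(self):
        bvecs = np.zeros((6, 3))
        bvecs[1:] = np.eye(3).repeat(2, axis=0)[:5]
        bvecs[1:] /= np.linalg.norm(bvecs[1:], axis=1, keepdims=True)
        scheme = DiffusionScheme([0] + [1200] * 5, bvecs)
        dwi = Volume(np.ones((2, 2, 2, 6)), np.eye(4))
        with pytest.raises(DesignMatrixRankError):
            fit_tensors(dwi, scheme)

    def test_all_zero_bvals_rejected(self):
        scheme = DiffusionScheme(np.zeros(7), np.zeros((7, 3)))
        dwi = Volume(np.ones((2, 2, 2, 7)), np.eye(4))
        with pytest.raises(DesignMatrixRankError):
            fit_tensors(dwi, scheme)

    def test_nonpositive_signals_masked_out(self, scheme):
        D = np.eye(3) * 0.7e-3
        sig = np.tile(forward_signals(D, scheme), (2, 2, 2, 1))
        sig[0, 0, 0, 3] = -1.0
        tf = fit_tensors(Volume(sig, np.eye(4)), scheme)
        assert not tf.mask[0, 0, 0]
        assert tf.mask[1, 1, 1]
        np.testing.assert_array_equal(tf.tensors[0, 0, 0], 0.0)


class TestDerivedMaps:
    def test_fa_of_isotropic_tensor_is_zero(self):
        assert fa_from_eigenvalues([1.0, 1.0, 1.0]) == pytest.approx(0.0, abs=1e-15)

    def test_fa_of_rank_one_tensor_is_one(self):
        assert fa_from_eigenvalues([1.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_fa_closed_form_for_prolate_tensor(self):
        """FA of eigenvalues (1.7, 0.3, 0.3) x 1e-3, cross-checked with the
        independent pairwise-difference form of the formula."""
        lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        pairwise = np.sqrt(0.5) * np.sqrt(
            (lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[2] - lam[0]) ** 2
        ) / np.linalg.norm(lam)
        assert fa_from_eigenvalues(lam) == pytest.approx(pairwise, abs=1e-12)
        assert fa_from_eigenvalues(lam) == pytest.approx(0.7990, abs=1e-3)

    def test_fa_rotation_invariant(self):
        rng = np.random.default_rng(6)
        lam = np.array([1.7e-3, 0.3e-3, 0.2e-3])
        base = fa_from_eigenvalues(lam)
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            D = Q @ np.diag(lam) @ Q.T
            rotated = np.sort(np.linalg.eigvalsh(D))[::-1]
            assert abs(fa_from_eigenvalues(rotated) - base) < 1e-9

    def _field_from_matrices(self, mats):
        shape = mats.shape[:-2]
        return TensorField(
            matrices_to_components(mats),
            np.ones(shape),
            np.ones(shape, bool),
            np.eye(4),
        )

    def test_color_map_axis_aligned_stick(self):
        D = np.zeros((1, 1, 1, 3, 3))
        D[..., 0, 0] = 1.0e-3  # pure stick along x
        rgb = color_direction_map(self._field_from_matrices(D))
        np.testing.assert_allclose(rgb.data[0, 0, 0], [1.0, 0.0, 0.0], atol=1e-9)

    def test_color_map_isotropic_is_black(self):
        D = np.tile(np.eye(3) * 1e-3, (2, 2, 2, 1, 1))
        rgb = color_direction_map(self._field_from_matrices(D))
        np.testing.assert_allclose(rgb.data, 0.0, atol=1e-12)

    def test_color_map_in_unit_range(self, straight_tensors):
        rgb = color_direction_map(straight_tensors)
        assert rgb.data.min() >= 0.0 and rgb.data.max() <= 1.0


class TestTensorFieldIO:
    def test_roundtrip(self, tmp_path, straight_tensors):
        save_tensorfield(straight_tensors, tmp_path / "t.nii")
        back = load_tensorfield(tmp_path / "t.nii")
        np.testing.assert_allclose(back.tensors, straight_tensors.tensors, atol=1e-12)
        np.testing.assert_array_equal(back.mask, straight_tensors.mask)
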