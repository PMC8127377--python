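import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from destreak.collaborative_filter import group_transform
from destreak.noise_model import (
    CorrelationKernel,
    CovarianceMaps,
    GroupGeometry,
    PowerSpectrum,
    autocovariance,
    block_difference_variances,
    generate_noise,
    group_variances,
    group_variances_dense,
    kernel_from_psd,
    psd_from_kernel,
    residual_streak_kernel,
    streak_kernel,
    tile_streak_profile,
)
from destreak.scale_pyramid import bin_axis, debin_axis
from destreak.transforms import dct_matrix, haar_matrix


def brute_force_dft2(x):
    """O(n^4) double-sum 2-D DFT, independent of numpy.fft."""
    h, w = x.shape
    out = np.zeros((h, w), dtype=complex)
    for u in range(h):
        for v in range(w):
            for a in range(h):
                for b in range(w):
                    out[u, v] += x[a, b] * np.exp(-2j * np.pi * (u * a / h + v * b / w))
    return out


class TestPsdKernelDuality:
    def test_impulse_kernel_flat_spectrum(self):
        g = CorrelationKernel(np.array([[2.0]]))
        psd = psd_from_kernel(g, (6, 6))
        assert np.allclose(psd.values, 4.0)

    def test_streak_kernel_spectrum_on_dc_row(self):
        g = streak_kernel(8, 1.0)
        psd = psd_from_kernel(g, (8, 10))
        assert np.all(psd.values[1:] == 0)
        assert np.any(psd.values[0] > 0)

    def test_matches_brute_force_dft(self, rng):
        g = CorrelationKernel(rng.normal(size=(3, 3)))
        psd = psd_from_kernel(g, (8, 8))
        from destreak.noise_model import _embed_kernel

        ref = np.abs(brute_force_dft2(_embed_kernel(g.values, (8, 8)))) ** 2
        assert np.allclose(psd.values, ref, atol=1e-8)

    def test_kernel_larger_than_shape_errors(self):
        with pytest.raises(ValueError):
            psd_from_kernel(CorrelationKernel(np.ones((4, 4))), (3, 8))

    def test_flat_psd_gives_impulse(self):
        g = kernel_from_psd(PowerSpectrum(np.full((8, 8), 4.0)))
        assert np.isclose(g.values[0, 0], 2.0)
        assert np.allclose(np.delete(g.values.ravel(), 0), 0.0)

    @staticmethod
    def _symmetrize(values):
        """Make a nonnegative array a valid PSD of a real process:
        Psi(f) = Psi(-f)."""
        rev = values[(-np.arange(values.shape[0])) % values.shape[0]][
            :, (-np.arange(values.shape[1])) % values.shape[1]
        ]
        return (values + rev) / 2.0

    def test_dc_row_psd_gives_vertically_constant_kernel(self):
        psd = np.zeros((8, 8))
        psd[0] = np.abs(np.random.default_rng(0).normal(size=8)) + 0.1
        g = kernel_from_psd(PowerSpectrum(self._symmetrize(psd)))
        assert np.allclose(g.values, g.values[0][None, :])

    def test_roundtrip(self, rng):
        psd = PowerSpectrum(self._symmetrize(rng.uniform(0.1, 2.0, size=(16, 16))))
        back = psd_from_kernel(kernel_from_psd(psd), (16, 16))
        assert np.allclose(back.values, psd.values, rtol=1e-8)

    def test_asymmetric_psd_rejected(self, rng):
        # a PSD violating Psi(f) = Psi(-f) has no real zero-phase kernel
        psd = rng.uniform(0.1, 2.0, size=(16, 16))
        with pytest.raises(ValueError):
            kernel_from_psd(PowerSpectrum(psd))

    def test_negative_psd_rejected(self):
        with pytest.raises(ValueError):
            PowerSpectrum(np.full((4, 4), -1.0))

    @given(st.integers(min_value=1, max_value=5), st.integers(min_value=1, max_value=5))
    @settings(max_examples=20, deadline=None)
    def test_roundtrip_property(self, kh, kw):
        rng = np.random.default_rng(kh * 10 + kw)
        g = CorrelationKernel(rng.normal(size=(kh, kw)))
        psd = psd_from_kernel(g, (8, 8))
        back = psd_from_kernel(kernel_from_psd(psd), (8, 8))
        assert np.allclose(back.values, psd.values, rtol=1e-8, atol=1e-12)


class TestGenerateNoise:
    def test_impulse_returns_raw_draw(self):
        g = CorrelationKernel(np.array([[1.0]]))
        out = generate_noise(g, (6, 6), seed=3)
        assert np.allclose(out, np.random.default_rng(3).standard_normal((6, 6)))

    def test_streak_noise_columns_constant(self):
        out = generate_noise(streak_kernel(16, 0.5), (16, 20), seed=0)
        assert np.allclose(out, out[0][None, :])

    def test_deterministic(self):
        g = streak_kernel(8, 1.0)
        assert np.array_equal(generate_noise(g, (8, 8), seed=7), generate_noise(g, (8, 8), seed=7))

    def test_empirical_std_converges(self):
        g = streak_kernel(64, 0.7)
        acc = 0.0
        n_fields = 500
        for s in range(n_fields):
            acc += generate_noise(g, (64, 64), seed=s).var()
        emp = np.sqrt(acc / n_fields)
        # 3 standard errors; each field has 64 independent streak values
        se = 0.7 / np.sqrt(2 * 64 * n_fields)
        assert abs(emp - 0.7) < 3 * se + 0.01


class TestStreakKernels:
    def test_entries(self):
        g = streak_kernel(8, 1.0)
        assert g.values.shape == (8, 1)
        assert np.allclose(g.values, 1 / np.sqrt(8))
        assert np.isclose(g.std, 1.0)

    def test_zero_sigma(self):
        assert np.all(streak_kernel(4, 0.0).values == 0)

    def test_scale_doubling_rule(self):
        # noise level at scale k grows as 2**(k/2); k=2 with 0.005 -> 0.010
        s0 = 0.005
        assert np.isclose(2 ** (2 / 2) * s0, 0.010)
        g = streak_kernel(8, 2 ** (2 / 2) * s0)
        assert np.isclose(g.std, 0.010)

    def test_variance_doubles_after_horizontal_binning(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 10**6 // 4))
        binned = bin_axis(x, 1, 2)
        ratio = binned.var() / x.var()
        assert abs(ratio - 2.0) < 0.02 * 2.0


class TestResidualStreakKernel:
    def test_unit_norm_and_low_frequency_notch(self):
        h = residual_streak_kernel(64, mc_iters=2000, seed=0)
        assert np.isclose(np.linalg.norm(h), 1.0)
        spec = np.abs(np.fft.fft(h))
        assert spec[0] < 0.02 * spec.max()

    def test_matches_dense_operator_oracle(self):
        w = 16
        iters = 100_000
        h = residual_streak_kernel(w, mc_iters=iters, seed=3)
        L = np.zeros((w, w))
        for i in range(w):
            e = np.zeros((1, w))
            e[0, i] = 1.0
            L[:, i] = (e - debin_axis(bin_axis(e, 1, 2), 1, w))[0]
        C = L @ L.T
        F = np.fft.fft(np.eye(w))
        var_f = np.clip(np.real(np.einsum("fa,ab,fb->f", F, C, F.conj())), 0.0, None)
        hk = np.fft.ifft(np.sqrt(var_f)).real
        hk /= np.linalg.norm(hk)
        # 3 Monte-Carlo standard errors on the per-frequency std
        tol = 3.0 / np.sqrt(2 * iters) + 1e-3
        assert np.abs(h - hk).max() < tol

    def test_mc_iters_validation(self):
        with pytest.raises(ValueError):
            residual_streak_kernel(16, mc_iters=1)

    def test_tile_vertical(self):
        h = residual_streak_kernel(16, mc_iters=500, seed=0)
        k = tile_streak_profile(h, 8, sigma=0.3)
        assert k.values.shape == (8, 16)
        assert np.isclose(k.std, 0.3)
        assert np.allclose(k.values, k.values[0][None, :])


class TestGroupVariances:
    def test_white_noise_orthonormal(self):
        psd = psd_from_kernel(CorrelationKernel(np.array([[0.7]])), (16, 16))
        geom = GroupGeometry(4, [(0, 0), (2, 5), (9, 3), (12, 12)], (16, 16))
        var = group_variances(psd, geom).values
        assert np.allclose(var, 0.49, rtol=1e-10)

    def test_single_block_dc_variance(self, rng):
        g = CorrelationKernel(rng.normal(size=(2, 2)) * 0.3)
        psd = psd_from_kernel(g, (12, 12))
        geom = GroupGeometry(4, [(3, 3)], (12, 12))
        var = group_variances(psd, geom, T2D=dct_matrix(4), T1D=np.eye(1)).values
        r = autocovariance(psd)
        # DC variance = (1/N) * sum over intra-block offsets of r
        acc = 0.0
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    for d in range(4):
                        acc += r[(c - a) % 12, (d - b) % 12]
        assert np.isclose(var[0, 0], acc / 16, rtol=1e-10)

    def test_identical_positions_difference_coefficient_zero(self, rng):
        g = CorrelationKernel(rng.normal(size=(3, 3)))
        psd = psd_from_kernel(g, (16, 16))
        geom = GroupGeometry(4, [(5, 5), (5, 5)], (16, 16))
        var = group_variances(psd, geom, T1D=haar_matrix(2)).values
        assert np.allclose(var[1], 0.0, atol=1e-10)  # the +/- coefficient

    def test_fast_path_matches_dense(self, rng):
        for trial in range(3):
            g = CorrelationKernel(rng.normal(size=(3, 3)))
            psd = psd_from_kernel(g, (16, 16))
            pos = [tuple(p) for p in rng.integers(0, 13, size=(4, 2))]
            geom = GroupGeometry(4, pos, (16, 16))
            dense = group_variances_dense(psd, geom, dct_matrix(4), haar_matrix(4)).values
            fast = CovarianceMaps(psd, 4).group_variances(geom.positions, haar_matrix(4))
            assert np.allclose(fast, dense, rtol=1e-6, atol=1e-12)

    def test_matches_empirical(self, rng):
        g = CorrelationKernel(rng.normal(size=(3, 3)) * 0.5)
        psd = psd_from_kernel(g, (16, 16))
        geom = GroupGeometry(4, [(0, 0), (4, 7), (10, 2)], (16, 16))
        T2, T1 = dct_matrix(4), np.eye(3)
        var = group_variances(psd, geom, T2D=T2, T1D=T1).values
        n_draws = 2000
        acc = np.zeros_like(var)
        for s in range(n_draws):
            eta = generate_noise(g, (16, 16), seed=s)
            blocks = np.stack([eta[r : r + 4, c : c + 4] for r, c in geom.positions])
            acc += group_transform(blocks, T2, T1).reshape(3, 16) ** 2
        emp = acc / n_draws
        se = var * np.sqrt(2.0 / n_draws)
        assert np.all(np.abs(emp - var) < 3 * se + 1e-12)

    def test_psd_shape_mismatch_errors(self):
        psd = PowerSpectrum(np.ones((8, 8)))
        geom = GroupGeometry(4, [(0, 0)], (16, 16))
        with pytest.raises(ValueError):
            group_variances(psd, geom)


class TestBlockDifferenceVariances:
    def test_zero_offset(self, rng):
        psd = psd_from_kernel(CorrelationKernel(rng.normal(size=(3, 3))), (16, 16))
        assert np.allclose(block_difference_variances(psd, 4, (0, 0)), 0.0, atol=1e-10)

    def test_white_disjoint(self):
        psd = psd_from_kernel(CorrelationKernel(np.array([[0.7]])), (16, 16))
        var = block_difference_variances(psd, 4, (5, 7))
        assert np.allclose(var, 2 * 0.49, rtol=1e-10)

    def test_streak_vertical_vs_horizontal_offset(self):
        psd = psd_from_kernel(streak_kernel(16, 0.5), (16, 16))
        vert = block_difference_variances(psd, 4, (5, 0))
        assert np.abs(vert).max() < 1e-10  # same columns: fully correlated noise
        cov = CovarianceMaps(psd, 4)
        horiz = block_difference_variances(psd, 4, (0, 8))
        assert np.allclose(horiz, 2 * cov.var0, atol=1e-10)

    def test_against_dense_oracle(self, rng):
        g = CorrelationKernel(rng.normal(size=(3, 3)))
        psd = psd_from_kernel(g, (16, 16))
        d = (2, 5)
        var = block_difference_variances(psd, 4, d)
        # dense: variance of T2D(block0 - blockd) via a 2-block group with
        # the (scaled) difference coefficient of the 2-point Haar transform
        geom = GroupGeometry(4, [(3, 3), (3 + d[0], 3 + d[1])], (16, 16))
        dense = group_variances_dense(psd, geom, dct_matrix(4), haar_matrix(2)).values
        # Haar difference coefficient is (b0 - b1)/sqrt(2): variance halves
        assert np.allclose(var, 2.0 * dense[1], rtol=1e-8, atol=1e-12)
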