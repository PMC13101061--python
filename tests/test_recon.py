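"""Forward model, closed-form Tikhonov inversion, focal stacks, color merge."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as ssim

import diffuscope as d
from diffuscope.errors import (
    DataError,
    DomainError,
    GeometryError,
    IllPosedError,
)
from diffuscope.recon import (
    Measurement,
    ReconConfig,
    forward_measure,
    merge_color,
    reconstruct_stack,
    tikhonov_deconvolve,
    tikhonov_objective,
)


def _delta(n):
    h = np.zeros((n, n))
    h[n // 2, n // 2] = 1.0
    return h


def _circulant_matrix(h, n):
    """Dense matrix of 2-D circular convolution with kernel h on an n x n
    grid — the independent linear-algebra oracle."""
    kern = np.fft.ifftshift(h)
    A = np.zeros((n * n, n * n))
    for r in range(n):
        for c in range(n):
            A[:, r * n + c] = np.roll(np.roll(kern, r, axis=0), c, axis=1).ravel()
    return A


class TestForwardMeasure:
    def test_delta_scene_reproduces_psf(self, screen192):
        h = d.caustic_psf(screen192)
        x = _delta(256)
        y = forward_measure(x, h, 0.0, 0, "linear").image
        embedded = np.zeros((256, 256))
        embedded[32:224, 32:224] = h
        assert np.allclose(y, embedded, atol=1e-12)

    @pytest.mark.parametrize("pad", ["linear", "circular"])
    def test_delta_psf_is_identity(self, pad):
        rng = np.random.default_rng(0)
        x = rng.random((96, 96))
        y = forward_measure(x, _delta(32), 0.0, 0, pad).image
        assert np.allclose(y, x, atol=1e-12)

    def test_energy_conserved_for_compact_scene(self, screen192):
        h = d.caustic_psf(screen192)
        x = np.zeros((512, 512))
        x[236:276, 236:276] = 1.0  # blob + PSF support stays inside the frame
        y = forward_measure(x, h, 0.0, 0, "linear").image
        assert y.sum() == pytest.approx(x.sum(), rel=1e-6)

    def test_noise_deterministic_per_seed(self):
        x = np.ones((32, 32))
        a = forward_measure(x, _delta(8), 0.1, 5, "circular").image
        b = forward_measure(x, _delta(8), 0.1, 5, "circular").image
        c = forward_measure(x, _delta(8), 0.1, 6, "circular").image
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_pitch_mismatch_raises(self):
        with pytest.raises(GeometryError):
            forward_measure(
                np.ones((16, 16)), _delta(8), scene_pitch=6.4, psf_pitch=12.8
            )

    def test_measurement_validation(self):
        with pytest.raises(DataError):
            Measurement(np.full((4, 4), np.nan), channel="green")
        with pytest.raises(DataError):
            Measurement(np.ones((4, 4)), channel="ultraviolet")


class TestTikhonovDeconvolve:
    def test_identity_psf_mu_zero(self):
        rng = np.random.default_rng(1)
        y = rng.random((48, 48))
        assert np.allclose(tikhonov_deconvolve(y, _delta(16), 0.0, "circular"), y,
                           atol=1e-12)

    def test_identity_psf_uniform_shrinkage(self):
        rng = np.random.default_rng(2)
        y = rng.random((48, 48))
        out = tikhonov_deconvolve(y, _delta(16), 0.5, "circular")
        assert np.allclose(out, y / 1.5, atol=1e-12)

    def test_mu_zero_illposed_rejected(self):
        # a two-pixel boxcar has an exact transfer-function zero at Nyquist
        h = np.zeros((16, 16))
        h[8, 8] = h[8, 9] = 0.5
        with pytest.raises(IllPosedError, match=r"\|H\|"):
            tikhonov_deconvolve(np.ones((16, 16)), h, 0.0, "circular")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_normal_equations(self, seed):
        """The FFT solution equals the minimizer of the regularized normal
        equations solved as a dense circulant linear system."""
        n, mu = 16, 0.01
        rng = np.random.default_rng(seed)
        x = rng.random((n, n))
        h = rng.random((n, n))
        h /= h.sum()
        A = _circulant_matrix(h, n)
        y = (A @ x.ravel()).reshape(n, n)
        oracle = np.linalg.solve(A.T @ A + mu * np.eye(n * n), A.T @ y.ravel())
        got = tikhonov_deconvolve(y, h, mu, "circular").ravel()
        assert np.linalg.norm(got - oracle) / np.linalg.norm(oracle) < 1e-8

    def test_linearity(self):
        rng = np.random.default_rng(3)
        h = rng.random((16, 16))
        h /= h.sum()
        y1, y2 = rng.random((32, 32)), rng.random((32, 32))
        a, b = 2.5, -0.7
        lhs = tikhonov_deconvolve(a * y1 + b * y2, h, 0.01, "circular")
        rhs = a * tikhonov_deconvolve(y1, h, 0.01, "circular") + b * (
            tikhonov_deconvolve(y2, h, 0.01, "circular")
        )
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_objective_descent(self):
        """The closed-form estimate attains a lower objective value than
        both the measurement itself and the zero image."""
        rng = np.random.default_rng(4)
        x = rng.random((32, 32))
        h = rng.random((32, 32))
        h /= h.sum()
        mu = 0.01
        y = forward_measure(x, h, 0.01, 0, "circular").image
        xh = tikhonov_deconvolve(y, h, mu, "circular")
        j_hat = tikhonov_objective(xh, y, h, mu)
        assert j_hat <= tikhonov_objective(y, y, h, mu)
        assert j_hat <= tikhonov_objective(np.zeros_like(y), y, h, mu)

    def test_negative_mu_rejected(self):
        with pytest.raises(DomainError):
            tikhonov_deconvolve(np.ones((8, 8)), _delta(8), -0.1)


class TestReconstructStack:
    def test_single_slice_matches_direct_call(self, stack192, phantom192):
        x = phantom192.channels["green"]
        h = stack192.psfs[4]
        m = forward_measure(x, h, 0.0, 0, "circular", channel="green")
        cfg = ReconConfig(
            pad_mode="circular", epsilon_grid=np.array([stack192.epsilon[4]])
        )
        fs = reconstruct_stack({"green": m}, stack192, cfg)
        direct = tikhonov_deconvolve(m, h, cfg.mu_for("green"), "circular")
        assert len(fs) == 1
        assert np.array_equal(fs.reconstructions["green"][0], direct)

    def test_off_grid_epsilon_rejected(self, stack192, phantom192):
        m = forward_measure(
            phantom192.channels["green"], stack192.psfs[0], 0.0, 0, "circular",
            channel="green",
        )
        cfg = ReconConfig(pad_mode="circular", epsilon_grid=np.array([1.0]))
        with pytest.raises(DomainError):
            reconstruct_stack({"green": m}, stack192, cfg)

    def test_reconstruction_count_logged(self, stack192, phantom192, caplog):
        import logging

        caplog.set_level(logging.INFO, logger="diffuscope.recon")
        m = forward_measure(
            phantom192.channels["green"], stack192.psfs[4], 0.0, 0, "circular",
            channel="green",
        )
        reconstruct_stack({"green": m}, stack192, ReconConfig(pad_mode="circular"))
        assert f"({len(stack192)} deconvolutions)" in caplog.text

    def test_true_epsilon_slice_is_most_similar(self, screen192, stack192,
                                                phantom192):
        """Deconvolving with the generating PSF yields the reconstruction
        most similar to ground truth; slices 5 D away are worse."""
        x = phantom192.channels["green"]
        h = d.caustic_psf(
            screen192, input_vergence=d.vergence_at_diffuser(0.0, relative=False)
        )
        m = forward_measure(x, h, 1e-3, 0, "circular", channel="green")
        fs = reconstruct_stack({"green": m}, stack192,
                               ReconConfig(pad_mode="circular"))
        i_true = int(np.argmin(np.abs(stack192.epsilon)))
        dr = float(x.max() - x.min())
        scores = [
            ssim(x, fs.reconstructions["green"][i], data_range=dr)
            for i in range(len(fs))
        ]
        far = np.abs(stack192.epsilon - 0.0) >= 5.0
        assert scores[i_true] > max(np.asarray(scores)[far])


class TestMergeColor:
    def test_identical_channels_gray(self):
        rng = np.random.default_rng(0)
        a = rng.random((32, 32))
        rgb = merge_color(a, a, a)
        assert rgb.shape == (32, 32, 3)
        assert np.array_equal(rgb[..., 0], rgb[..., 1])
        assert np.array_equal(rgb[..., 1], rgb[..., 2])

    def test_sum_mode_preserves_bar_resolution(self):
        t = d.make_bar_target([4.0, 8.0], n=256, pixel_size=26.4)
        from diffuscope.focus import read_resolution

        merged = merge_color(t.image, t.image, t.image, mode="sum")
        single = read_resolution(t.image, t, 0.1).resolved_lp_mm
        assert read_resolution(merged, t, 0.1).resolved_lp_mm == single

    def test_percentile_clipping_saturation_bound(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(200, 200))
        rgb = merge_color(img, img, img, percentiles=(0.1, 99.9))
        for c in range(3):
            frac_hi = np.mean(rgb[..., c] == 1.0)
            frac_lo = np.mean(rgb[..., c] == 0.0)
            assert frac_hi <= 0.002 and frac_lo <= 0.002

    def test_shape_mismatch_raises(self):
        with pytest.raises(GeometryError):
            merge_color(np.ones((8, 8)), np.ones((8, 8)), np.ones((9, 9)))
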