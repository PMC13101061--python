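"""Phase screen, caustic propagation, PSF stack, and MTF analysis."""

import numpy as np
import pytest

import diffuscope as d
from diffuscope import optics
from diffuscope.diffuser import (
    PSFStack,
    build_psf_stack,
    caustic_psf,
    make_phase_screen,
    mtf_radial,
    resolution_from_mtf,
    vergence_at_diffuser,
)
from diffuscope.errors import DataError, DomainError, SamplingError


def _rms_radius(psf, pitch_um):
    n = psf.shape[0]
    c = (np.arange(n) - n // 2) * pitch_um * 1e-3
    xx, yy = np.meshgrid(c, c)
    return float(np.sqrt((psf * (xx**2 + yy**2)).sum()))


class TestPhaseScreen:
    def test_deterministic(self):
        a = make_phase_screen(seed=7, n=128)
        b = make_phase_screen(seed=7, n=128)
        assert np.array_equal(a.phase, b.phase)
        assert not np.array_equal(a.phase, make_phase_screen(seed=8, n=128).phase)

    def test_zero_divergence_is_flat(self):
        s = make_phase_screen(seed=0, n=64, divergence_fwhm=0.0)
        assert np.all(s.phase == 0.0)

    def test_divergence_matches_request(self):
        s = make_phase_screen(seed=3, n=256, divergence_fwhm=0.5)
        assert s.deflection_fwhm_measured() == pytest.approx(0.5, rel=0.10)

    def test_argument_validation(self):
        with pytest.raises(DomainError):
            make_phase_screen(seed=0, n=32)
        with pytest.raises(SamplingError):
            make_phase_screen(seed=0, n=128, pitch=6.4, correlation_length=10.0)


class TestCausticPsf:
    def test_unit_energy_and_nonnegative(self, screen192):
        p = caustic_psf(screen192)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert p.min() >= 0.0

    def test_flat_screen_gives_smooth_blur(self):
        """Without the diffuser the pattern is a smooth aperture-diffraction
        blur; the diffuser turns it into a high-contrast caustic network."""
        flat = make_phase_screen(seed=0, n=192, divergence_fwhm=0.0)
        rough = make_phase_screen(seed=0, n=192)
        p_flat = caustic_psf(flat)
        p_caustic = caustic_psf(rough)

        def interior_contrast(p):
            n = p.shape[0]
            core = p[n // 4 : -n // 4, n // 4 : -n // 4]
            return core.std() / core.mean()

        # the flat field shows only shallow aperture ripples; the caustic
        # network is fully modulated (speckle contrast ~ 1 and above)
        assert interior_contrast(p_flat) < 0.5
        assert interior_contrast(p_caustic) > 1.0
        assert interior_contrast(p_caustic) > 2 * interior_contrast(p_flat)

    def test_rms_radius_monotone_in_vergence(self, screen192):
        radii = [
            _rms_radius(caustic_psf(screen192, input_vergence=v), screen192.pitch)
            for v in (-4.0, -2.0, 0.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(radii) > 0)

    def test_scale_modes_agree(self, screen192):
        for v in (-2.0, 3.0, 12.6):
            rp = _rms_radius(
                caustic_psf(screen192, input_vergence=v, scale_mode="physical"),
                screen192.pitch,
            )
            rg = _rms_radius(
                caustic_psf(screen192, input_vergence=v, scale_mode="geometric"),
                screen192.pitch,
            )
            assert rg == pytest.approx(rp, rel=0.02)

    def test_nyquist_violation_raises(self, screen192):
        with pytest.raises(SamplingError, match="grid"):
            caustic_psf(screen192, input_vergence=500.0)

    def test_bad_arguments(self, screen192):
        with pytest.raises(DomainError):
            caustic_psf(screen192, propagation_distance=-1.0)
        with pytest.raises(DomainError):
            caustic_psf(screen192, scale_mode="magic")


class TestVergenceRelay:
    def test_emmetropic_baseline_is_zero(self):
        assert vergence_at_diffuser(0.0) == 0.0

    def test_strictly_monotone_and_sign_preserving(self):
        eps = np.linspace(-12, 12, 25)
        v = np.array([vergence_at_diffuser(e) for e in eps])
        assert np.all(np.diff(v) > 0)
        assert np.all(v[eps < 0] < 0) and np.all(v[eps > 0] > 0)

    def test_absolute_matches_conjugate_geometry(self):
        """The relayed beam vergence equals the divergence from the
        conjugate fundus plane F''."""
        for e in (-12.0, 0.0, 12.0):
            g = optics.imaging_geometry(e)
            assert vergence_at_diffuser(e, relative=False) == pytest.approx(
                1000.0 / g.d_Fpp_D, abs=1e-9
            )


class TestPsfStack:
    def test_sweep_endpoints_and_ordering(self, stack192):
        assert stack192.epsilon[0] == pytest.approx(-12.63, abs=5e-3)
        assert stack192.epsilon[-1] == pytest.approx(12.18, abs=5e-3)
        assert np.all(np.diff(stack192.epsilon) > 0)
        sums = stack192.psfs.reshape(len(stack192), -1).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert stack192.psfs.min() >= 0

    def test_empty_range_raises(self, screen192):
        with pytest.raises(DomainError):
            build_psf_stack(screen192, (6.0, -12.0), 3.0)
        with pytest.raises(DomainError):
            build_psf_stack(screen192, (-12.0, 6.0), -1.0)

    def test_validation(self, stack192):
        with pytest.raises(DataError):
            PSFStack(
                psfs=stack192.psfs[:3] * 2.0,  # not unit-sum
                delta_z=stack192.delta_z[:3],
                epsilon=stack192.epsilon[:3],
                f_lens=stack192.f_lens,
                wavelength_nm=550.0,
                pitch=6.4,
            )
        with pytest.raises(DataError):
            PSFStack(
                psfs=stack192.psfs[:3],
                delta_z=stack192.delta_z[:3],
                epsilon=stack192.epsilon[:3] + 1.0,  # inconsistent with delta_z
                f_lens=stack192.f_lens,
                wavelength_nm=550.0,
                pitch=6.4,
            )

    def test_index_nearest(self, stack192):
        i = stack192.index_nearest(0.1)
        assert stack192.epsilon[i] == pytest.approx(0.0)
        with pytest.raises(DomainError):
            stack192.index_nearest(stack192.epsilon[2] + 1.0, tol=0.05)


class TestMtf:
    def test_delta_psf_flat_mtf(self):
        psf = np.zeros((64, 64))
        psf[32, 32] = 1.0
        freq, mod = mtf_radial(psf, 6.4)
        assert np.allclose(mod, 1.0, atol=1e-9)
        assert freq[-1] == pytest.approx(1.0 / (2 * 6.4e-3))

    @pytest.mark.parametrize("sigma", [1.5, 2.0])
    def test_gaussian_psf_matches_closed_form(self, sigma):
        n = 128
        c = np.arange(n) - n // 2
        xx, yy = np.meshgrid(c, c)
        psf = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        psf /= psf.sum()
        freq, mod = mtf_radial(psf, 6.4)
        f_cyc_px = freq * 6.4e-3
        expected = np.exp(-2 * np.pi**2 * sigma**2 * f_cyc_px**2)
        assert np.all(np.abs(mod - expected) < 0.02)

    def test_broader_psf_smaller_mtf(self):
        n = 128
        c = np.arange(n) - n // 2
        xx, yy = np.meshgrid(c, c)

        def g(s):
            p = np.exp(-(xx**2 + yy**2) / (2 * s**2))
            return p / p.sum()

        _, narrow = mtf_radial(g(1.5), 6.4)
        _, broad = mtf_radial(g(3.0), 6.4)
        assert np.all(broad[1:] <= narrow[1:] + 1e-12)

    def test_nonfinite_raises(self):
        with pytest.raises(DataError):
            mtf_radial(np.full((8, 8), np.nan), 6.4)


class TestResolutionFromMtf:
    def test_delta_psf_reaches_fundus_nyquist(self):
        psf = np.zeros((64, 64))
        psf[32, 32] = 1.0
        curve = mtf_radial(psf, 6.4)
        for eps in (0.0, -12.0, 12.0):
            r_um = optics.object_pixel_size(eps)
            assert resolution_from_mtf(curve, 1e-3, eps) == pytest.approx(
                1.0 / (2 * r_um * 1e-3), rel=1e-6
            )

    def test_gaussian_crossing(self):
        n, sigma = 256, 2.0
        c = np.arange(n) - n // 2
        xx, yy = np.meshgrid(c, c)
        psf = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        psf /= psf.sum()
        curve = mtf_radial(psf, 6.4)
        floor = 0.05
        got = resolution_from_mtf(curve, floor, 0.0)
        # invert the Gaussian MTF for the crossing frequency
        f_star_px = np.sqrt(-np.log(floor) / (2 * np.pi**2 * sigma**2))
        expected = (f_star_px / 6.4e-3) * (6.4 / optics.object_pixel_size(0.0))
        bin_width = curve[0][1] * (6.4 / optics.object_pixel_size(0.0))
        assert abs(got - expected) <= bin_width

    def test_floor_monotonicity_and_domain(self):
        s = make_phase_screen(seed=1, n=128)
        curve = mtf_radial(caustic_psf(s), s.pitch)
        res = [resolution_from_mtf(curve, m) for m in (1e-4, 1e-3, 1e-2, 0.1)]
        assert np.all(np.diff(res) <= 0)
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(DomainError):
                resolution_from_mtf(curve, bad)


def test_stack_tiff_roundtrip_bitexact(tmp_path, stack192):
    """A regenerated stack written and re-read as 32-bit float TIFF is
    bit-identical to the float32 cast of the original."""
    from diffuscope.io import load_psf_stack, save_psf_stack

    path = tmp_path / "stack.tif"
    save_psf_stack(path, stack192)
    loaded = load_psf_stack(path)
    assert np.array_equal(
        loaded.psfs.astype(np.float32), stack192.psfs.astype(np.float32)
    )
    assert np.allclose(loaded.epsilon, stack192.epsilon, atol=1e-12)
    assert loaded.provenance == "simulated"
    assert loaded.seed == stack192.seed
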