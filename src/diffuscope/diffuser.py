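"""Synthetic caustic-PSF calibration for a holographic-diffuser camera.

The physical instrument is calibrated by imaging a pinhole through a weak
(0.5 degree) holographic diffuser while sweeping the pinhole axially to
induce a range of defocus errors; the recorded caustic pattern at each
position is the PSF for that defocus error.  This module is the simulated
stand-in for that bench procedure:

* :func:`make_phase_screen` draws a band-limited Gaussian random phase whose
  RMS local wavefront slope realizes a requested ray-deflection FWHM (the
  diffuser's divergence specification).
* :func:`caustic_psf` propagates a soft-apertured unit-amplitude field
  through the screen with an added quadratic vergence phase, using the
  band-limited angular-spectrum method, and returns the normalized
  intensity.  The vergence is what scales/reshapes the caustic, exactly as
  the wavefront emerging from an ametropic eye does at the diffuser plane.
* :func:`build_psf_stack` sweeps the calibration displacement range and
  assembles the defocus-indexed :class:`PSFStack`.
* :func:`mtf_radial` / :func:`resolution_from_mtf` compute the radially
  binned modulation transfer of a PSF and the noise-floor-limited
  resolution on the fundus.

The simulated chain is exactly shift-invariant by construction (one PSF per
plane); the physical system is only approximately so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from . import optics
from .errors import DataError, DegenerateGeometryError, DomainError, SamplingError
from .optics import SystemConstants, DEFAULTS

__all__ = [
    "PhaseScreen",
    "PSFStack",
    "make_phase_screen",
    "caustic_psf",
    "vergence_at_diffuser",
    "build_psf_stack",
    "mtf_radial",
    "resolution_from_mtf",
]

#: FWHM of a unit-variance Gaussian.
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_WAVELENGTH_NM = 550.0  # centre of the green illumination band
DEFAULT_PITCH_UM = 6.4  # simulate on the sensor pixel grid
DEFAULT_DIVERGENCE_DEG = 0.5
DEFAULT_CORRELATION_UM = 60.0
#: Aperture (conjugate-pupil patch on the diffuser) as a fraction of grid extent.
DEFAULT_APERTURE_FRACTION = 0.6


@dataclass(frozen=True)
class PhaseScreen:
    """A deterministic random phase screen standing in for the diffuser.

    ``phase`` is the optical phase in radians at ``wavelength_nm`` on a
    square grid of sample spacing ``pitch`` (um).  ``divergence_fwhm`` is
    the per-axis FWHM (degrees) of the ray-deflection distribution the
    screen was scaled to produce.
    """

    phase: np.ndarray
    pitch: float
    divergence_fwhm: float
    seed: int
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    correlation_length: float = DEFAULT_CORRELATION_UM

    @property
    def n(self) -> int:
        return self.phase.shape[0]

    def deflection_fwhm_measured(self) -> float:
        """Per-axis ray-deflection FWHM (degrees) from finite differences.

        The local deflection angle is (lambda / 2 pi) * grad(phase); for a
        Gaussian screen the per-axis distribution is Gaussian and its FWHM
        is 2 sqrt(2 ln 2) times the slope RMS.
        """
        lam_um = self.wavelength_nm * 1e-3
        gy, gx = np.gradient(self.phase, self.pitch)
        slope_rms = np.sqrt(0.5 * (np.var(gx) + np.var(gy)))
        return np.degrees(_FWHM * lam_um / (2.0 * np.pi) * slope_rms)


def make_phase_screen(
    seed: int,
    n: int = 512,
    pitch: float = DEFAULT_PITCH_UM,
    divergence_fwhm: float = DEFAULT_DIVERGENCE_DEG,
    correlation_length: float = DEFAULT_CORRELATION_UM,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
) -> PhaseScreen:
    """Draw a band-limited Gaussian phase screen with a target divergence.

    White Gaussian noise is smoothed with a Gaussian kernel of the given
    correlation length (periodic boundaries, so the screen tiles cleanly on
    the FFT grid) and rescaled so the RMS local wavefront slope corresponds
    to the requested per-axis ray-deflection FWHM at ``wavelength_nm``.
    Bit-identical for identical (seed, parameters).
    """
    if n < 64:
        raise DomainError("phase-screen grid must be at least 64 samples")
    if pitch <= 0:
        raise DomainError("pitch must be positive")
    if divergence_fwhm < 0:
        raise DomainError("divergence_fwhm must be non-negative")
    if correlation_length < 2.0 * pitch:
        raise SamplingError(
            f"correlation_length = {correlation_length} um is below 2*pitch = "
            f"{2 * pitch} um; the screen would alias on this grid"
        )
    if divergence_fwhm == 0.0:
        return PhaseScreen(
            np.zeros((n, n)), pitch, 0.0, seed, wavelength_nm, correlation_length
        )
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n, n))
    smooth = gaussian_filter(white, sigma=correlation_length / pitch, mode="wrap")
    smooth -= smooth.mean()
    std = smooth.std()
    if std == 0:
        raise DomainError("degenerate screen: zero variance after smoothing")
    smooth /= std
    # Current per-axis deflection std of the unit-variance screen, radians.
    lam_um = wavelength_nm * 1e-3
    gy, gx = np.gradient(smooth, pitch)
    slope_rms = np.sqrt(0.5 * (np.var(gx) + np.var(gy)))
    theta_rms_now = lam_um / (2.0 * np.pi) * slope_rms
    theta_rms_target = np.radians(divergence_fwhm) / _FWHM
    phase = smooth * (theta_rms_target / theta_rms_now)
    return PhaseScreen(phase, pitch, divergence_fwhm, seed, wavelength_nm, correlation_length)


def _angular_spectrum(u: np.ndarray, pitch_mm: float, lam_mm: float, z_mm: float) -> np.ndarray:
    """Band-limited angular-spectrum propagation over ``z_mm``.

    Spatial frequencies whose rays would leave the grid half-extent over the
    propagation distance are suppressed (the standard band limit that keeps
    the periodic transfer function from aliasing); evanescent components are
    dropped.
    """
    n = u.shape[0]
    f = np.fft.fftfreq(n, d=pitch_mm)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    f2 = fx**2 + fy**2
    kz_arg = np.maximum(0.0, 1.0 / lam_mm**2 - f2)
    transfer = np.where(f2 < 1.0 / lam_mm**2,
                        np.exp(2j * np.pi * z_mm * np.sqrt(kz_arg)), 0.0)
    half = n * pitch_mm / 2.0
    f_lim = half / (lam_mm * np.hypot(z_mm, half))
    transfer *= (np.abs(fx) <= f_lim) & (np.abs(fy) <= f_lim)
    return np.fft.ifft2(np.fft.fft2(u) * transfer)


def caustic_psf(
    screen: PhaseScreen,
    propagation_distance: float = 11.0,
    wavelength_nm: float | None = None,
    input_vergence: float = 0.0,
    aperture_diameter_mm: float | None = None,
    scale_mode: str = "physical",
) -> np.ndarray:
    """Caustic intensity pattern a distance behind the diffuser.

    A unit-amplitude field limited by a soft-edged (super-Gaussian) circular
    aperture — the conjugate-pupil patch illuminated on the diffuser — picks
    up the screen phase and the ``input_vergence`` (diopters; positive =
    diverging, which magnifies the propagated pattern), and is propagated
    ``propagation_distance`` mm by the band-limited angular-spectrum method.
    Returns |field|^2 normalized to unit sum.

    ``scale_mode`` chooses how the vergence enters:

    * ``'physical'`` — a sampled quadratic phase before propagation (the
      literal wave-optics route).  Raises :class:`SamplingError` when that
      phase is not Nyquist-sampled on the screen grid, which caps the
      product of grid size and vergence.
    * ``'geometric'`` — the Fresnel scaling theorem: propagate the
      unvergenced field over the effective distance z/(1 + zV) and magnify
      the intensity coordinates by 1 + zV.  Exact within the Fresnel
      approximation, alias-free at any grid size, and faster for sweeps.

    The two modes agree on the ordering (and closely on the value) of the
    caustic's RMS radius as a function of vergence.
    """
    if propagation_distance <= 0:
        raise DomainError("propagation_distance must be positive")
    if scale_mode not in ("physical", "geometric"):
        raise DomainError("scale_mode must be 'physical' or 'geometric'")
    if not np.all(np.isfinite(screen.phase)):
        raise DataError("phase screen contains non-finite values")
    n = screen.n
    pitch_mm = screen.pitch * 1e-3
    lam_mm = (wavelength_nm or screen.wavelength_nm) * 1e-6
    extent_mm = n * pitch_mm

    coords = (np.arange(n) - n // 2) * pitch_mm
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    r2 = xx**2 + yy**2
    v_per_mm = input_vergence * 1e-3  # D -> 1/mm
    magnif = 1.0 + propagation_distance * v_per_mm
    if magnif <= 0:
        raise DomainError(
            f"vergence {input_vergence} D focuses the beam before the sensor "
            f"plane at {propagation_distance} mm"
        )

    if aperture_diameter_mm is None:
        aperture_diameter_mm = DEFAULT_APERTURE_FRACTION * extent_mm
    r0 = aperture_diameter_mm / 2.0
    aperture = np.exp(-((np.sqrt(r2) / r0) ** 8))

    if scale_mode == "physical":
        total_phase = screen.phase + np.pi * v_per_mm * r2 / lam_mm
        step = max(
            np.abs(np.diff(total_phase, axis=0)).max(initial=0.0),
            np.abs(np.diff(total_phase, axis=1)).max(initial=0.0),
        )
        if step >= np.pi:
            pitch_req = screen.pitch * np.pi / step * 0.99
            n_req = int(np.ceil(extent_mm * 1e3 / pitch_req))
            raise SamplingError(
                f"phase step {step:.2f} rad/sample exceeds pi: grid "
                f"undersampled; need pitch <= {pitch_req:.2f} um, i.e. a "
                f"grid of at least {n_req} samples to cover the same "
                f"aperture (or use scale_mode='geometric')"
            )
        field = aperture * np.exp(1j * total_phase)
        out = _angular_spectrum(field, pitch_mm, lam_mm, propagation_distance)
        intensity = np.abs(out) ** 2
    else:
        field = aperture * np.exp(1j * screen.phase)
        z_eff = propagation_distance / magnif
        out = _angular_spectrum(field, pitch_mm, lam_mm, z_eff)
        base = np.abs(out) ** 2
        c = n // 2
        rows = (np.arange(n) - c) / magnif + c
        cols = (np.arange(n) - c) / magnif + c
        intensity = map_coordinates(
            base, np.meshgrid(rows, cols, indexing="ij"), order=1, mode="constant"
        )
        intensity = np.clip(intensity, 0.0, None)
    total = intensity.sum()
    if total <= 0 or not np.isfinite(total):
        raise DataError("propagated field carries no energy")
    return intensity / total


def vergence_at_diffuser(
    epsilon: float,
    f_eye: float | None = None,
    constants: SystemConstants = DEFAULTS,
    relative: bool = True,
) -> float:
    """Wavefront vergence (D, diverging positive) at the diffuser plane.

    Light from a fundus point reaches the cornea as a spherical wave
    diverging from the fundus, V_in = 1/(f_eye - delta_z) = 1/f_eye +
    epsilon/1000 (1/mm) — the defocus relation again, which is how the
    eye's internal geometry is abstracted into epsilon.  The bundle is
    relayed through the fixed cornea->diffuser train
    M = T(dL3_D) @ [[A, B], [C, D]] by the paraxial vergence transform
    V' = (M21 + M22 V) / (M11 + M12 V).  With the as-built constants this
    reproduces exactly the divergence from the conjugate fundus plane,
    1/d_F'',D: about 12.6 D for an emmetropic eye, 11.0 D at -12 D of
    myopia, 14.2 D at +12 D of hyperopia — it is this vergence that scales
    the caustic.

    By default the *excess* over the emmetropic baseline is returned (0 at
    epsilon = 0, strictly monotone and sign-preserving in epsilon); pass
    ``relative=False`` for the absolute beam vergence used when simulating
    a PSF.
    """
    f = constants.f_eye if f_eye is None else f_eye
    if f <= 0:
        raise DomainError("f_eye must be positive")
    m = np.array([[1.0, constants.dL3_D], [0.0, 1.0]]) @ constants.abcd()

    def relay(v: float) -> float:
        den = m[0, 0] + m[0, 1] * v
        if abs(den) < 1e-12:
            raise DegenerateGeometryError("vergence relay pole: M11 + M12*V = 0")
        return (m[1, 0] + m[1, 1] * v) / den

    v_in = 1.0 / f + epsilon * 1e-3  # 1/mm, diverging from the fundus point
    v_out = relay(v_in)
    if relative:
        v_out -= relay(1.0 / f)
    return v_out * 1e3


@dataclass
class PSFStack:
    """Defocus-indexed set of unit-sum PSF images.

    ``psfs`` has shape (n_planes, n, n); ``delta_z`` (mm) and ``epsilon``
    (D) index the planes, consistent with each other through the defocus
    relation for ``f_lens``; entries are strictly ordered by epsilon.
    """

    psfs: np.ndarray
    delta_z: np.ndarray
    epsilon: np.ndarray
    f_lens: float
    wavelength_nm: float
    pitch: float
    provenance: str = "simulated"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.psfs = np.asarray(self.psfs, dtype=float)
        self.delta_z = np.asarray(self.delta_z, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if not (len(self.psfs) == len(self.delta_z) == len(self.epsilon)):
            raise DataError("psfs, delta_z and epsilon must have equal length")
        if len(self.psfs) == 0:
            raise DomainError("empty PSF stack")
        sums = self.psfs.reshape(len(self.psfs), -1).sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise DataError("every PSF must be normalized to unit sum")
        if np.any(self.psfs < -1e-12):
            raise DataError("PSF intensities must be non-negative")
        expected = np.array(
            [optics.defocus_error(dz, self.f_lens) for dz in self.delta_z]
        )
        if np.any(np.abs(expected - self.epsilon) > 1e-6):
            raise DataError("epsilon inconsistent with delta_z for f_lens")
        if np.any(np.diff(self.epsilon) <= 0):
            raise DataError("stack must be strictly ordered by epsilon")

    def __len__(self) -> int:
        return len(self.psfs)

    def index_nearest(self, epsilon: float, tol: float | None = None) -> int:
        """Index of the plane with epsilon closest to the request.

        With ``tol`` given, raises :class:`DomainError` if no plane is
        within that many diopters.
        """
        i = int(np.argmin(np.abs(self.epsilon - epsilon)))
        if tol is not None and abs(self.epsilon[i] - epsilon) > tol:
            raise DomainError(
                f"no PSF within {tol} D of epsilon = {epsilon} D "
                f"(nearest is {self.epsilon[i]:.3f} D)"
            )
        return i


def build_psf_stack(
    screen: PhaseScreen,
    delta_z_range: tuple[float, float] = (-12.0, 6.0),
    step: float = 0.05,
    f_lens: float | None = None,
    constants: SystemConstants = DEFAULTS,
    wavelength_nm: float | None = None,
    aperture_diameter_mm: float | None = None,
    scale_mode: str = "physical",
) -> PSFStack:
    """Simulate the axial calibration sweep and assemble the PSF stack.

    One caustic PSF per displacement sample over ``delta_z_range`` (mm,
    inclusive endpoints, default the bench sweep -12..+6 mm) at spacing
    ``step`` (mm, default 0.05); each sample's defocus error follows the
    defocus relation for ``f_lens`` (default the model cornea), and the
    vergence applied to the screen is the relayed excess vergence at the
    diffuser for that error.
    """
    if step <= 0:
        raise DomainError("step must be positive")
    zmin, zmax = delta_z_range
    if zmax < zmin:
        raise DomainError("empty delta_z range")
    f = constants.f_model if f_lens is None else f_lens
    lam = wavelength_nm or screen.wavelength_nm
    delta_z = np.arange(zmin, zmax + step / 2.0, step)
    eps = np.array([optics.defocus_error(dz, f) for dz in delta_z])
    psfs = np.stack(
        [
            caustic_psf(
                screen,
                propagation_distance=constants.dD_S,
                wavelength_nm=lam,
                input_vergence=vergence_at_diffuser(
                    e, constants=constants, relative=False
                ),
                aperture_diameter_mm=aperture_diameter_mm,
                scale_mode=scale_mode,
            )
            for e in eps
        ]
    )
    return PSFStack(
        psfs=psfs,
        delta_z=delta_z,
        epsilon=eps,
        f_lens=f,
        wavelength_nm=lam,
        pitch=screen.pitch,
        provenance="simulated",
        seed=screen.seed,
    )


def mtf_radial(psf: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Radially binned modulation transfer function of a PSF.

    Returns (spatial frequency in cycles/mm at the sensor, modulation),
    with modulation 1 at zero frequency.  Frequencies run to the grid
    Nyquist 1/(2*pitch).
    """
    psf = np.asarray(psf, dtype=float)
    if not np.all(np.isfinite(psf)):
        raise DataError("PSF contains non-finite values")
    n = psf.shape[0]
    otf = np.fft.fftshift(np.abs(np.fft.fft2(psf)))
    dc = otf[n // 2, n // 2]
    if dc <= 0:
        raise DataError("PSF has zero total intensity")
    otf /= dc
    idx = np.arange(n) - n // 2
    rr = np.rint(np.hypot(*np.meshgrid(idx, idx, indexing="ij"))).astype(int)
    nbins = n // 2 + 1
    mask = rr < nbins
    sums = np.bincount(rr[mask], weights=otf[mask], minlength=nbins)
    counts = np.bincount(rr[mask], minlength=nbins)
    modulation = sums / counts
    freq = np.arange(nbins) / (n * pitch * 1e-3)  # cycles/mm at the sensor
    return freq, modulation


def resolution_from_mtf(
    curve: tuple[np.ndarray, np.ndarray],
    noise_floor: float = 1e-3,
    epsilon: float = 0.0,
    constants: SystemConstants = DEFAULTS,
    f_eye: float | None = None,
) -> float:
    """Noise-floor-limited resolution on the fundus (lp/mm).

    The highest sensor-plane frequency whose modulation stays at or above
    ``noise_floor`` is mapped to the fundus through the sensor-pixel to
    object-pixel ratio delta / R(epsilon).  The curve is assumed sampled on
    the sensor pixel pitch ``constants.delta``.
    """
    if not (0.0 < noise_floor < 1.0):
        raise DomainError("noise_floor must lie strictly between 0 and 1")
    freq, modulation = curve
    passed = np.asarray(freq)[np.asarray(modulation) >= noise_floor]
    if passed.size == 0:
        return 0.0
    f_sensor = float(passed.max())  # cycles/mm at the sensor
    r_um = optics.object_pixel_size(epsilon, f_eye, constants)
    return f_sensor * constants.delta / r_um
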