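"""Forward measurement model and closed-form Tikhonov refocusing.

The sensor measurement in channel c of a fundus plane with defocus error
epsilon is modelled as a linear shift-invariant blur plus white Gaussian
noise:

    y_c = h_eps * x_c + n

and each channel is refocused by minimizing the Tikhonov objective

    argmin_x || y_c - h_eps * x ||_2^2 + mu || x ||_2^2

whose exact minimizer on a periodic grid is the regularized inverse filter

    x_hat = F^-1 { conj(H) Y / (|H|^2 + mu) }.

Deconvolving one measurement with every PSF in the calibration stack yields
a focal stack over defocus error, from which the sharpest slice is chosen
(see :mod:`diffuscope.focus`).

Boundary handling: the Fourier solution is circulant.  ``pad_mode='linear'``
(default) zero-pads scene and measurement by the PSF support before the
transform and crops back, which suppresses wraparound on extended scenes;
``pad_mode='circular'`` applies the literal periodic equation, which is the
exact inverse of a periodic forward model and the form checked against a
dense linear-algebra oracle in the tests.  PSF centre convention: the
geometric centre pixel (N//2, N//2), also for even sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .diffuser import PSFStack
from .errors import DataError, DomainError, GeometryError, IllPosedError

__all__ = [
    "Measurement",
    "ReconConfig",
    "FocalStack",
    "forward_measure",
    "tikhonov_deconvolve",
    "tikhonov_objective",
    "reconstruct_stack",
    "merge_color",
]

logger = logging.getLogger(__name__)

VALID_CHANNELS = ("red", "green", "blue", "nir")
PAD_MODES = ("linear", "circular")


@dataclass
class Measurement:
    """One single-channel sensor frame with its provenance."""

    image: np.ndarray
    channel: str
    exposure_ms: float = 40.0
    noise_sigma: float | None = None
    seed: int | None = None
    psf_stack_id: str | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise DataError("measurement image must be 2-D")
        if not np.all(np.isfinite(self.image)):
            raise DataError("measurement contains non-finite values")
        if self.channel not in VALID_CHANNELS:
            raise DataError(
                f"unknown channel '{self.channel}'; expected one of {VALID_CHANNELS}"
            )


@dataclass
class ReconConfig:
    """Per-channel regularization and reconstruction-grid settings.

    Default regularization strengths are the empirically balanced values for
    the three illumination channels: the high-contrast green channel needs
    the least smoothing, the low-signal blue channel the most.  The NIR
    channel shares the red setting (it is displayed as red).
    """

    mu: dict[str, float] = field(
        default_factory=lambda: {"red": 0.007, "green": 0.002, "blue": 0.02}
    )
    pad_mode: str = "linear"
    epsilon_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pad_mode not in PAD_MODES:
            raise DomainError(f"pad_mode must be one of {PAD_MODES}")
        for ch, m in self.mu.items():
            if m < 0:
                raise DomainError(f"mu for channel '{ch}' must be non-negative")

    def mu_for(self, channel: str) -> float:
        if channel == "nir":
            channel = "red"
        try:
            return self.mu[channel]
        except KeyError:
            raise DomainError(f"no regularization strength set for '{channel}'")


@dataclass
class FocalStack:
    """Per-defocus, per-channel reconstructions of one capture.

    ``reconstructions`` maps channel name to an array of shape
    (n_slices, H, W); ``epsilon`` gives the defocus error of each slice.
    ``sharpness`` and ``selected_index`` are filled by the focus module.
    """

    reconstructions: dict[str, np.ndarray]
    epsilon: np.ndarray
    mu: dict[str, float] = field(default_factory=dict)
    sharpness: np.ndarray | None = None
    selected_index: int | None = None

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        shapes = {a.shape for a in self.reconstructions.values()}
        if len(shapes) > 1:
            raise GeometryError("channels disagree on focal-stack shape")
        for ch, arr in self.reconstructions.items():
            if arr.shape[0] != len(self.epsilon):
                raise GeometryError(
                    f"channel '{ch}' has {arr.shape[0]} slices for "
                    f"{len(self.epsilon)} epsilon values"
                )

    @property
    def channels(self) -> list[str]:
        return list(self.reconstructions)

    def __len__(self) -> int:
        return len(self.epsilon)

    def slice_rgb(self, index: int) -> np.ndarray:
        """Display-ready RGB image of one slice (see :func:`merge_color`)."""
        r = self.reconstructions.get("red", self.reconstructions.get("nir"))
        g = self.reconstructions["green"]
        b = self.reconstructions["blue"]
        return merge_color(r[index], g[index], b[index])


def _embed_centered(h: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Embed (or crop) a PSF into ``shape`` keeping its centre at (N//2, N//2)."""
    out = np.zeros(shape)
    src = [slice(None), slice(None)]
    dst = [slice(None), slice(None)]
    for ax in range(2):
        hs, os_ = h.shape[ax], shape[ax]
        hc, oc = hs // 2, os_ // 2
        take = min(hs, os_)
        src[ax] = slice(hc - take // 2, hc - take // 2 + take)
        dst[ax] = slice(oc - take // 2, oc - take // 2 + take)
    out[tuple(dst)] = h[tuple(src)]
    return out


def _transfer(h: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Transfer function of ``h`` on a periodic grid of ``shape``."""
    return sfft.fft2(np.fft.ifftshift(_embed_centered(h, shape)))


def _check_pitch(scene_pitch: float | None, psf_pitch: float | None) -> None:
    if scene_pitch is not None and psf_pitch is not None:
        if abs(scene_pitch - psf_pitch) > 1e-6 * max(scene_pitch, psf_pitch):
            raise GeometryError(
                f"scene pitch {scene_pitch} um and PSF pitch {psf_pitch} um differ"
            )


def forward_measure(
    x: np.ndarray,
    h: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pad_mode: str = "linear",
    channel: str = "green",
    scene_pitch: float | None = None,
    psf_pitch: float | None = None,
) -> Measurement:
    """Simulate a sensor measurement: blur the scene with the PSF, add noise.

    ``pad_mode='linear'`` performs a linear convolution (zero-padded to
    scene + PSF support, cropped back to the scene frame); ``'circular'``
    wraps periodically.  Noise is i.i.d. Gaussian of the given sigma, drawn
    from ``numpy.random.default_rng(seed)``.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("scene contains non-finite values")
    if noise_sigma < 0:
        raise DomainError("noise_sigma must be non-negative")
    if pad_mode not in PAD_MODES:
        raise DomainError(f"pad_mode must be one of {PAD_MODES}")
    _check_pitch(scene_pitch, psf_pitch)

    if pad_mode == "circular":
        y = sfft.ifft2(sfft.fft2(x) * _transfer(h, x.shape)).real
    else:
        pshape = tuple(sfft.next_fast_len(nx + nh) for nx, nh in zip(x.shape, h.shape))
        xp = np.zeros(pshape)
        off = tuple(nh // 2 for nh in h.shape)
        xp[off[0] : off[0] + x.shape[0], off[1] : off[1] + x.shape[1]] = x
        yp = sfft.ifft2(sfft.fft2(xp) * _transfer(h, pshape)).real
        y = yp[off[0] : off[0] + x.shape[0], off[1] : off[1] + x.shape[1]]
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, y.shape)
    return Measurement(image=y, channel=channel, noise_sigma=noise_sigma, seed=seed)


def tikhonov_deconvolve(
    y: Measurement | np.ndarray,
    h: np.ndarray,
    mu: float,
    pad_mode: str = "linear",
) -> np.ndarray:
    """Closed-form Tikhonov-regularized deconvolution.

    Returns the exact global minimizer of ||y - h * x||^2 + mu ||x||^2 on
    the (padded) periodic grid, cropped back to the measurement frame.
    ``mu = 0`` (plain inverse filter) is allowed only when the transfer
    function is bounded away from zero.
    """
    img = y.image if isinstance(y, Measurement) else np.asarray(y, dtype=float)
    if not np.all(np.isfinite(img)):
        raise DataError("measurement contains non-finite values")
    if mu < 0:
        raise DomainError("mu must be non-negative")
    if pad_mode not in PAD_MODES:
        raise DomainError(f"pad_mode must be one of {PAD_MODES}")

    if pad_mode == "circular":
        pshape = img.shape
        yp = img
        off = (0, 0)
    else:
        pshape = tuple(
            sfft.next_fast_len(ny + nh) for ny, nh in zip(img.shape, h.shape)
        )
        off = tuple(nh // 2 for nh in h.shape)
        yp = np.zeros(pshape)
        yp[off[0] : off[0] + img.shape[0], off[1] : off[1] + img.shape[1]] = img

    H = _transfer(np.asarray(h, dtype=float), pshape)
    if mu == 0.0:
        hmin = np.abs(H).min()
        if hmin <= 1e-12:
            raise IllPosedError(
                f"mu = 0 requested but the transfer function reaches "
                f"|H| = {hmin:.3e}; the inverse filter is ill-posed"
            )
    xp = sfft.ifft2(np.conj(H) * sfft.fft2(yp) / (np.abs(H) ** 2 + mu)).real
    return xp[off[0] : off[0] + img.shape[0], off[1] : off[1] + img.shape[1]]


def tikhonov_objective(
    x: np.ndarray, y: np.ndarray, h: np.ndarray, mu: float, pad_mode: str = "circular"
) -> float:
    """Value of the Tikhonov objective ||y - h*x||^2 + mu ||x||^2."""
    resid = y - forward_measure(x, h, noise_sigma=0.0, pad_mode=pad_mode).image
    return float(np.sum(resid**2) + mu * np.sum(np.asarray(x) ** 2))


def reconstruct_stack(
    measurements: dict[str, Measurement],
    stack: PSFStack,
    config: ReconConfig | None = None,
) -> FocalStack:
    """Deconvolve each channel with each calibrated PSF into a focal stack.

    The reconstruction grid defaults to the stack's native epsilon grid;
    a custom ``config.epsilon_grid`` is matched to stack planes by nearest
    neighbour within 0.05 D (a request farther than that raises).
    """
    config = config or ReconConfig()
    shapes = {m.image.shape for m in measurements.values()}
    if len(shapes) != 1:
        raise GeometryError("measurement channels disagree on spatial shape")

    if config.epsilon_grid is None:
        indices = list(range(len(stack)))
        grid = stack.epsilon.copy()
    else:
        grid = np.asarray(config.epsilon_grid, dtype=float)
        indices = [stack.index_nearest(e, tol=0.05) for e in grid]
        grid = stack.epsilon[indices]

    recs: dict[str, np.ndarray] = {}
    n_dec = 0
    for ch, meas in measurements.items():
        mu = config.mu_for(ch)
        slices = [
            tikhonov_deconvolve(meas, stack.psfs[i], mu, config.pad_mode)
            for i in indices
        ]
        recs[ch] = np.stack(slices)
        n_dec += len(indices)
    logger.info(
        "reconstructed %d slices x %d channels (%d deconvolutions), "
        "mu=%s, pad_mode=%s, epsilon=[%.2f..%.2f] D",
        len(indices), len(measurements), n_dec,
        {c: config.mu_for(c) for c in measurements}, config.pad_mode,
        grid.min(), grid.max(),
    )
    return FocalStack(
        reconstructions=recs,
        epsilon=grid,
        mu={c: config.mu_for(c) for c in measurements},
    )


def merge_color(
    x_r: np.ndarray,
    x_g: np.ndarray,
    x_b: np.ndarray,
    mode: str = "rescale",
    percentiles: tuple[float, float] = (0.1, 99.9),
) -> np.ndarray:
    """Combine three channel reconstructions for display.

    ``mode='rescale'`` (default): each channel is clipped to the given
    percentile range, rescaled to [0, 1], and stacked into an (H, W, 3) RGB
    image.  ``mode='sum'``: the channels are summed and jointly rescaled to
    a single grayscale frame — the form used for resolution targets, where
    per-channel white balance is irrelevant.
    """
    chans = [np.asarray(a, dtype=float) for a in (x_r, x_g, x_b)]
    if len({a.shape for a in chans}) != 1:
        raise GeometryError("channel shapes differ")
    lo_p, hi_p = percentiles
    if not (0 <= lo_p < hi_p <= 100):
        raise DomainError("invalid percentile range")

    def rescale(a: np.ndarray) -> np.ndarray:
        lo, hi = np.percentile(a, [lo_p, hi_p])
        if hi <= lo:
            return np.zeros_like(a)
        return np.clip((a - lo) / (hi - lo), 0.0, 1.0)

    if mode == "sum":
        return rescale(sum(chans))
    if mode != "rescale":
        raise DomainError("mode must be 'rescale' or 'sum'")
    return np.stack([rescale(a) for a in chans], axis=-1)
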