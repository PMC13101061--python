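"""Raster and metadata I/O: TIFF/PNG images with JSON sidecars, PSF-stack
and focal-stack serialization, and run configuration.

Conventions: TIFF is the raster format for everything scientific (8/16-bit
integer or 32-bit float, multi-page for stacks); PNG is accepted for 8/16-bit
single frames.  Arbitrary metadata travels in a human-diffable JSON sidecar
at ``<image-path>.json``.  Arrays are row-major with the origin at the top
left and x = column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .diffuser import (
    DEFAULT_CORRELATION_UM,
    DEFAULT_DIVERGENCE_DEG,
    DEFAULT_PITCH_UM,
    DEFAULT_WAVELENGTH_NM,
    PSFStack,
)
from .errors import FormatError
from .optics import SystemConstants
from .recon import FocalStack, ReconConfig

__all__ = [
    "read_image",
    "write_image",
    "save_psf_stack",
    "load_psf_stack",
    "save_focal_stack",
    "load_focal_stack",
    "SimulationConfig",
    "RunConfig",
    "config_hash",
]

_TIFF_DTYPES = (np.uint8, np.uint16, np.float32)
_PNG_DTYPES = (np.uint8, np.uint16)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_image(path, image: np.ndarray, metadata: dict | None = None) -> None:
    """Write a 2-D image (or stack of 2-D pages) losslessly, plus sidecar.

    TIFF accepts uint8/uint16/float32 (multi-page via a 3-D array); PNG
    accepts uint8/uint16 single frames.  Anything else raises
    :class:`FormatError` naming the offender.
    """
    path = Path(path)
    image = np.asarray(image)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        if not any(image.dtype == np.dtype(d) for d in _TIFF_DTYPES):
            raise FormatError(
                f"unsupported TIFF dtype {image.dtype}; use uint8, uint16 or float32"
            )
        tifffile.imwrite(path, image, photometric="minisblack")
    elif suffix == ".png":
        if not any(image.dtype == np.dtype(d) for d in _PNG_DTYPES):
            raise FormatError(
                f"unsupported PNG dtype {image.dtype}; use uint8 or uint16"
            )
        if image.ndim != 2:
            raise FormatError("PNG supports single 2-D frames only")
        iio.imwrite(path, image)
    else:
        raise FormatError(f"unsupported image format '{suffix}' for {path.name}")
    if metadata is not None:
        _sidecar(path).write_text(json.dumps(metadata, indent=1, sort_keys=True))


def read_image(path) -> tuple[np.ndarray, dict | None]:
    """Read an image written by :func:`write_image`; returns (array, sidecar)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        image = tifffile.imread(path)
    elif suffix == ".png":
        image = iio.imread(path)
    else:
        raise FormatError(f"unsupported image format '{suffix}' for {path.name}")
    meta = None
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return image, meta


def save_psf_stack(path, stack: PSFStack) -> None:
    """Multi-page float32 TIFF (one page per defocus plane) + JSON sidecar."""
    meta = {
        "delta_z": stack.delta_z.tolist(),
        "epsilon": stack.epsilon.tolist(),
        "f_lens": stack.f_lens,
        "wavelength_nm": stack.wavelength_nm,
        "pitch": stack.pitch,
        "provenance": stack.provenance,
        "seed": stack.seed,
    }
    write_image(path, stack.psfs.astype(np.float32), meta)


def load_psf_stack(path) -> PSFStack:
    pages, meta = read_image(path)
    if meta is None:
        raise FormatError(f"PSF stack {path} is missing its JSON sidecar")
    pages = np.atleast_3d(pages)
    if pages.ndim == 3 and pages.shape[0] != len(meta["epsilon"]):
        pages = pages.reshape(len(meta["epsilon"]), *pages.shape[-2:])
    return PSFStack(
        psfs=pages.astype(float),
        delta_z=np.array(meta["delta_z"]),
        epsilon=np.array(meta["epsilon"]),
        f_lens=meta["f_lens"],
        wavelength_nm=meta["wavelength_nm"],
        pitch=meta["pitch"],
        provenance=meta.get("provenance", "measured"),
        seed=meta.get("seed"),
    )


def save_focal_stack(path, stack: FocalStack) -> None:
    """All slices of all channels as float32 pages (slice-major) + sidecar."""
    channels = stack.channels
    pages = np.stack(
        [stack.reconstructions[c][s] for s in range(len(stack)) for c in channels]
    )
    meta = {
        "epsilon": stack.epsilon.tolist(),
        "channels": channels,
        "mu": stack.mu,
        "sharpness": None if stack.sharpness is None else stack.sharpness.tolist(),
        "selected_index": stack.selected_index,
    }
    write_image(path, pages.astype(np.float32), meta)


def load_focal_stack(path) -> FocalStack:
    pages, meta = read_image(path)
    if meta is None:
        raise FormatError(f"focal stack {path} is missing its JSON sidecar")
    channels = meta["channels"]
    n_slices = len(meta["epsilon"])
    pages = pages.reshape(n_slices, len(channels), *pages.shape[-2:])
    recs = {c: pages[:, i].astype(float) for i, c in enumerate(channels)}
    stack = FocalStack(
        reconstructions=recs,
        epsilon=np.array(meta["epsilon"]),
        mu=meta.get("mu", {}),
        selected_index=meta.get("selected_index"),
    )
    if meta.get("sharpness") is not None:
        stack.sharpness = np.array(meta["sharpness"])
    return stack


@dataclass
class SimulationConfig:
    """Grid and diffuser parameters for the simulated calibration."""

    grid: int = 256
    pitch: float = DEFAULT_PITCH_UM
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    divergence_fwhm: float = DEFAULT_DIVERGENCE_DEG
    correlation_length: float = DEFAULT_CORRELATION_UM
    seed: int = 0
    delta_z_range: tuple[float, float] = (-12.0, 6.0)
    step: float = 2.0
    injected_epsilon: float = -8.6
    noise_sigma: float = 1e-4
    phantom_grid: int = 256


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    optics: SystemConstants = field(default_factory=SystemConstants)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # The synthetic demo world is periodic (phantom, blur and deconvolution
    # all live on the same FFT grid), so the demo defaults to the circular
    # boundary model; real extended scenes should use 'linear'.
    recon: ReconConfig = field(default_factory=lambda: ReconConfig(pad_mode="circular"))
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "optics": self.optics.to_dict(),
            "simulation": asdict(self.simulation),
            "recon": {
                "mu": dict(self.recon.mu),
                "pad_mode": self.recon.pad_mode,
                "epsilon_grid": None
                if self.recon.epsilon_grid is None
                else list(self.recon.epsilon_grid),
            },
            "log_level": self.log_level,
        }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = d.get("simulation", {})
        if "delta_z_range" in sim:
            sim = {**sim, "delta_z_range": tuple(sim["delta_z_range"])}
        rc = d.get("recon", {})
        grid = rc.get("epsilon_grid")
        recon = ReconConfig(
            mu=dict(rc.get("mu", ReconConfig().mu)),
            pad_mode=rc.get("pad_mode", "linear"),
            epsilon_grid=None if grid is None else np.asarray(grid, dtype=float),
        )
        return cls(
            optics=SystemConstants.from_dict(d.get("optics", {})),
            simulation=SimulationConfig(**sim),
            recon=recon,
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            source = Path(source).read_text()
        return cls.from_dict(json.loads(source))


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 digest of a run configuration."""
    return hashlib.sha256(config.to_json().encode()).hexdigest()
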