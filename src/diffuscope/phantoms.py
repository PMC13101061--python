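"""Synthetic ground-truth scenes: a fundus-like reflectance phantom and a
three-bar resolution target.

The fundus phantom emulates the gross reflectance structure a fundus camera
sees: a reddish background with correlated choroidal texture, a bright
elliptical optic disk, a darker macula, and a branching vessel tree whose
absorption is strongest in green (haemoglobin), so vessel Michelson contrast
is ordered green > red > blue.  The bar target is a plain ordered set of
three-dark-bar groups on bright ground — the readout a bar chart supports
(the finest group whose bars remain distinct) needs no licensed chart
layout.  Both generators are pure functions of (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DomainError

__all__ = ["FundusPhantom", "BarTarget", "make_fundus_phantom", "make_bar_target",
           "vessel_contrast"]

CHANNELS = ("red", "green", "blue")

# Background reflectance and vessel absorption depth per channel.  The depths
# set the vessel Michelson contrast depth/(2 - depth): green 0.60, red 0.18,
# blue 0.08 on full-depth vessel cores.
_BACKGROUND = {"red": 0.75, "green": 0.45, "blue": 0.22}
_VESSEL_DEPTH = {"red": 0.30, "green": 0.75, "blue": 0.15}
_DISK_LEVEL = {"red": 0.95, "green": 0.85, "blue": 0.50}


@dataclass
class FundusPhantom:
    """Three-channel reflectance scene with geometry metadata.

    ``channels`` maps 'red'/'green'/'blue' to [0, 1] reflectance arrays;
    ``pixel_size`` is the object-space pixel size on the fundus (um);
    ``features`` records the placed structures (optic disk centre/radius,
    macula centre, vessel polylines in pixel coordinates); ``vessel_mask``
    is the rasterized, anti-aliased vessel map in [0, 1] the channels were
    built from.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    features: dict
    seed: int
    vessel_mask: np.ndarray | None = None


@dataclass
class BarTarget:
    """Three-bar resolution target.

    ``groups`` is ordered by strictly increasing realized frequency; each
    entry records the realized lp/mm on the fundus, the integer pixel period
    actually rendered, and the pixel box of the group's bars.
    """

    image: np.ndarray
    groups: list[dict]
    pixel_size: float


def _stamp_polyline(mask: np.ndarray, points: np.ndarray, widths: np.ndarray) -> None:
    """Stamp filled disks of the given radii along a polyline (in place)."""
    n = mask.shape[0]
    for (r, c), w in zip(points, widths):
        rad = max(1.0, w)
        r0, r1 = int(max(0, r - rad)), int(min(n, r + rad + 1))
        c0, c1 = int(max(0, c - rad)), int(min(n, c + rad + 1))
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2


def _vessel_tree(rng: np.random.Generator, n: int, origin: tuple[float, float]):
    """Random-walk vessel tree of decreasing caliber rooted at the disk."""
    polylines = []
    mask = np.zeros((n, n), dtype=bool)
    n_main = 6
    base_angles = rng.uniform(0, 2 * np.pi, n_main)
    for ang0 in base_angles:
        queue = [(np.array(origin, dtype=float), ang0, 0.012 * n, 0)]
        while queue:
            pos, ang, width, depth = queue.pop()
            pts, widths = [], []
            step = 0.02 * n
            for _ in range(rng.integers(15, 30)):
                ang += rng.normal(0.0, 0.25)
                pos = pos + step * np.array([np.sin(ang), np.cos(ang)])
                if not (0 <= pos[0] < n and 0 <= pos[1] < n):
                    break
                pts.append(pos.copy())
                widths.append(width)
                width *= 0.985
            if pts:
                pts = np.array(pts)
                _stamp_polyline(mask, pts, np.array(widths))
                polylines.append(pts.tolist())
                if depth < 2 and rng.random() < 0.7:
                    split = rng.normal(0.6, 0.1)
                    queue.append((pts[-1], ang + split, width * 0.75, depth + 1))
                    queue.append((pts[-1], ang - split, width * 0.75, depth + 1))
    soft = gaussian_filter(mask.astype(float), 0.8)
    return np.clip(soft / max(soft.max(), 1e-12), 0.0, 1.0), polylines, mask


def make_fundus_phantom(
    seed: int, n: int = 512, pixel_size: float = 26.4
) -> FundusPhantom:
    """Generate a fundus-like reflectance phantom.

    ``pixel_size`` (um on the fundus) only tags the geometry metadata; the
    rendering itself is in pixels.  Raises :class:`DomainError` for grids
    under 128 pixels, where the features become unresolvable.
    """
    if n < 128:
        raise DomainError("fundus phantom needs a grid of at least 128 pixels")
    if pixel_size <= 0:
        raise DomainError("pixel_size must be positive")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    # Optic disk: bright ellipse, displaced temporally from centre.
    disk_c = (n * (0.5 + rng.normal(0, 0.02)), n * (0.64 + rng.normal(0, 0.02)))
    disk_r = n * 0.065
    d_disk = np.hypot((yy - disk_c[0]) / 1.1, xx - disk_c[1]) / disk_r
    disk = 1.0 / (1.0 + np.exp((d_disk - 1.0) * 8.0))  # soft-edged ellipse

    # Macula: broad dark depression on the opposite side.
    mac_c = (n * (0.5 + rng.normal(0, 0.02)), n * (0.30 + rng.normal(0, 0.02)))
    mac_r = n * 0.11
    macula = np.exp(-(((yy - mac_c[0]) ** 2 + (xx - mac_c[1]) ** 2) / (2 * mac_r**2)))

    vessels, polylines, core = _vessel_tree(rng, n, disk_c)

    # Low-amplitude correlated background texture (choroidal mottling).
    texture = gaussian_filter(rng.standard_normal((n, n)), n / 64.0)
    texture /= max(np.abs(texture).max(), 1e-12)

    channels: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        img = np.full((n, n), _BACKGROUND[ch])
        img += 0.04 * texture * _BACKGROUND[ch] / _BACKGROUND["red"]
        img *= 1.0 - 0.18 * macula  # macula darkening
        img = img * (1.0 - disk) + _DISK_LEVEL[ch] * disk
        img *= 1.0 - _VESSEL_DEPTH[ch] * vessels
        channels[ch] = np.clip(img, 0.0, 1.0)

    features = {
        "optic_disk": {"center": list(disk_c), "radius": disk_r},
        "macula": {"center": list(mac_c), "radius": mac_r},
        "vessel_polylines": polylines,
    }
    return FundusPhantom(channels, pixel_size, features, seed, vessel_mask=vessels)


def vessel_contrast(phantom: FundusPhantom) -> dict[str, float]:
    """Michelson vessel-vs-background contrast per channel.

    Measured on the phantom's own vessel raster: vessel pixels are full-depth
    cores (mask > 0.99), background pixels are far from every rendered
    feature.  Returns {channel: (bg - vessel) / (bg + vessel)}.
    """
    if phantom.vessel_mask is None:
        raise DomainError("phantom carries no vessel raster")
    n = phantom.vessel_mask.shape[0]
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    disk = phantom.features["optic_disk"]
    mac = phantom.features["macula"]
    d_disk = np.hypot(yy - disk["center"][0], xx - disk["center"][1])
    d_mac = np.hypot(yy - mac["center"][0], xx - mac["center"][1])
    # vessels crossing the bright disk would bias the estimate; sample
    # full-depth cores away from the disk only
    vessel_px = (phantom.vessel_mask > 0.99) & (d_disk > 1.8 * disk["radius"])
    bg_px = (
        (phantom.vessel_mask < 1e-6)
        & (d_disk > 2.5 * disk["radius"])
        & (d_mac > 2.5 * mac["radius"])
    )
    out = {}
    for ch, img in phantom.channels.items():
        v = float(img[vessel_px].mean())
        b = float(img[bg_px].mean())
        out[ch] = (b - v) / (b + v)
    return out


def make_bar_target(
    frequencies: list[float], n: int = 512, pixel_size: float = 26.4
) -> BarTarget:
    """Render ordered three-bar groups at the requested fundus frequencies.

    Each group is three dark bars (width = half the period, rounded down)
    on bright ground, with the period rounded to the nearest achievable
    integer pixel count; the metadata records the *realized* frequency
    1/(period_px * pixel_size).  Frequencies above the fundus-plane Nyquist
    1/(2*pixel_size) raise :class:`DomainError`, as do requests that
    collide onto the same integer period.
    """
    if not frequencies:
        raise DomainError("at least one frequency is required")
    if pixel_size <= 0:
        raise DomainError("pixel_size must be positive")
    ps_mm = pixel_size * 1e-3
    nyquist = 1.0 / (2.0 * ps_mm)
    freqs = sorted(float(f) for f in frequencies)
    image = np.ones((n, n))
    groups: list[dict] = []

    band = n // (len(freqs) + 1)
    bar_len = max(8, int(0.6 * band))
    for k, f_req in enumerate(freqs):
        if f_req <= 0:
            raise DomainError("frequencies must be positive")
        if f_req > nyquist:
            raise DomainError(
                f"{f_req:.2f} lp/mm exceeds the fundus-plane Nyquist "
                f"{nyquist:.2f} lp/mm at pixel_size = {pixel_size} um"
            )
        period_px = int(round(1.0 / (f_req * ps_mm)))
        period_px = max(2, period_px)
        realized = 1.0 / (period_px * ps_mm)
        if groups and period_px == groups[-1]["period_px"]:
            raise DomainError(
                f"frequencies {groups[-1]['requested_lp_mm']:.2f} and "
                f"{f_req:.2f} lp/mm collide on a {period_px}-pixel period"
            )
        bar_w = max(1, period_px // 2)
        width_px = 2 * period_px + bar_w
        row0 = (k + 1) * band - bar_len // 2
        col0 = (n - width_px) // 2
        if col0 < 0 or row0 < 0 or row0 + bar_len > n:
            raise DomainError(
                f"group at {f_req:.2f} lp/mm does not fit an {n}-pixel grid"
            )
        for b in range(3):
            c = col0 + b * period_px
            image[row0 : row0 + bar_len, c : c + bar_w] = 0.0
        groups.append(
            {
                "frequency_lp_mm": realized,
                "requested_lp_mm": f_req,
                "period_px": period_px,
                "bar_width_px": bar_w,
                "row0": row0,
                "row1": row0 + bar_len,
                "col0": col0,
                "col1": col0 + width_px,
                "orientation": "vertical",
            }
        )
    return BarTarget(image=image, groups=groups, pixel_size=pixel_size)
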