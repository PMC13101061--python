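"""Sharpness scoring, autofocus over a focal stack, and bar-target readout.

After refocusing, the correctly matched defocus slice is the sharpest image
in the stack.  Sharpness is scored by the variance of the discrete
Laplacian of the mean-normalized image — a standard, intensity-scale-
invariant focus metric (a gradient-energy alternative is provided, since no
single metric is canonical).  Resolution on a three-bar target is read out
as the finest group whose averaged perpendicular profile keeps Michelson
contrast above a threshold with all three bars producing distinct minima;
when the scene sat behind the 25.4 mm bench model cornea, the readout can
be rescaled by f_model / f_eye to the equivalent resolution in a human eye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import laplace
from scipy.signal import find_peaks

from .errors import DomainError, GeometryError
from .optics import DEFAULTS, SystemConstants
from .phantoms import BarTarget
from .recon import FocalStack

__all__ = [
    "FocusReport",
    "ResolutionReadout",
    "sharpness_score",
    "gradient_energy",
    "select_focus",
    "read_resolution",
]

logger = logging.getLogger(__name__)


@dataclass
class FocusReport:
    """Outcome of an autofocus search over a focal stack."""

    epsilon_selected: float
    index: int
    scores: np.ndarray
    confidence: float
    channel: str
    low_confidence: bool = False


@dataclass
class ResolutionReadout:
    """Resolution estimate from a three-bar target reconstruction.

    ``resolved_lp_mm`` is the finest group passing the resolved criterion
    (0.0 when none does); ``per_group_contrast`` lists (frequency, Michelson
    contrast) for every group; ``eye_equivalent_lp_mm`` is the resolved
    value rescaled by f_model / f_eye when the eye correction was requested.
    """

    resolved_lp_mm: float
    per_group_contrast: list[tuple[float, float]]
    eye_equivalent_lp_mm: float | None
    contrast_threshold: float


def sharpness_score(image: np.ndarray) -> float:
    """Variance of the Laplacian of the mean-normalized image.

    Invariant to positive global intensity scaling; a constant image scores
    exactly 0.
    """
    img = np.asarray(image, dtype=float)
    mean = img.mean()
    if mean == 0 or np.ptp(img) == 0:
        return 0.0
    return float(laplace(img / abs(mean)).var())


def gradient_energy(image: np.ndarray) -> float:
    """Alternative focus metric: mean squared gradient of the normalized image."""
    img = np.asarray(image, dtype=float)
    mean = img.mean()
    if mean == 0 or np.ptp(img) == 0:
        return 0.0
    gy, gx = np.gradient(img / abs(mean))
    return float(np.mean(gx**2 + gy**2))


def select_focus(
    stack: FocalStack,
    channel: str = "green",
    metric=sharpness_score,
    margin: float = 0.1,
    confidence_threshold: float = 1.0,
) -> FocusReport:
    """Pick the sharpest slice of a focal stack.

    Scores every slice of ``channel`` (default green, the highest-contrast
    channel) with ``metric`` after trimming a boundary margin (fraction of
    the frame; deconvolution edge artifacts would otherwise dominate), and
    selects the argmax; ties break toward the slice with epsilon nearest 0.
    Confidence is the ratio of the best score to the median score; below
    ``confidence_threshold`` a warning is logged and flagged.
    """
    if len(stack) == 0:
        raise DomainError("empty focal stack")
    if channel not in stack.reconstructions:
        raise DomainError(
            f"channel '{channel}' not in stack (has {stack.channels})"
        )
    slices = stack.reconstructions[channel]
    m = int(round(margin * slices.shape[1]))
    view = slices[:, m : slices.shape[1] - m, m : slices.shape[2] - m] if m else slices
    scores = np.array([metric(s) for s in view])

    best = scores.max()
    tied = np.flatnonzero(scores == best)
    index = int(tied[np.argmin(np.abs(stack.epsilon[tied]))])
    med = float(np.median(scores))
    confidence = float(best / med) if med > 0 else float("inf")
    low = confidence < confidence_threshold
    if low:
        logger.warning(
            "autofocus confidence %.3f below threshold %.3f; the stack may "
            "contain no focused content", confidence, confidence_threshold,
        )
    stack.sharpness = scores
    stack.selected_index = index
    return FocusReport(
        epsilon_selected=float(stack.epsilon[index]),
        index=index,
        scores=scores,
        confidence=confidence,
        channel=channel,
        low_confidence=low,
    )


def _group_profile(recon: np.ndarray, group: dict) -> np.ndarray:
    """Averaged profile across a group's bars (perpendicular to the bars)."""
    pad = group["period_px"]
    c0 = max(0, group["col0"] - pad)
    c1 = min(recon.shape[1], group["col1"] + pad)
    box = recon[group["row0"] : group["row1"], c0:c1]
    return box.mean(axis=0)


def read_resolution(
    recon: np.ndarray,
    target: BarTarget,
    contrast_threshold: float = 0.1,
    apply_eye_correction: bool = False,
    constants: SystemConstants = DEFAULTS,
) -> ResolutionReadout:
    """Finest resolved bar group of a reconstructed target.

    For each group, the profile perpendicular to the bars (averaged along
    them) yields a Michelson contrast (max - min)/(max + min); a group is
    resolved iff that contrast reaches ``contrast_threshold`` AND all three
    bars produce distinct local minima in the profile.  When
    ``apply_eye_correction`` is set, the result is multiplied by
    f_model / f_eye to translate bench resolution to the human eye.
    """
    recon = np.asarray(recon, dtype=float)
    if not (0 < contrast_threshold < 1):
        raise DomainError("contrast_threshold must lie in (0, 1)")
    if recon.shape != target.image.shape:
        raise GeometryError(
            f"reconstruction shape {recon.shape} does not match target "
            f"{target.image.shape}"
        )
    per_group: list[tuple[float, float]] = []
    resolved = 0.0
    for group in target.groups:
        profile = _group_profile(recon, group)
        hi, lo = profile.max(), profile.min()
        contrast = (hi - lo) / (hi + lo) if hi + lo > 0 else 0.0
        per_group.append((group["frequency_lp_mm"], float(contrast)))
        minima, _ = find_peaks(
            -profile,
            distance=max(1, int(0.6 * group["period_px"])),
            prominence=contrast_threshold * (hi + lo) / 2.0,
        )
        if contrast >= contrast_threshold and len(minima) >= 3:
            resolved = max(resolved, group["frequency_lp_mm"])
    if resolved == 0.0:
        logger.warning("no bar group resolved at threshold %.2f", contrast_threshold)
    eye = None
    if apply_eye_correction:
        eye = resolved * constants.f_model / constants.f_eye
    return ResolutionReadout(
        resolved_lp_mm=resolved,
        per_group_contrast=per_group,
        eye_equivalent_lp_mm=eye,
        contrast_threshold=contrast_threshold,
    )
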