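"""Paraxial ray-matrix model of the eye-to-diffuser imaging train.

The eye is treated as a reduced thin lens of power ~60 D (focal length
``f_eye`` = 16.7 mm).  A refractive error is modelled as an axial
displacement ``delta_z`` of the fundus from the back focal plane of that
lens; the corresponding defocus error in diopters is the difference in
vergence between the displaced and the in-focus fundus point:

    epsilon = 1000 * (1 / (f - delta_z) - 1 / f)        [D, f and delta_z in mm]

The fixed optical train from the cornea to the final relay lens L3 is a
single ray-transfer matrix [[A, B], [C, D]].  Composing it with free-space
propagations on either side and applying the imaging condition yields the
conjugate fundus plane F'' behind L3, the lateral magnification fundus -> F'',
and finally the object-space pixel size R on the fundus:

    d_L3,F'' = -(A*(f_eye - dz) + B) / (C*(f_eye - dz) + D)
    M_L      = A + C * d_L3,F''
    R        = (d_F'',D / d_D,S) * (1 / M_L) * delta

where d_F'',D = d_L3,D - d_L3,F'' is the distance from the conjugate fundus
plane to the diffuser, d_D,S the diffuser-to-sensor distance, and delta the
sensor pixel pitch.  Theoretical resolution on the fundus scales inversely
with R, anchored at the emmetropic value.

Units: all distances are millimetres internally except the sensor pitch and
pixel size (micrometres, as they are quoted); diopters are reciprocal metres,
with the single mm -> m factor of 1000 applied inside :func:`defocus_error`.
Sign convention: positive ``delta_z`` displaces the fundus toward the lens
(a shorter, hyperopic eye) and yields positive ``epsilon``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import DegenerateGeometryError, DomainError

__all__ = [
    "SystemConstants",
    "DefocusState",
    "ImagingGeometry",
    "defocus_error",
    "displacement_for_defocus",
    "conjugate_distance",
    "lateral_magnification",
    "imaging_geometry",
    "object_pixel_size",
    "theoretical_resolution",
    "fov_estimate",
    "system_matrix",
]

#: Emmetropic theoretical-resolution anchor on the fundus, lp/mm.
DEFAULT_RESOLUTION_ANCHOR = 12.5


@dataclass(frozen=True)
class SystemConstants:
    """Fixed paraxial description of the cornea-to-sensor train.

    Defaults are the as-built values of the instrument this package models:
    the cornea->L3 ray-transfer matrix elements ``A`` (dimensionless), ``B``
    (mm), ``C`` (1/mm), ``D`` (dimensionless); the L3->diffuser and
    diffuser->sensor distances (mm); the sensor pixel pitch ``delta`` (um);
    and the focal lengths (mm) of the reduced in-vivo eye, the 25.4 mm
    bench model cornea, and the HEINE model eye.
    """

    A: float = 1.340
    B: float = -40.98
    C: float = 0.0125
    D: float = 0.3654
    dL3_D: float = 111.6
    dD_S: float = 11.0
    delta: float = 6.4
    f_eye: float = 16.7
    f_model: float = 25.4
    f_heine: float = 18.0

    def __post_init__(self) -> None:
        if self.dL3_D <= 0 or self.dD_S <= 0:
            raise DomainError("relay distances dL3_D and dD_S must be positive")
        if self.delta <= 0:
            raise DomainError("sensor pixel pitch delta must be positive")
        for name in ("f_eye", "f_model", "f_heine"):
            if getattr(self, name) <= 0:
                raise DomainError(f"focal length {name} must be positive")

    def abcd(self) -> np.ndarray:
        """The cornea->L3 ray-transfer matrix [[A, B], [C, D]]."""
        return np.array([[self.A, self.B], [self.C, self.D]], dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SystemConstants":
        return cls(**d)


#: Module-wide default constants (the as-built system).
DEFAULTS = SystemConstants()


@dataclass(frozen=True)
class DefocusState:
    """A (delta_z, epsilon) pair that is self-consistent for a given lens.

    ``delta_z`` is the signed axial fundus displacement from the back focal
    plane (mm), ``epsilon`` the defocus error (D), ``f_lens`` the focal
    length the pair is defined against (mm).
    """

    delta_z: float
    epsilon: float
    f_lens: float

    def __post_init__(self) -> None:
        if abs(defocus_error(self.delta_z, self.f_lens) - self.epsilon) > 1e-9:
            raise DomainError(
                "inconsistent DefocusState: epsilon does not match delta_z"
            )

    @classmethod
    def from_delta_z(cls, delta_z: float, f_lens: float) -> "DefocusState":
        return cls(delta_z, defocus_error(delta_z, f_lens), f_lens)

    @classmethod
    def from_epsilon(cls, epsilon: float, f_lens: float) -> "DefocusState":
        return cls(displacement_for_defocus(epsilon, f_lens), epsilon, f_lens)


@dataclass(frozen=True)
class ImagingGeometry:
    """Derived conjugate geometry for one defocus state.

    Fields: L3 -> conjugate-fundus-plane distance (mm), lateral magnification
    fundus -> F'' (dimensionless), conjugate-plane -> diffuser distance (mm),
    and object-space pixel size on the fundus (um).
    """

    d_L3_Fpp: float
    M_L: float
    d_Fpp_D: float
    R: float


def defocus_error(delta_z: float, f_lens: float) -> float:
    """Defocus error (D) for a fundus displaced ``delta_z`` mm from the back
    focal plane of a lens with focal length ``f_lens`` mm.

    The error is the difference in optical power between the displaced and
    the in-focus configuration, 1/(f - dz) - 1/f, converted from 1/mm to
    diopters.  Positive displacement (toward the lens) gives hyperopic,
    positive error.
    """
    if f_lens <= 0:
        raise DomainError("f_lens must be positive")
    if delta_z >= f_lens:
        raise DomainError(
            f"delta_z = {delta_z} mm places the fundus at or beyond optical "
            f"infinity for f_lens = {f_lens} mm"
        )
    return 1000.0 * (1.0 / (f_lens - delta_z) - 1.0 / f_lens)


def displacement_for_defocus(epsilon: float, f_lens: float) -> float:
    """Axial displacement (mm) producing defocus error ``epsilon`` (D).

    Exact algebraic inverse of :func:`defocus_error`:
    delta_z = f - 1 / (1/f + epsilon/1000).
    """
    if f_lens <= 0:
        raise DomainError("f_lens must be positive")
    power = 1.0 / f_lens + epsilon / 1000.0  # 1/mm
    if power <= 0:
        raise DomainError(
            f"epsilon = {epsilon} D has no finite fundus position for "
            f"f_lens = {f_lens} mm (requires epsilon > {-1000.0 / f_lens:.3f} D)"
        )
    return f_lens - 1.0 / power


def system_matrix(
    delta_z: float, d_L3_Fpp: float, f_eye: float, constants: SystemConstants = DEFAULTS
) -> np.ndarray:
    """Ray-transfer matrix H from the fundus to a plane ``d_L3_Fpp`` behind L3.

    H = T(d_L3_Fpp) @ [[A, B], [C, D]] @ T(f_eye - delta_z), where T(d) is
    free-space propagation over d.  At the conjugate plane the upper-right
    element of H vanishes (imaging condition).
    """

    def t(d: float) -> np.ndarray:
        return np.array([[1.0, d], [0.0, 1.0]])

    return t(d_L3_Fpp) @ constants.abcd() @ t(f_eye - delta_z)


def conjugate_distance(
    delta_z: float, f_eye: float | None = None, constants: SystemConstants = DEFAULTS
) -> float:
    """Distance (mm) from L3 to the conjugate fundus plane F''.

    Solves the imaging condition on the fundus -> F'' system matrix:
    d = -(A*(f_eye - dz) + B) / (C*(f_eye - dz) + D).
    """
    f = constants.f_eye if f_eye is None else f_eye
    u = f - delta_z
    den = constants.C * u + constants.D
    if abs(den) < 1e-12:
        raise DegenerateGeometryError(
            "conjugate plane at infinity: C*(f_eye - delta_z) + D vanishes"
        )
    return -(constants.A * u + constants.B) / den


def lateral_magnification(
    d_L3_Fpp: float, constants: SystemConstants = DEFAULTS
) -> float:
    """Lateral magnification fundus -> F'': M_L = A + C * d_L3,F''."""
    return constants.A + constants.C * d_L3_Fpp


def imaging_geometry(
    epsilon: float, f_eye: float | None = None, constants: SystemConstants = DEFAULTS
) -> ImagingGeometry:
    """Full conjugate geometry for a defocus error ``epsilon`` (D)."""
    f = constants.f_eye if f_eye is None else f_eye
    dz = displacement_for_defocus(epsilon, f)
    d = conjugate_distance(dz, f, constants)
    m = lateral_magnification(d, constants)
    if abs(m) < 1e-12:
        raise DegenerateGeometryError("vanishing lateral magnification")
    d_fpp_d = constants.dL3_D - d
    r = (d_fpp_d / constants.dD_S) * (1.0 / m) * constants.delta
    if r <= 0:
        raise DegenerateGeometryError(
            f"non-positive object pixel size R = {r:.4g} um at epsilon = {epsilon} D"
        )
    return ImagingGeometry(d_L3_Fpp=d, M_L=m, d_Fpp_D=d_fpp_d, R=r)


def object_pixel_size(
    epsilon: float, f_eye: float | None = None, constants: SystemConstants = DEFAULTS
) -> float:
    """Object-space pixel size R on the fundus (um) at defocus error ``epsilon``."""
    return imaging_geometry(epsilon, f_eye, constants).R


def theoretical_resolution(
    epsilon: float,
    anchor_lp_mm: float = DEFAULT_RESOLUTION_ANCHOR,
    f_eye: float | None = None,
    constants: SystemConstants = DEFAULTS,
) -> float:
    """Theoretical resolution on the fundus (lp/mm) at defocus error ``epsilon``.

    Resolution varies with defocus purely through the system magnification, so
    it scales inversely with the object-space pixel size:
    anchor * R(0) / R(epsilon), with ``anchor_lp_mm`` the emmetropic value
    (default 12.5 lp/mm for the as-built system).
    """
    if anchor_lp_mm <= 0:
        raise DomainError("anchor_lp_mm must be positive")
    r0 = object_pixel_size(0.0, f_eye, constants)
    return anchor_lp_mm * r0 / object_pixel_size(epsilon, f_eye, constants)


def fov_estimate(
    n_pixels: int,
    epsilon: float = 0.0,
    f_eye: float | None = None,
    constants: SystemConstants = DEFAULTS,
) -> float:
    """Full visual-cone field of view (degrees) spanned by ``n_pixels``.

    Maps the pixel count through the object-space pixel size to a fundus
    extent and converts to visual angle: 2*atan(n*R/2 / f_eye).  This is a
    paraxial estimate from pixel size and eye focal length only; it ignores
    pupil-relay vignetting, so it bounds rather than reproduces a full
    ray-traced field of view.
    """
    if n_pixels < 0:
        raise DomainError("n_pixels must be non-negative")
    if n_pixels == 0:
        return 0.0
    f = constants.f_eye if f_eye is None else f_eye
    extent_mm = n_pixels * object_pixel_size(epsilon, f, constants) / 1000.0
    return math.degrees(2.0 * math.atan(extent_mm / 2.0 / f))
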