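"""Angular bookkeeping for the tilted three-microscope train.

Conventions (fixed throughout the package): the O1 optical axis is the lab
z-axis, the light-sheet is tilted about x, and the sheet plane makes the
inclination ``alpha`` with the O1 focal (xy) plane.  The O3 axis is normal to
the sheet, i.e. the unit vector (0, -sin(alpha), cos(alpha)) in lab
coordinates; the "tilted frame" is the right-handed frame whose z-axis is the
O3 axis and whose x-axis coincides with the lab x-axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import K_LS, SystemConfig

__all__ = [
    "abbe_remap",
    "snell",
    "tilt_matrix",
    "EffectivePupil",
    "effective_pupil",
    "lightsheet_geometry",
]

#: Rays closer than this to grazing incidence on the O2->O3 interface are
#: treated as vignetted (the 1/cos obliquity factor diverges at the rim and
#: such rays carry no usable power).
GRAZING_LIMIT = math.radians(89.5)


class GeometryError(ValueError):
    """Raised for unimageable configurations (empty pupil, no sheet aperture)."""


def abbe_remap(theta, na, na_prime, n):
    """Map objective-side ray angles to tube-lens-side angles.

    For a microscope whose objective (numerical aperture ``na``, immersion
    ``n``) and tube lens (``na_prime``) share a back focal plane and both obey
    the Abbe sine condition, a ray at polar angle ``theta`` on the objective
    side emerges at ``theta' = arcsin((na'/na) * n * sin(theta))``.

    Rays whose sine argument exceeds 1 are vignetted at the tube lens and
    returned as NaN.
    """
    s = (na_prime / na) * n * np.sin(theta)
    with np.errstate(invalid="ignore"):
        out = np.arcsin(s)
    return np.where(np.abs(s) <= 1.0, out, np.nan)


def snell(theta, n_from, n_to):
    """Refraction angle across a planar index change; NaN beyond TIR."""
    s = n_from * np.sin(theta) / n_to
    with np.errstate(invalid="ignore"):
        out = np.arcsin(s)
    return np.where(np.abs(s) <= 1.0, out, np.nan)


def tilt_matrix(alpha: float) -> np.ndarray:
    """Rotation taking lab-frame components to tilted-frame components.

    The tilted frame's z-axis is the O3 axis (0, -sin a, cos a) in the lab;
    the returned matrix R satisfies R @ (0, -sin a, cos a) = (0, 0, 1).
    """
    c, s = math.cos(alpha), math.sin(alpha)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])


@dataclass
class EffectivePupil:
    """Boolean acceptance mask over a direction grid in the O1 cone.

    ``area_fraction`` is the accepted solid angle divided by the solid angle
    of the O1 cap clipped to the O2 acceptance (the best any tertiary
    microscope could pass).
    """

    theta: np.ndarray
    phi: np.ndarray
    weight: np.ndarray
    mask: np.ndarray
    area_fraction: float


def direction_grid(theta_max: float, n_theta: int = 200, n_phi: int = 400):
    """Equal-weight quadrature grid over a spherical cap of half-angle theta_max.

    Gauss-Legendre in cos(theta) x midpoint in phi; weights sum to the exact
    cap solid angle.
    """
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    c0 = math.cos(theta_max)
    cos_t = 0.5 * (x + 1.0) * (1.0 - c0) + c0
    w_t = wx * 0.5 * (1.0 - c0)
    phi = (np.arange(n_phi) + 0.5) * (2 * math.pi / n_phi)
    w_phi = 2 * math.pi / n_phi
    theta_g, phi_g = np.meshgrid(np.arccos(cos_t), phi, indexing="ij")
    w = np.broadcast_to((w_t * w_phi)[:, None], theta_g.shape).copy()
    return theta_g, phi_g, w


def pupil_mask(config: SystemConfig, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Acceptance test for rays given by O1-side direction (theta, phi).

    A ray survives if it is inside the O1 and O2 acceptance cones (the
    O1->O2 relay preserves the polar angle), reaches the tilted O2->O3
    interface below grazing incidence, and refracts into the O3 acceptance
    cone.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    ok = (theta <= config.theta1_max + 1e-12) & (theta <= config.theta2_max + 1e-12)
    # direction in tilted frame; polar angle from O3 axis = incidence angle
    st, ct = np.sin(theta), np.cos(theta)
    d = np.stack([st * np.cos(phi), st * np.sin(phi), ct], axis=-1)
    dt = d @ tilt_matrix(config.alpha).T
    cos_inc = np.clip(dt[..., 2], -1.0, 1.0)
    theta_inc = np.arccos(cos_inc)
    ok &= theta_inc < GRAZING_LIMIT
    # refract remote medium -> O3 immersion, require inside O3 cone
    ok &= config.n2 * np.sin(theta_inc) <= config.na3 + 1e-12
    return ok


def effective_pupil(config: SystemConfig, n_theta: int = 200, n_phi: int = 400) -> EffectivePupil:
    """Angular overlap of the O2 acceptance and the tilted O3 acceptance.

    Raises :class:`GeometryError` if the overlap is empty (unimageable
    configuration).
    """
    theta_det = min(config.theta1_max, config.theta2_max)
    theta, phi, w = direction_grid(theta_det, n_theta, n_phi)
    mask = pupil_mask(config, theta, phi)
    total = w.sum()
    accepted = w[mask].sum()
    if accepted == 0.0:
        raise GeometryError("empty O2/O3 pupil overlap: configuration cannot image")
    return EffectivePupil(theta, phi, w, mask, float(accepted / total))


def lightsheet_geometry(config: SystemConfig) -> tuple[float, float, float]:
    """Light-sheet NA, usable length and waist thickness.

    The sheet is launched through O1 with a flat-top beam filling the maximum
    available aperture: the pupil arc centered on the sheet direction spans
    the half-angle ``arcsin(NA1/n1) - (pi/2 - alpha)``, so
    ``NA_sheet = n1 sin(half-angle)``.  Length is approximated by the
    confocal parameter 2*n1*lambda_ex/(pi*NA_g^2) of the equivalent Gaussian
    beam with ``NA_g = NA_sheet / K_LS`` (single frozen flat-top-to-Gaussian
    equivalence factor).  The waist profile of the flat-top fill is sinc^2
    (uniform kz band of width 2 NA_sheet / lambda_ex across the sheet
    normal); the reported thickness is its intensity FWHM
    0.886 * lambda_ex / (2 NA_sheet).

    Returns
    -------
    (na_sheet, length_um, thickness_nm)
    """
    half = math.asin(config.na1 / config.n1) - (math.pi / 2 - config.alpha)
    if half <= 0:
        raise GeometryError(
            "no aperture available for the light-sheet: need arcsin(NA1/n1) > 90 deg - alpha"
        )
    na_sheet = config.n1 * math.sin(half)
    na_g = na_sheet / K_LS
    length_nm = 2.0 * config.n1 * config.lambda_ex / (math.pi * na_g**2)
    thickness = 0.886 * config.lambda_ex / (2.0 * na_sheet)
    return na_sheet, length_nm * 1e-3, thickness
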