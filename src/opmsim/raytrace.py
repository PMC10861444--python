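"""Per-ray 3x3 polarization matrices of the OPM train and their composition.

Every optical element acts on the full 3-component electric field of a ray as
a 3x3 matrix.  A microscope is a meridional bend (objective collimation
followed by tube-lens focusing, each obeying the sine condition) sandwiched
between azimuthal rotations, times a scalar aplanatic apodization and a
polarization-resolved transmission mask.  The complete system chain is

    T_sys = Rz(-phi_a) M3(th3) Ry(th3) F_T Ry(-th_i) Rz(phi_a) Rx(tilt)
            Rz(-phi) Mbar2(th2) M1(th1) Rz(phi)

acting on the dipole far field, where phi is the ray azimuth about the O1
axis, phi_a its azimuth in the tilted (O3) frame, th_i the incidence angle on
the O2->O3 interface and F_T the Fresnel transmission of the index change.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .config import SystemConfig
from .geometry import GRAZING_LIMIT, abbe_remap, snell, tilt_matrix

log = logging.getLogger("opmsim")

__all__ = [
    "rotation_matrix",
    "fresnel_transmission",
    "interface_power_transmission",
    "quarter_wave_transmission",
    "TransmissionCurve",
    "transmission_mask",
    "microscope_matrix",
    "system_matrix",
    "trace_system",
]


def rotation_matrix(axis: str, angle: float) -> np.ndarray:
    """Right-handed rotation matrix about a coordinate axis.

    ``rotation_matrix(a, t) @ rotation_matrix(a, -t)`` is the identity and
    the result is orthogonal with determinant +1.
    """
    c, s = math.cos(angle), math.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"axis must be one of x, y, z, got {axis!r}")


def _ry(angle):
    """Broadcastable rotation about y for array angles; shape (..., 3, 3)."""
    angle = np.asarray(angle, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    z = np.zeros_like(c)
    o = np.ones_like(c)
    return np.stack(
        [np.stack([c, z, s], -1), np.stack([z, o, z], -1), np.stack([-s, z, c], -1)], -2
    )


def _rz(angle):
    angle = np.asarray(angle, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    z = np.zeros_like(c)
    o = np.ones_like(c)
    return np.stack(
        [np.stack([c, -s, z], -1), np.stack([s, c, z], -1), np.stack([z, z, o], -1)], -2
    )


def fresnel_transmission(theta_incident, n1: float, n2: float):
    """Fresnel amplitude transmission coefficients (t_s, t_p).

    Standard single-interface coefficients in the s/p basis,

        t_s = 2 n1 cos(ti) / (n1 cos(ti) + n2 cos(tt))
        t_p = 2 n1 cos(ti) / (n2 cos(ti) + n1 cos(tt))

    Rays beyond the total-internal-reflection critical angle are fully
    blocked (both coefficients zero), never complex-propagated: evanescent
    components cannot reach the camera in a far-field imaging system.
    """
    theta_incident = np.asarray(theta_incident, dtype=float)
    tt = snell(theta_incident, n1, n2)
    blocked = np.isnan(tt)
    tt = np.where(blocked, 0.0, tt)
    ci, ct = np.cos(theta_incident), np.cos(tt)
    t_s = 2 * n1 * ci / (n1 * ci + n2 * ct)
    t_p = 2 * n1 * ci / (n2 * ci + n1 * ct)
    zero = np.zeros_like(t_s)
    return np.where(blocked, zero, t_s), np.where(blocked, zero, t_p)


def interface_power_transmission(theta_incident, n1: float, n2: float):
    """Power transmittance (T_s, T_p) of a single planar interface.

    T = (n2 cos(tt) / n1 cos(ti)) |t|^2; zero beyond the critical angle.
    """
    theta_incident = np.asarray(theta_incident, dtype=float)
    t_s, t_p = fresnel_transmission(theta_incident, n1, n2)
    tt = snell(theta_incident, n1, n2)
    tt = np.where(np.isnan(tt), 0.0, tt)
    with np.errstate(divide="ignore", invalid="ignore"):
        geom = n2 * np.cos(tt) / (n1 * np.cos(theta_incident))
    return geom * t_s**2, geom * t_p**2


def quarter_wave_transmission(theta_incident, n_in: float, n_sub: float):
    """Power transmittance (T_s, T_p) of an ideal quarter-wave AR coating.

    Single homogeneous layer of index sqrt(n_in n_sub) and quarter-wave
    optical thickness at normal incidence, by the standard thin-film
    characteristic matrix.  Reflection vanishes at normal incidence; at
    grazing incidence the transmission collapses as for any real interface
    (a coating cannot rescue grazing rays).  Beyond-critical rays are zero.
    """
    theta = np.asarray(theta_incident, dtype=float)
    n_c = math.sqrt(n_in * n_sub)
    sin_t = n_in * np.sin(theta)
    blocked = sin_t > n_sub  # total internal reflection into the substrate
    with np.errstate(invalid="ignore"):
        cos_c = np.sqrt(np.clip(1.0 - (sin_t / n_c) ** 2, 0.0, None))
        cos_s = np.sqrt(np.clip(1.0 - (sin_t / n_sub) ** 2, 0.0, None))
    cos_i = np.cos(theta)
    delta = (math.pi / 2.0) * cos_c
    out = []
    for pol in ("s", "p"):
        if pol == "s":
            e0, ec, es = n_in * cos_i, n_c * cos_c, n_sub * cos_s
        else:
            with np.errstate(divide="ignore"):
                e0 = np.where(cos_i > 0, n_in / np.where(cos_i > 0, cos_i, 1.0), np.inf)
                ec = np.where(cos_c > 0, n_c / np.where(cos_c > 0, cos_c, 1.0), np.inf)
                es = np.where(cos_s > 0, n_sub / np.where(cos_s > 0, cos_s, 1.0), np.inf)
        b = np.cos(delta) + 1j * np.sin(delta) * es / ec
        c = 1j * ec * np.sin(delta) + np.cos(delta) * es
        with np.errstate(invalid="ignore", divide="ignore"):
            t = 4.0 * e0 * es / np.abs(e0 * b + c) ** 2
        t = np.where(np.isfinite(t), t, 0.0)
        out.append(np.where(blocked | (cos_i <= 0) | (cos_s <= 0), 0.0, t))
    return out[0], out[1]


@dataclass
class TransmissionCurve:
    """Degree-5 polynomial fits of normalized power transmission vs angle.

    ``coeffs_p``/``coeffs_s`` are :class:`numpy.polynomial.Polynomial`
    coefficient arrays (lowest order first) in the variable theta (radians);
    ``theta_max`` bounds the fitted domain.  Curves are normalized so the
    maximum fitted power is 1.
    """

    coeffs_p: np.ndarray
    coeffs_s: np.ndarray
    theta_max: float
    name: str = ""

    @classmethod
    def fit(cls, theta_deg, power_p, power_s, name: str = "") -> "TransmissionCurve":
        """Fit degree-5 polynomials to measured (angle, power) samples."""
        th = np.radians(np.asarray(theta_deg, dtype=float))
        p = np.asarray(power_p, dtype=float)
        s = np.asarray(power_s, dtype=float)
        norm = max(p.max(), s.max())
        cp = np.polynomial.Polynomial.fit(th, p / norm, deg=5).convert().coef
        cs = np.polynomial.Polynomial.fit(th, s / norm, deg=5).convert().coef
        curve = cls(cp, cs, float(th.max()), name=name)
        log.info(
            "fitted transmission curve %s: p-coeffs %s, s-coeffs %s",
            name or "<anon>", np.array2string(cp, precision=4),
            np.array2string(cs, precision=4),
        )
        return curve

    @classmethod
    def from_file(cls, path, name: str = "") -> "TransmissionCurve":
        """Load a 3-column plain-text table (angle_deg, T_p, T_s) and fit."""
        data = np.loadtxt(path, comments="#", delimiter=None)
        if data.ndim != 2 or data.shape[1] != 3:
            raise ValueError(f"{path}: expected 3 columns (angle_deg, T_p, T_s)")
        return cls.fit(data[:, 0], data[:, 1], data[:, 2], name=name or str(path))

    @classmethod
    def flat(cls) -> "TransmissionCurve":
        """Lossless objective: unit power for both polarizations."""
        z = np.zeros(6)
        cp = z.copy(); cp[0] = 1.0
        return cls(cp, cp.copy(), math.pi / 2, name="flat")

    def power(self, theta, polarization: str):
        """Normalized power transmission at angle theta (radians), clamped to [0, 1].

        Angles outside the fitted domain are clamped to the boundary value
        with a warning.
        """
        theta = np.asarray(theta, dtype=float)
        if np.any(theta > self.theta_max + 1e-9):
            warnings.warn(
                f"transmission curve {self.name or '<anon>'}: angle beyond fitted "
                f"domain ({math.degrees(self.theta_max):.1f} deg); clamping",
                stacklevel=2,
            )
        th = np.clip(theta, 0.0, self.theta_max)
        coeffs = {"p": self.coeffs_p, "s": self.coeffs_s}[polarization]
        return np.clip(np.polynomial.polynomial.polyval(th, coeffs), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "coeffs_p": [float(c) for c in self.coeffs_p],
            "coeffs_s": [float(c) for c in self.coeffs_s],
            "theta_max_deg": math.degrees(self.theta_max),
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransmissionCurve":
        return cls(
            np.asarray(d["coeffs_p"], dtype=float),
            np.asarray(d["coeffs_s"], dtype=float),
            math.radians(d["theta_max_deg"]),
            d.get("name", ""),
        )

    def to_table(self, n: int = 91) -> np.ndarray:
        """Sampled (angle_deg, T_p, T_s) table over the fitted domain."""
        th = np.linspace(0.0, self.theta_max, n)
        return np.column_stack(
            [np.degrees(th), self.power(th, "p"), self.power(th, "s")]
        )


def transmission_mask(curve: TransmissionCurve | None, theta, polarization: str):
    """Amplitude factor sqrt(power) of an objective transmission curve.

    Measured curves are power transmissions; fields carry the square root
    (this amplitude-vs-power convention is logged for every traced run).
    A ``None`` curve is lossless.
    """
    if curve is None:
        return np.ones_like(np.asarray(theta, dtype=float))
    return np.sqrt(curve.power(theta, polarization))


def _mask_diag(amp_p, amp_s):
    """diag(amp_p, amp_s, amp_p): polarization mask in the meridional frame.

    The meridional (p) field components live in the xz-plane of the ray's
    meridional frame, the sagittal (s) component along y; the matrix commutes
    with meridional Ry bends, so its position inside the sandwich is free.
    """
    amp_p = np.asarray(amp_p, dtype=float)
    amp_s = np.asarray(amp_s, dtype=float)
    z = np.zeros_like(amp_p)
    return np.stack(
        [
            np.stack([amp_p, z, z], -1),
            np.stack([z, amp_s, z], -1),
            np.stack([z, z, amp_p], -1),
        ],
        -2,
    )


def microscope_matrix(
    theta_obj,
    config: SystemConfig,
    index: int,
    order: str = "objective_first",
) -> np.ndarray:
    """Meridional-frame matrix M_i (or Mbar_i) of one microscope.

    ``order="objective_first"`` gives M_i = T_i(th') O_i(th) G_i(th) A_i(th):
    the objective collimates a converging/diverging ray at ``theta_obj`` and
    the tube lens refocuses at th' from the sine-condition remap.
    ``order="tube_first"`` gives Mbar_i = O_i(th) T_i(th') G_i A_i: the tube
    lens collimates at th' and the objective focuses at ``theta_obj``.  The
    scalar apodization is the aplanatic energy-conservation factor
    sqrt(cos th'/cos th) (objective first) or its reciprocal (tube first),
    the only choices that conserve per-ray power in the unity-transmission
    limit.  Rays vignetted at the tube lens or outside the acceptance cone
    yield the zero matrix.
    """
    theta_obj = np.asarray(theta_obj, dtype=float)
    n = (config.n1, config.n2, config.n3)[index - 1]
    na = (config.na1, config.na2, config.na3)[index - 1]
    theta_acc = math.asin(min(na / n, 1.0))
    ratio = config.tube_ratio(index)
    theta_tube = abbe_remap(theta_obj, na, na * ratio, n)
    vignetted = np.isnan(theta_tube) | (theta_obj > theta_acc + 1e-12)
    theta_tube = np.where(vignetted, 0.0, theta_tube)
    # vignetted entries are zeroed below; evaluate masks/apodization on the
    # clipped angle so they stay finite and silent meanwhile
    theta_eval = np.clip(theta_obj, 0.0, theta_acc)

    curve = config.transmission.get(f"o{index}")
    amp_p = transmission_mask(curve, theta_eval, "p")
    amp_s = transmission_mask(curve, theta_eval, "s")

    if order == "objective_first":
        bend = _ry(theta_tube - theta_obj)
        apod = np.sqrt(np.cos(theta_tube) / np.cos(theta_eval))
    elif order == "tube_first":
        bend = _ry(theta_obj - theta_tube)
        apod = np.sqrt(np.cos(theta_eval) / np.cos(theta_tube))
    else:
        raise ValueError(f"order must be objective_first or tube_first, got {order!r}")

    m = bend @ _mask_diag(amp_p, amp_s) * apod[..., None, None]
    return np.where(vignetted[..., None, None], 0.0, m)


def _o3_interface_amplitudes(config: SystemConfig, theta_inc):
    """Per-ray (amp_p, amp_s, theta3) for the O2->O3 transition.

    ``theta_inc`` is the incidence angle on the interface (from the O3 axis)
    in the remote medium n2.  Amplitudes are sqrt of the power transmittance
    so that lossless couplings conserve per-ray power exactly:

    - matched: unity (no index change),
    - ar_coated: ideal quarter-wave coating transmittance (perfect at normal
      incidence, collapsing at grazing) times the O3 transmission-curve mask
      evaluated at theta3,
    - fresnel: two uncoated interfaces n2 -> coverslip -> n3 (power product,
      multiple reflections neglected), times any O3 curve.
    """
    theta_inc = np.asarray(theta_inc, dtype=float)
    theta3 = snell(theta_inc, config.n2, config.n3)
    blocked = np.isnan(theta3) | (theta_inc >= GRAZING_LIMIT)
    theta3 = np.where(blocked, 0.0, theta3)

    curve = config.transmission.get("o3")
    amp_p = transmission_mask(curve, theta3, "p")
    amp_s = transmission_mask(curve, theta3, "s")

    if config.o3_coupling == "ar_coated":
        ts, tp = quarter_wave_transmission(theta_inc, config.n2, config.n3)
        amp_p = amp_p * np.sqrt(np.clip(tp, 0.0, None))
        amp_s = amp_s * np.sqrt(np.clip(ts, 0.0, None))
    elif config.o3_coupling == "fresnel":
        ts1, tp1 = interface_power_transmission(theta_inc, config.n2, config.coverslip_n)
        th_g = snell(theta_inc, config.n2, config.coverslip_n)
        th_g = np.where(np.isnan(th_g), 0.0, th_g)
        ts2, tp2 = interface_power_transmission(th_g, config.coverslip_n, config.n3)
        amp_p = amp_p * np.sqrt(np.clip(tp1 * tp2, 0.0, None))
        amp_s = amp_s * np.sqrt(np.clip(ts1 * ts2, 0.0, None))

    zero = np.zeros_like(amp_p)
    return (
        np.where(blocked, zero, amp_p),
        np.where(blocked, zero, amp_s),
        theta3,
        blocked,
    )


def system_matrix(theta1, phi, config: SystemConfig, sample_referred: bool = False):
    """Full per-ray transfer matrix of the three-microscope chain.

    Parameters
    ----------
    theta1, phi : array_like
        Ray direction at the O1 side (polar angle from the O1 axis, azimuth).
    sample_referred : bool
        If False, compose the full published chain ending in the camera-side
        converging field (through M3).  If True, stop in the tilted remote
        frame after the O2->O3 interface transmission: the polarization mask
        of O3 and the interface amplitudes are applied as s/p scalars but the
        refraction and O3/T3 bends are omitted, giving the field whose Debye
        focus is the sample-referred PSF.

    Returns
    -------
    t : ndarray (..., 3, 3)
        Transfer matrices; zero matrices for vignetted rays.
    mask : ndarray (...,) bool
        True where the ray survives.
    """
    theta1 = np.asarray(theta1, dtype=float)
    phi = np.asarray(phi, dtype=float)
    theta1, phi = np.broadcast_arrays(theta1, phi)

    alive = theta1 <= config.theta1_max + 1e-12
    # perfect-3D relay O1->O2: theta2 = theta1 ray by ray
    theta2 = theta1
    alive &= theta2 <= config.theta2_max + 1e-12

    # The published chain writes Rz(phi) ... Rz^-1(phi) with passive
    # (component) rotations; in the active convention used here the
    # meridional frame opens with Rz(-phi) and closes with Rz(+phi).
    m1 = microscope_matrix(theta1, config, 1, order="objective_first")
    m2 = microscope_matrix(theta2, config, 2, order="tube_first")
    merid = _rz(phi) @ m2 @ m1 @ _rz(-phi)

    # direction in the tilted (O3) frame
    st, ct = np.sin(theta1), np.cos(theta1)
    d = np.stack([st * np.cos(phi), st * np.sin(phi), ct], -1)
    rt = tilt_matrix(config.alpha)
    dt = d @ rt.T
    theta_inc = np.arccos(np.clip(dt[..., 2], -1.0, 1.0))
    phi_a = np.arctan2(dt[..., 1], dt[..., 0])
    alive &= theta_inc < GRAZING_LIMIT
    alive &= config.n2 * np.sin(theta_inc) <= config.na3 + 1e-12

    amp_p, amp_s, theta3, blocked = _o3_interface_amplitudes(config, theta_inc)
    alive &= ~blocked
    ft = _mask_diag(amp_p, amp_s)

    if sample_referred:
        # F_T commutes with the meridional Ry bends, so the omitted
        # Ry(theta3) .. Ry(-theta_inc) refraction bend drops out exactly.
        chain = _rz(phi_a) @ ft @ _rz(-phi_a) @ rt @ merid
    else:
        # O3's polarization mask is already inside ft; build M3 without it.
        cfg3 = config.replace(transmission={**config.transmission, "o3": None})
        m3 = microscope_matrix(theta3, cfg3, 3, order="objective_first")
        chain = (
            _rz(phi_a)
            @ m3
            @ _ry(theta3)
            @ ft
            @ _ry(-theta_inc)
            @ _rz(-phi_a)
            @ rt
            @ merid
        )

    chain = np.where(alive[..., None, None], chain, 0.0)
    return chain, alive


def trace_system(config: SystemConfig, theta1, phi):
    """System matrices composed with the dipole far-field projector.

    Returns ``g`` with ``g @ p_hat`` the traced per-solid-angle far-field of
    a unit dipole ``p_hat`` (normalized so a free dipole radiates unit total
    power: amplitude sqrt(3/8pi) sin(angle to axis)), plus the survival mask.
    """
    theta1 = np.asarray(theta1, dtype=float)
    phi = np.asarray(phi, dtype=float)
    theta1, phi = np.broadcast_arrays(theta1, phi)
    t, alive = system_matrix(theta1, phi, config, sample_referred=True)
    st, ct = np.sin(theta1), np.cos(theta1)
    r = np.stack([st * np.cos(phi), st * np.sin(phi), ct], -1)
    proj = np.eye(3) - r[..., :, None] * r[..., None, :]
    return math.sqrt(3.0 / (8.0 * math.pi)) * (t @ proj), alive
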