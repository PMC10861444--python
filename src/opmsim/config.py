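"""System configuration for an oblique plane microscope (OPM) simulation.

An OPM concatenates three microscopes: a primary high-NA objective O1 whose
focal volume is relayed at magnification n1/n2 into a remote space by O2
(perfect 3D imaging), and a tertiary microscope O3 tilted so that its focal
plane coincides with the oblique light-sheet.  The light-sheet is inclined by
``alpha`` from the O1 focal plane, so the O3 optical axis is inclined by
``alpha`` from the O1/O2 axis.

All angles are stored in radians and all lengths in nanometres internally;
configuration files use degrees and nm/µm as labelled.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

log = logging.getLogger("opmsim")

#: Default sine ratio between tube lens and objective acceptance,
#: sin(theta_tube) = TUBE_SINE_SCALE * sin(theta_obj).  Choosing the tube
#: NA ratios as TUBE_SINE_SCALE / n_i for every microscope makes the O1->O2
#: relay an exact perfect-3D system (theta_2 = theta_1 ray by ray).
TUBE_SINE_SCALE = 0.05

#: Flat-top to Gaussian light-sheet equivalence factor: the sheet fills the
#: available aperture with a flat-top beam, but length/thickness are quoted
#: via the Gaussian confocal parameter with NA_gauss = NA_sheet / K_LS.
#: Calibrated once (geometric mean over the published sheet-length column)
#: and frozen.
K_LS = 1.28


class ConfigError(ValueError):
    """Raised when a configuration violates a physical or schema invariant."""


@dataclass
class SystemConfig:
    """Complete description of one OPM configuration.

    Parameters
    ----------
    na1, na2, na3 : float
        Numerical apertures of the three objectives.
    n1, n2, n3 : float
        Immersion refractive indices (O2 remote space is usually air).
    alpha : float
        Light-sheet inclination from the O1 focal plane, radians.
    lambda_ex, lambda_em : float
        Excitation and emission wavelengths in nm.
    sheet_polarization : str
        ``"s"`` (E-field along x, perpendicular to the tilt plane) or
        ``"p"`` (E-field in the tilt plane, along the sheet normal).
    o3_coupling : str
        How the O2 -> O3 transition is modelled: ``"matched"`` (no index
        change), ``"ar_coated"`` (index change, Fresnel suppressed by the
        anti-reflection coating; transmission from the O3 curve instead) or
        ``"fresnel"`` (uncoated interfaces; ``coverslip_n`` slab between
        remote air space and the O3 immersion).
    coverslip_n : float
        Refractive index of the coverslip slab used when
        ``o3_coupling == "fresnel"``.
    transmission : dict
        Optional per-objective transmission curves, keys ``"o1"``, ``"o2"``,
        ``"o3"``; values are :class:`~opmsim.raytrace.TransmissionCurve` or
        ``None`` for a lossless objective.
    n_p : float
        Photons at the brightest voxel of the noiseless PSF.
    sigma_rms : float
        Camera read-noise RMS in electrons.
    bias : float
        Camera offset in counts.
    n_dipoles : int
        Size of the emitter ensemble.
    dipole_mode : str
        ``"isotropic_photoselected"`` or ``"aligned"``.
    n_noise_realizations : int
        Noise draws averaged for the resolution report.
    seed : int
        Master seed; all stochastic sub-streams derive from it.
    grid_shape : (int, int, int)
        PSF voxel grid (z, y, x); every dimension must be odd.
    pitch_xy, pitch_z : float or None
        Sample-referred voxel pitches in nm; ``None`` selects defaults from
        the Nyquist rule (with a 0.8 margin laterally).
    pupil_samples : int
        Samples across the pupil diameter for the traced ray grid.
    """

    na1: float = 1.35
    na2: float = 0.95
    na3: float = 1.0
    n1: float = 1.404
    n2: float = 1.0
    n3: float = 1.52
    tube_na_ratios: tuple[float, float, float] | None = None
    alpha: float = math.radians(30.0)
    lambda_ex: float = 488.0
    lambda_em: float = 507.0
    sheet_polarization: str = "s"
    o3_coupling: str = "ar_coated"
    coverslip_n: float = 1.5
    transmission: dict[str, Any] = field(default_factory=dict)
    n_p: float = 1e4
    sigma_rms: float = 1.6
    bias: float = 100.0
    n_dipoles: int = 100
    dipole_mode: str = "isotropic_photoselected"
    n_noise_realizations: int = 10
    seed: int = 0
    grid_shape: tuple[int, int, int] = (257, 129, 129)
    pitch_xy: float | None = None
    pitch_z: float | None = None
    pupil_samples: int = 129

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def theta1_max(self) -> float:
        """O1 acceptance half-angle (radians)."""
        return math.asin(self.na1 / self.n1)

    @property
    def theta2_max(self) -> float:
        """O2 acceptance half-angle in the remote space (radians)."""
        return math.asin(self.na2 / self.n2)

    @property
    def theta3_max(self) -> float:
        """O3 acceptance half-angle in its immersion medium (radians)."""
        return math.asin(self.na3 / self.n3)

    def tube_ratio(self, i: int) -> float:
        """NA'/NA for microscope ``i`` (1-based)."""
        if self.tube_na_ratios is not None:
            return self.tube_na_ratios[i - 1]
        n = (self.n1, self.n2, self.n3)[i - 1]
        return TUBE_SINE_SCALE / n

    def default_pitch_xy(self) -> float:
        from .focal import nyquist_pixel

        na_det = self.n1 * math.sin(min(self.theta1_max, self.theta2_max))
        return 0.8 * nyquist_pixel(self.lambda_em, na_det)

    def default_pitch_z(self) -> float:
        return 120.0

    def pitches(self) -> tuple[float, float]:
        """(pitch_xy, pitch_z) in nm with defaults resolved."""
        return (
            self.pitch_xy if self.pitch_xy is not None else self.default_pitch_xy(),
            self.pitch_z if self.pitch_z is not None else self.default_pitch_z(),
        )

    def sheet_polarization_vector(self) -> "tuple[float, float, float]":
        """Unit electric-field vector of the light-sheet at the focus (lab frame).

        s: along x (perpendicular to the tilt plane).  p: in the tilt (yz)
        plane, perpendicular to the sheet propagation direction
        (0, cos alpha, sin alpha) -- i.e. along the sheet normal / O3 axis.
        """
        if self.sheet_polarization == "s":
            return (1.0, 0.0, 0.0)
        a = self.alpha
        return (0.0, -math.sin(a), math.cos(a))

    # -- validation and (de)serialization ----------------------------------

    def validate(self) -> None:
        for i, (na, n) in enumerate(
            [(self.na1, self.n1), (self.na2, self.n2), (self.na3, self.n3)], start=1
        ):
            if not 0 < na <= n:
                raise ConfigError(
                    f"objective {i}: require 0 < NA <= n, got NA{i}={na}, n{i}={n}"
                )
        if not 0 < self.alpha < math.pi / 2:
            raise ConfigError(f"alpha must be in (0, 90) degrees, got {math.degrees(self.alpha)}")
        if self.lambda_ex <= 0 or self.lambda_em <= 0:
            raise ConfigError("wavelengths must be positive")
        if self.n_p <= 0:
            raise ConfigError("n_p (photons at brightest pixel) must be positive")
        if self.sheet_polarization not in ("s", "p"):
            raise ConfigError(f"sheet_polarization must be 's' or 'p', got {self.sheet_polarization!r}")
        if self.o3_coupling not in ("matched", "ar_coated", "fresnel"):
            raise ConfigError(f"unknown o3_coupling {self.o3_coupling!r}")
        if self.n_dipoles < 1:
            raise ConfigError("n_dipoles must be >= 1")
        if self.dipole_mode not in ("isotropic_photoselected", "aligned"):
            raise ConfigError(f"unknown dipole_mode {self.dipole_mode!r}")
        if any(s % 2 == 0 for s in self.grid_shape):
            raise ConfigError(f"grid_shape dimensions must be odd, got {self.grid_shape}")

    def replace(self, **kw: Any) -> "SystemConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        d = {
            "na1": self.na1, "na2": self.na2, "na3": self.na3,
            "n1": self.n1, "n2": self.n2, "n3": self.n3,
            "alpha_deg": math.degrees(self.alpha),
            "lambda_ex_nm": self.lambda_ex, "lambda_em_nm": self.lambda_em,
            "sheet_polarization": self.sheet_polarization,
            "o3_coupling": self.o3_coupling, "coverslip_n": self.coverslip_n,
            "n_p": self.n_p, "sigma_rms": self.sigma_rms, "bias": self.bias,
            "n_dipoles": self.n_dipoles, "dipole_mode": self.dipole_mode,
            "n_noise_realizations": self.n_noise_realizations,
            "seed": self.seed, "grid_shape": list(self.grid_shape),
            "pitch_xy_nm": self.pitch_xy, "pitch_z_nm": self.pitch_z,
            "pupil_samples": self.pupil_samples,
        }
        if self.tube_na_ratios is not None:
            d["tube_na_ratios"] = list(self.tube_na_ratios)
        trans = {}
        for key, curve in self.transmission.items():
            if curve is not None:
                trans[key] = curve.to_dict()
        if trans:
            d["transmission"] = trans
        return d


_FIELD_MAP = {
    "alpha_deg": ("alpha", math.radians),
    "lambda_ex_nm": ("lambda_ex", float),
    "lambda_em_nm": ("lambda_em", float),
    "pitch_xy_nm": ("pitch_xy", lambda v: None if v is None else float(v)),
    "pitch_z_nm": ("pitch_z", lambda v: None if v is None else float(v)),
}

_VALID_KEYS = {f.name for f in dataclasses.fields(SystemConfig)} | set(_FIELD_MAP)


def config_from_dict(data: dict[str, Any]) -> SystemConfig:
    from .raytrace import TransmissionCurve

    kw: dict[str, Any] = {}
    for key, value in data.items():
        if key not in _VALID_KEYS:
            raise ConfigError(f"unknown configuration field {key!r}")
        if key in _FIELD_MAP:
            name, conv = _FIELD_MAP[key]
            kw[name] = conv(value)
        elif key == "grid_shape":
            kw[key] = tuple(int(v) for v in value)
        elif key == "tube_na_ratios":
            kw[key] = tuple(float(v) for v in value)
        elif key == "transmission":
            kw[key] = {
                obj: (TransmissionCurve.from_dict(spec) if spec is not None else None)
                for obj, spec in value.items()
            }
        else:
            kw[key] = value
    return SystemConfig(**kw)


def load_config(path: str | Path) -> SystemConfig:
    """Load and validate a YAML configuration file.

    Angles in the file are degrees, lengths nm (suffixes ``_deg``/``_nm``);
    defaults are applied for missing fields and every defaulted field is
    logged.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration root must be a mapping")
    cfg = config_from_dict(data)
    given = set(data)
    defaulted = sorted(
        k for k in _VALID_KEYS if k not in given and _FIELD_MAP.get(k, (k,))[0] not in given
    )
    log.info("loaded %s; defaulted fields: %s", path, ", ".join(defaulted))
    return cfg


def dump_config(cfg: SystemConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def preset(name: str, **overrides: Any) -> SystemConfig:
    """Named system presets.

    ``"agy"``: 1.35 NA silicone O1 / 0.95 NA dry O2 / 1.0 NA glass-immersion
    O3 with anti-reflection-coated tip (the published main configuration).
    ``"water_coverslip"``: same but water-immersion O3 behind a 1.5-RI
    coverslip with uncoated Fresnel interfaces.  ``"ideal_dry"``: hypothetical
    1.0 NA dry O3, no index change (upper bound, no Fresnel loss).
    """
    base = dict(na1=1.35, na2=0.95, na3=1.0, n1=1.404, n2=1.0,
                lambda_ex=488.0, lambda_em=507.0)
    if name == "agy":
        base.update(n3=1.52, o3_coupling="ar_coated")
    elif name == "water_coverslip":
        base.update(n3=1.33, o3_coupling="fresnel", coverslip_n=1.5)
    elif name == "ideal_dry":
        base.update(n3=1.0, o3_coupling="matched")
    elif name == "fig5":
        base.update(n1=1.33, na1=1.25, n3=1.52, o3_coupling="ar_coated")
    else:
        raise ConfigError(f"unknown preset {name!r}")
    base.update(overrides)
    return SystemConfig(**base)
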