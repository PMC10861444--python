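"""Camera noise model, noise-aware OTF resolution limits, and light efficiency.

The camera model scales the noiseless PSF so its brightest voxel holds N_p
photons, draws Poisson shot noise, adds zero-mean Gaussian read noise of RMS
sigma_RMS, adds a bias offset and discretizes.  The practically resolvable
frequency support of the optical transfer function is then bounded by the
stochastic background

    |eta| = sqrt(DC + sigma_RMS^2 - b)

(DC taken as the stack mean, the transform normalized by sqrt(N_voxels));
subtracting it from |OTF|, the per-axis cutoff is the first zero crossing of
the band-averaged profile, and resolution = 1/cutoff.  The kz direction has
two distinct limits: the on-axis crossing gives the optical sectioning
thickness, the maximum kz extent anywhere in the support gives the axial
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import uniform_filter

from .config import SystemConfig
from .dipoles import analytic_second_moment
from .focal import PSFStack
from .geometry import direction_grid, lightsheet_geometry, pupil_mask
from .raytrace import trace_system

__all__ = [
    "snr",
    "apply_noise",
    "NoisyPSF",
    "otf_background",
    "resolution_limits",
    "ResolutionReport",
    "psf_area_volume",
    "optical_efficiency",
]


def snr(n_p: float, sigma_rms: float) -> float:
    """Signal-to-noise ratio at the brightest pixel, N_p / sqrt(N_p + sigma^2)."""
    if n_p < 0:
        raise ValueError("photon count must be non-negative")
    if n_p == 0:
        return 0.0
    return n_p / math.sqrt(n_p + sigma_rms**2)


@dataclass
class NoisyPSF:
    """Integer camera counts with the noise parameters that produced them."""

    counts: np.ndarray
    n_p: float
    sigma_rms: float
    bias: float
    seed: object


def apply_noise(
    psf: PSFStack,
    n_p: float,
    sigma_rms: float,
    bias: float,
    seed,
) -> NoisyPSF:
    """Simulate the camera readout of a noiseless PSF.

    Scale so the brightest voxel equals ``n_p`` photons, Poisson-sample, add
    zero-mean Gaussian noise of RMS ``sigma_rms``, add ``bias``, round to
    integers and clip at zero.  ``seed`` may be an int or a numpy Generator /
    SeedSequence; the same seed reproduces identical counts.
    """
    if n_p < 1:
        raise ValueError("need at least one photon at the brightest pixel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scaled = psf.voxels * (n_p / psf.voxels.max())
    counts = rng.poisson(scaled).astype(np.float64)
    if sigma_rms > 0:
        counts += rng.normal(0.0, sigma_rms, size=counts.shape)
    counts += bias
    counts = np.clip(np.rint(counts), 0, None)
    return NoisyPSF(counts, n_p, sigma_rms, bias, seed)


def otf_background(otf_dc: float, sigma_rms: float, bias: float) -> float:
    """Expected OTF background magnitude sqrt(DC + sigma_RMS^2 - b).

    ``otf_dc`` is the zero-frequency component of the noisy stack's transform
    on the mean scale (stack mean); the background applies to the transform
    normalized by sqrt(N_voxels).
    """
    radicand = otf_dc + sigma_rms**2 - bias
    if radicand < 0:
        raise ValueError(
            f"negative radicand {radicand:.3g}: bias estimate inconsistent with the stack DC"
        )
    return math.sqrt(radicand)


@dataclass
class ResolutionReport:
    """Noise-aware resolution limits and derived PSF/light-sheet figures.

    Lengths in nm except ``psf_area`` (µm²), ``psf_volume`` (µm³) and
    ``sheet_length`` (µm).  ``saturated`` lists axes whose cutoff hit the
    frequency band edge (resolution beyond the sampling).
    """

    res_x: float
    res_y: float
    res_z: float
    sectioning: float
    psf_area: float = 0.0
    psf_volume: float = 0.0
    sheet_length: float = 0.0
    sheet_thickness: float = 0.0
    snr: float = 0.0
    efficiency: float = 0.0
    saturated: tuple = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["saturated"] = list(self.saturated)
        return d


def _first_crossing(profile: np.ndarray, dnu: float) -> tuple[float, bool]:
    """First sub-bin zero crossing of a background-subtracted profile.

    ``profile[0]`` is the DC bin; returns (cutoff frequency, saturated flag),
    the flag set when no crossing exists inside the band (band edge used).
    """
    neg = np.nonzero(profile <= 0.0)[0]
    neg = neg[neg > 0]
    if len(neg) == 0:
        return (len(profile) - 1) * dnu, True
    i = int(neg[0])
    y0, y1 = profile[i - 1], profile[i]
    frac = y0 / (y0 - y1) if y0 != y1 else 0.0
    return (i - 1 + frac) * dnu, False


def _band_profile(mag: np.ndarray, axis: int) -> np.ndarray:
    """|OTF| profile along +axis, averaged over a +-1-bin transverse band.

    ``mag`` is the magnitude of the DFT of the (z, y, x) stack with the x
    axis half (rfftn layout) and DC at index 0 of every axis.
    """
    other = [a for a in range(3) if a != axis]
    sl: list = [slice(None)] * 3
    acc = None
    for da in (-1, 0, 1):
        for db in (-1, 0, 1):
            s = list(sl)
            # the x axis is rfft-halved: its -1 bin is the +1 bin's mirror
            s[other[0]] = abs(da) if other[0] == 2 else da
            s[other[1]] = abs(db) if other[1] == 2 else db
            band = mag[tuple(s)]
            acc = band if acc is None else acc + band
    prof = acc / 9.0
    n = mag.shape[axis]
    if axis != 2:  # full-length axes: positive half only
        n = n // 2 + 1
    return prof[:n]


def resolution_limits(
    psf: PSFStack,
    config: SystemConfig,
    n_realizations: int | None = None,
    seed=None,
) -> ResolutionReport:
    """Noise-aware resolution report for a noiseless PSF under the camera model.

    For each noise realization the stack is Fourier transformed, the
    stochastic background subtracted from |OTF|, and four cutoffs extracted:
    along kx and ky (lateral), along the kz axis (sectioning) and the maximum
    kz extent of the support (axial resolution, from the first crossing of
    the per-kz-plane maximum of the 3x3x3 box-averaged background-subtracted
    magnitude).  Cutoffs are averaged over realizations.
    """
    if n_realizations is None:
        n_realizations = config.n_noise_realizations
    if n_realizations < 1:
        raise ValueError("need at least one noise realization")
    if seed is None:
        seed = np.random.SeedSequence([int(config.seed), 0xC0FFEE])
    if isinstance(seed, int):
        seed = np.random.SeedSequence(seed)
    streams = seed.spawn(n_realizations)

    nz, ny, nx = psf.shape
    dnu_z, dnu_y, dnu_x = psf.frequency_steps()
    nvox = psf.voxels.size
    cut = np.zeros((n_realizations, 4))
    sat_flags = [set() for _ in range(4)]
    for r, ss in enumerate(streams):
        noisy = apply_noise(psf, config.n_p, config.sigma_rms, config.bias,
                            np.random.default_rng(ss))
        f = np.fft.rfftn(noisy.counts.astype(np.float32))
        mag = np.abs(f) / math.sqrt(nvox)
        bg = otf_background(float(noisy.counts.mean()), config.sigma_rms, config.bias)
        for j, (axis, dnu) in enumerate(((2, dnu_x), (1, dnu_y), (0, dnu_z))):
            prof = _band_profile(mag, axis) - bg
            cut[r, j], sat = _first_crossing(prof, dnu)
            if sat:
                sat_flags[j].add("xyS"[j])
        # max kz extent of the support: the plane-max statistic of pure noise
        # sits above the mean background, so calibrate its zero level on the
        # highest-frequency lateral corner of the transform (outside any
        # physical support) instead of using bg directly.
        sm = uniform_filter(mag, size=3, mode="nearest")
        plane_max = sm.max(axis=(1, 2))
        qy, qx = mag.shape[1] // 4, mag.shape[2] // 2
        corner = sm[:, qy : qy + max(qy, 2), qx // 2 :]
        noise_level = float(np.median(corner.max(axis=(1, 2))))
        prof_z = plane_max[: nz // 2 + 1] - noise_level
        cut[r, 3], sat = _first_crossing(prof_z, dnu_z)
        if sat:
            sat_flags[3].add("z")
    mean_cut = cut.mean(axis=0)
    res_x, res_y, sectioning, res_z = (1.0 / mean_cut).tolist()

    na_sheet, length_um, thickness = lightsheet_geometry(config)
    area, volume = psf_area_volume(res_x, res_y, sectioning)
    saturated = tuple(sorted(set().union(*sat_flags)))
    return ResolutionReport(
        res_x=res_x,
        res_y=res_y,
        res_z=res_z,
        sectioning=sectioning,
        psf_area=area,
        psf_volume=volume,
        sheet_length=length_um,
        sheet_thickness=thickness,
        snr=snr(config.n_p, config.sigma_rms),
        saturated=saturated,
    )


def psf_area_volume(res_x: float, res_y: float, sectioning: float) -> tuple[float, float]:
    """Ellipsoidal in-focus PSF area (µm²) and volume (µm³).

    area = pi (x/2)(y/2); volume = (4 pi/3)(x/2)(y/2)(S/2) with the
    sectioning thickness as the axial diameter (inputs in nm).
    """
    rx, ry, rs = res_x / 2e3, res_y / 2e3, sectioning / 2e3
    return math.pi * rx * ry, 4.0 * math.pi / 3.0 * rx * ry * rs


def optical_efficiency(
    config: SystemConfig,
    polarization: str | None = None,
    n_theta: int = 180,
    n_phi: int = 360,
) -> float:
    """Fraction of the ensemble's emitted light transmitted to the camera.

    The photoselected-ensemble second moment C (infinite-ensemble limit for a
    deterministic figure) weights the traced per-ray transmitted power:

        eff = sum_rays tr(G C G^H) dOmega / tr(C)

    over the surviving effective pupil, with G the per-solid-angle system
    chain including all transmission masks and Fresnel losses.  The
    excitation-path transmission of the sheet through O1 (its own curve at
    the sheet angle, per polarization) multiplies the result.
    """
    if polarization is None:
        polarization = config.sheet_polarization
    cfg = config if polarization == config.sheet_polarization else config.replace(
        sheet_polarization=polarization
    )
    c = analytic_second_moment(cfg.sheet_polarization_vector())
    theta, phi, w = direction_grid(cfg.theta1_max, n_theta, n_phi)
    g, alive = trace_system(cfg, theta, phi)
    power = np.einsum("...ij,jk,...ik->...", g, c, g.conj()).real
    power = np.where(alive, power, 0.0)
    collected = float(np.sum(power * w))

    # excitation delivery through O1 (unit for the default flat curve)
    curve = cfg.transmission.get("o1")
    if curve is not None:
        theta_sheet = math.pi / 2 - cfg.alpha
        exc = curve.power(theta_sheet, polarization)
        collected *= float(exc)
    return collected / float(np.trace(c))
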