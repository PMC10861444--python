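"""Synthetic objective-transmission curves for testing and default configs.

The published transmission masks come from bench measurements of a 0.95 NA
dry objective and the AMS-AGY v1.0 glass-immersion objective whose raw data
live in an external deposit; these generators synthesize plain-text tables
with the same qualitative structure (synthetic stand-ins, not measurements):

- ``dry_like``: p-transmission exceeds s at high angle with a steep s
  roll-off, as typical for a high-NA dry apochromat;
- ``agy_like``: near-flat and polarization-insensitive (|T_s - T_p| < 0.05),
  as for the anti-reflection-coated glass-tipped tertiary objective;
- ``coverslip_fresnel``: exact two-interface Fresnel power transmission of
  an uncoated 1.5-RI slab between air and water;
- ``flat``: lossless.
"""

from __future__ import annotations

import numpy as np

from .raytrace import TransmissionCurve, interface_power_transmission

__all__ = ["generate_fixture_transmission", "write_transmission_table"]


def generate_fixture_transmission(
    style: str,
    seed: int = 0,
    theta_max_deg: float | None = None,
    n_points: int = 60,
) -> TransmissionCurve:
    """Generate a synthetic transmission curve and fit it like a measurement.

    ``seed`` perturbs the sampled points with small measurement-like scatter
    (1% RMS) before the degree-5 polynomial fit; ``seed=0`` is noise-free.
    """
    rng = np.random.default_rng(seed)
    if style == "flat":
        return TransmissionCurve.flat()
    if style == "dry_like":
        tmax = theta_max_deg if theta_max_deg is not None else 72.0
        th = np.linspace(0.0, tmax, n_points)
        x = th / tmax
        t_p = 1.0 - 0.20 * x**3
        t_s = 1.0 - 0.10 * x**2 - 0.35 * x**5
    elif style == "agy_like":
        tmax = theta_max_deg if theta_max_deg is not None else 50.0
        th = np.linspace(0.0, tmax, n_points)
        x = th / tmax
        t_p = 1.0 - 0.06 * x**2
        t_s = 1.0 - 0.04 * x**2 - 0.05 * x**4
    elif style == "coverslip_fresnel":
        tmax = theta_max_deg if theta_max_deg is not None else 89.0
        th = np.linspace(0.0, tmax, n_points)
        rad = np.radians(th)
        ts1, tp1 = interface_power_transmission(rad, 1.0, 1.5)
        th_g = np.arcsin(np.clip(np.sin(rad) / 1.5, -1, 1))
        ts2, tp2 = interface_power_transmission(th_g, 1.5, 1.33)
        t_p = tp1 * tp2
        t_s = ts1 * ts2
    else:
        raise ValueError(f"unknown fixture style {style!r}")
    if seed != 0:
        t_p = np.clip(t_p + rng.normal(0, 0.01, t_p.shape), 0, None)
        t_s = np.clip(t_s + rng.normal(0, 0.01, t_s.shape), 0, None)
    return TransmissionCurve.fit(th, t_p, t_s, name=style)


def write_transmission_table(curve: TransmissionCurve, path, n: int = 91) -> None:
    """Write a 3-column plain-text table (angle_deg, T_p, T_s)."""
    table = curve.to_table(n)
    header = f"transmission curve {curve.name or '<anon>'}\nangle_deg T_p T_s"
    np.savetxt(path, table, header=header, fmt="%.6f")
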