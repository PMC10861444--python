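"""Fixed-orientation dipole emitters and photoselected ensembles.

Fluorophores with high fluorescence anisotropy (negligible rotational
diffusion between absorption and emission) are modelled as non-rotating
point dipoles: a light-sheet with unit polarization e excites a dipole of
orientation p with probability |p.e|^2, and the excited dipole emits with the
classical sin^2 far-field pattern about its own axis.  An ensemble PSF is the
excitation-weighted incoherent sum of single-dipole intensity PSFs, which is
fully determined by the 3x3 weighted second-moment matrix of the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "dipole_farfield",
    "excitation_weight",
    "DipoleEnsemble",
    "sample_ensemble",
    "analytic_second_moment",
]

_AMP = np.sqrt(3.0 / (8.0 * np.pi))  # unit-total-power normalization


def dipole_farfield(orientation, theta, phi):
    """Far-field electric field of a unit-power dipole along ``orientation``.

    The field at observation direction r(theta, phi) is transverse,
    E = A ((r x p) x r) = A (p - (p.r) r) with A = sqrt(3/8pi), so that the
    radiated power integrates to 1 over the full sphere for any orientation.
    """
    p = np.asarray(orientation, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st, ct = np.sin(theta), np.cos(theta)
    r = np.stack([st * np.cos(phi), st * np.sin(phi), ct], axis=-1)
    return _AMP * (p - (r @ p)[..., None] * r)


def excitation_weight(dipole_orientation, sheet_polarization) -> float:
    """Photoselection probability |p.e|^2 for unit vectors p, e."""
    p = np.asarray(dipole_orientation, dtype=float)
    e = np.asarray(sheet_polarization, dtype=float)
    return float(np.dot(p, e) ** 2)


@dataclass
class DipoleEnsemble:
    """A seeded ensemble of dipole orientations with excitation weights."""

    orientations: np.ndarray  # (n, 3) unit vectors
    weights: np.ndarray       # (n,) in [0, 1]
    mode: str
    seed: int

    def __len__(self) -> int:
        return len(self.orientations)

    def second_moment(self) -> np.ndarray:
        """Weighted second-moment matrix C = sum_i w_i p_i p_i^T / sum_i w_i.

        The ensemble intensity PSF equals sum_jk C_jk F_j F_k* where F_j is
        the focal field of a unit dipole along axis j (traced through the
        system); diagonalizing C reduces any ensemble to three eigen-dipoles
        exactly.
        """
        w = self.weights
        c = np.einsum("i,ij,ik->jk", w, self.orientations, self.orientations)
        return c / w.sum()


def sample_ensemble(n: int, mode: str, sheet_polarization, seed: int) -> DipoleEnsemble:
    """Draw a reproducible dipole ensemble.

    ``isotropic_photoselected``: orientations uniform on the sphere
    (Marsaglia via the seeded generator), weighted by |p.e|^2 -- the
    zero-rotational-diffusion photoselection model.  ``aligned``: all dipoles
    along the sheet polarization with unit weight.
    """
    if n < 1:
        raise ValueError(f"ensemble size must be >= 1, got {n}")
    e = np.asarray(sheet_polarization, dtype=float)
    e = e / np.linalg.norm(e)
    if mode == "aligned":
        p = np.tile(e, (n, 1))
        w = np.ones(n)
    elif mode == "isotropic_photoselected":
        rng = np.random.default_rng(seed)
        p = _uniform_sphere(rng, n)
        w = (p @ e) ** 2
    else:
        raise ValueError(f"unknown ensemble mode {mode!r}")
    return DipoleEnsemble(p, w, mode, seed)


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """Marsaglia (1972) rejection sampling of uniform unit vectors."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        u = rng.uniform(-1.0, 1.0, size=(2 * (n - filled) + 8, 2))
        s = (u**2).sum(axis=1)
        u = u[s < 1.0]
        s = s[s < 1.0]
        take = min(len(u), n - filled)
        u, s = u[:take], s[:take]
        root = np.sqrt(1.0 - s)
        out[filled : filled + take, 0] = 2 * u[:, 0] * root
        out[filled : filled + take, 1] = 2 * u[:, 1] * root
        out[filled : filled + take, 2] = 1.0 - 2 * s
        filled += take
    return out


def analytic_second_moment(sheet_polarization) -> np.ndarray:
    """Infinite-ensemble limit of the photoselected second moment.

    For orientations uniform on the sphere weighted by |p.e|^2,
    C = (I + 2 e e^T) / 5 (trace 1), from the fourth-order sphere moments
    <p_i^4> = 1/5 and <p_i^2 p_j^2> = 1/15.
    """
    e = np.asarray(sheet_polarization, dtype=float)
    e = e / np.linalg.norm(e)
    return (np.eye(3) + 2.0 * np.outer(e, e)) / 5.0
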