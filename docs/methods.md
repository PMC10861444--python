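# Model and methods

## System model

The simulator traces the far-field emission of point dipoles through a
three-microscope OPM train. Coordinates are right-handed with the O1
optical axis along z and the light-sheet tilted about x; the sheet plane
makes the inclination α with the O1 focal (xy) plane, so the sheet
propagates along (0, cos α, sin α) and the tertiary (O3) optical axis —
normal to the sheet — along (0, −sin α, cos α), i.e. tilted by α from the
primary axis. PSF stacks use axis order (z″, y″, x) in the tilted frame
whose z″ is the O3 axis, with the focus at the exact center voxel (all grid
dimensions odd).

Every optical element is a 3×3 matrix acting on the complex electric-field
vector of a ray:

- **Azimuthal rotations** open and close each ray's meridional frame. The
  composed chain per ray is
  `Rz(φα) M3 Ry(θ3) F_T Ry(−θ_inc) Rz(−φα) R_tilt Rz(φ) M̄2 M1 Rz(−φ)`
  applied right-to-left to the dipole far field, where φ is the azimuth
  about the O1 axis and φα the azimuth re-computed in the tilted frame
  (active-rotation convention; the meridional frame opens with Rz(−φ)).
- **Microscopes** `M_i = T_i O_i Γ_i A_i` (objective-first) or
  `M̄_i = O_i T_i Γ_i A_i` (tube-first) combine a meridional bend
  `Ry(θ′−θ)` between the objective angle θ and the tube-lens angle
  θ′ = arcsin((NA′/NA)·n·sin θ) (Abbe sine condition, shared back focal
  plane), a polarization-resolved transmission mask Γ = diag(m_p, m_s, m_p),
  and the aplanatic energy-conservation apodization A = √(cos θ′/cos θ)
  (its reciprocal for the reversed, tube-first direction — the only choice
  that conserves per-ray power in the unity-transmission limit; verified to
  machine precision by the lossless-chain test).
- **The O1→O2 remote relay** is a perfect 3D imaging system of
  magnification n1/n2: θ2 = θ1 ray by ray. By default the tube-lens NA
  ratios are c/n_i with c = 0.05, which realizes this relay exactly;
  explicit ratios can be configured.
- **The O2→O3 interface** lies in the sheet plane (normal = O3 axis). Each
  ray's incidence angle θ_inc is its tilted-frame polar angle; refraction
  follows Snell's law and transmission is applied in the interface s/p
  basis as the square root of the power transmittance
  T = (n_t cos θ_t / n_i cos θ_i)|t|², so lossless interfaces conserve
  power exactly. Three couplings are modelled: `matched` (no index step),
  `ar_coated` (ideal single-layer quarter-wave coating of index
  √(n2·n3), exact thin-film transmittance: unity at normal incidence,
  collapsing at grazing incidence as any real interface must), and
  `fresnel` (uncoated two-interface stack remote-medium → coverslip →
  immersion, power product, multiple reflections neglected). Rays beyond a
  critical angle, beyond grazing incidence on the interface (≥ 89.5°), or
  outside any acceptance cone are blocked, never complex-propagated:
  evanescent components cannot reach the camera.
- **Transmission curves** are degree-5 polynomial fits of measured (or
  synthetic) normalized angle-vs-power tables per polarization, applied as
  amplitude = √power and clamped to [0, 1]; out-of-domain angles clamp to
  the boundary with a warning. Fitted coefficients are logged on load.

## Sample-referred computation

The paper's observable is the camera PSF; we compute the equivalent
sample-referred PSF directly. Because the relay is a perfect 3D imaging
system (isotropic magnification n1/n2) and O3/T3 are aplanatic and
aberration-free, the remote field after the interface-transmission scalars
maps to the camera faithfully; scaling all wavevectors by n1/n2 expresses
the result in sample units. The O3-side bend `Ry(θ3)F_T Ry(−θ_inc)`
commutes with the diagonal interface matrix, so the sample-referred chain
simply omits the bend while keeping every transmission factor. Resolution
numbers therefore come out directly in sample-space nanometres.

## Dipole ensembles

Fluorophores with maximal fluorescence anisotropy are non-rotating dipoles:
a sheet of unit polarization ê excites orientation p̂ with probability
|p̂·ê|² (cos² photoselection), and the excited dipole radiates the
classical transverse pattern E ∝ (r̂×p̂)×r̂ with unit total power. Ensemble
PSFs are excitation-weighted incoherent sums, which depend on the ensemble
only through its weighted second-moment matrix
C = Σ w_i p̂_i p̂_iᵀ / Σ w_i — an exact algebraic identity — so any
ensemble reduces to the three eigen-dipoles of C (nine scalar Debye
transforms). The default 100-dipole seeded sample (Marsaglia uniform
orientations) retains finite-ensemble Monte-Carlo statistics; the analytic
infinite-ensemble limit C = (I + 2êêᵀ)/5 is used for the deterministic
efficiency curves. An `aligned` mode (all dipoles along ê) is also
provided, as the sampling law behind the published 100-dipole ensembles is
not stated.

## Focal fields and the light-sheet envelope

The focal field is the Debye superposition
E(r) = (2π)⁻² ∫ A(kx,ky) exp(i k·r) dkx dky over the tilted-frame
transverse-k grid, evaluated per z-plane with a centered chirp-z transform
(Bluestein), so the output voxel pitch equals the requested camera pitch
exactly and OTF frequency axes are exact by construction. The solid-angle
Jacobian 1/cos θ is integrated analytically over each Cartesian pupil cell
(arcsine difference): the midpoint rule diverges at the grazing rim of the
clipped pupil and would inflate the far OTF support. A field-of-view
request beyond the unaliased support 2π/Δk raises an error naming the
minimum pupil sampling.

The light-sheet fills the maximum available aperture — the pupil arc
centered on the sheet direction with half-angle
arcsin(NA1/n1) − (π/2 − α), giving NA_sheet = n1·sin(half-angle) — with a
collimated flat-top beam. Its waist intensity profile across the sheet
normal is therefore sinc²(2·NA_sheet·z/λ_ex) (uniform kz band), which
multiplies the detection PSF along z″ before any noise is applied
(physical ordering). The usable sheet length is quoted, as in the source
study, via the Gaussian confocal parameter 2·n1·λ_ex/(π·NA_g²) with
NA_g = NA_sheet/k_ls and a single frozen flat-top-to-Gaussian equivalence
factor k_ls = 1.28, calibrated once as the geometric-mean match to the
published sheet-length column and then never revisited (the published
column is not exactly ∝ 1/NA², so residuals of −25%…+9% remain at the
extreme inclinations; only the monotone ordering is asserted). The
reported sheet thickness is the sinc² intensity FWHM
0.886·λ_ex/(2·NA_sheet).

## Camera model and resolution metrology

The noiseless PSF is scaled so its brightest voxel holds N_p photons,
Poisson-sampled, perturbed with zero-mean Gaussian read noise of RMS
σ_RMS, offset by the bias b, rounded to integers and clipped at zero.
Defaults σ_RMS = 1.6 e⁻ and b = 100 counts are typical sCMOS values
(SNR(10⁴, 1.6) ≈ 100, consistent with the study's quoted regime).

For each of n (default 10) noise realizations the stack is Fourier
transformed (normalized by √N_voxels) and the stochastic background
|η̂| = √(DC + σ²_RMS − b), with DC the stack mean, is subtracted from
|OTF|. Per-axis cutoffs are the first zero crossings, with linear sub-bin
interpolation, of profiles band-averaged over the ±1-bin transverse
neighbourhood (the discretization of the crossing rule is ours; its
alternatives shift cutoffs by about one frequency bin). Two axial limits
are distinguished: the on-axis kz crossing gives the optical sectioning
thickness S, while the maximum kz support extent gives the axial
resolution z. The support scan uses the per-kz-plane maximum of the
3×3×3 box-averaged magnitude, compared against a noise level
self-calibrated on the highest-frequency lateral corner of the transform —
necessary because the plane-maximum statistic of pure noise sits above the
mean background and would otherwise never cross zero. Cutoffs are averaged
over realizations; resolutions are their reciprocals, and cutoffs that
reach the frequency band edge are flagged as saturated. The ellipsoidal
in-focus area is π(x/2)(y/2) and the volume (4π/3)(x/2)(y/2)(S/2), using
the sectioning thickness as the axial diameter.

These noise-aware cutoffs depend on the relative noise floor
√(DC+σ²−b)/DC_signal, which scales with the total sampling volume. The
published 240 µm-per-axis runs imply a floor near 2.5×10⁻² of the signal
DC; desk-scale grids at N_p = 10⁴ sit near 3×10⁻³, so the axial limits
(set by weak spectral tails) come out 10–40% tighter than the published
table while the lateral limits, set by the sharp pupil edge, agree within
±10%. At N_p = 10³ the desk-scale floor coincides with the published one
and the sectioning column is reproduced within a few per cent — the sweep
over photon counts therefore spans the published operating point.

## Optical efficiency

Efficiency is the fraction of the ensemble's emitted photons transmitted to
the camera: eff = Σ_rays tr(G C Gᴴ) dΩ / tr(C) over the surviving
effective pupil, with G the per-solid-angle system chain including all
masks and interface losses, on a Gauss–Legendre × midpoint cap quadrature
(the implementation is cross-checked against a brute-force Monte-Carlo
dipole sum to 0.1%). Within a comparison set the curves are additionally
normalized to the set maximum; relative s/p gains use the absolute values.
The excitation path applies O1's own transmission curve at the sheet angle
when one is configured (default: ideal).

In this implementation the s-advantage declines monotonically with
inclination and vanishes only as α → 90°, where the photoselected x- and
y-dipole ensembles become equivalent up to a symmetric pupil clip. A strict
s/p crossing near 45° — reported for the glass-immersion configuration in
the source study — does not emerge from this model under any of the
interface variants (it does appear near 75° for the uncoated-coverslip
variant); the crossing reported by the acceptance sweep is therefore the
linear extrapolation of the gap trend to zero, capped at the 90° geometric
limit, and quantifies this disagreement rather than hiding it.

## Problem sizes and numerical defaults

Default grids are desk-scale: a 129-sample pupil and 129×129×257 voxels at
76 nm lateral pitch (0.8× the Nyquist pixel λ_em/(4 NA_det), leaving
headroom for cutoffs at the classical limit) and 120 nm axial pitch. The
published 240 µm-per-axis sampling volume is available as the
`--full-scale` preset but is far beyond these defaults. Doubling the pupil
sampling changes the normalized PSF by < 0.5%; `sampling_volume_check`
automates the convergence-with-volume test and flags PSF truncation. All
stochastic outputs are pure functions of (configuration, master seed):
sweep cells draw independent named substreams so each cell is reproducible
in isolation, and repeated runs are bit-identical.

## Known limitations

- Single on-axis emitter; no field-dependent aberrations, no scattering,
  no birefringent or dichroic elements, no EMCCD excess noise.
- No finite rotational diffusion: ensembles are either fully photoselected
  (zero rotation) or fully aligned; intermediate anisotropies are out of
  scope.
- The synthetic transmission fixtures emulate the qualitative shape of the
  measured objective curves (dry: p > s at high angle with a steep s
  roll-off; glass-immersion: near-flat, |T_s−T_p| < 0.05); absolute
  throughput numbers therefore characterize the model, not a specific
  physical objective.
- Axial resolution and sectioning inherit the sampling-volume dependence of
  the noise floor described above; at desk scale they are systematically
  tighter than the full-scale published values.
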