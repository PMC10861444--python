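# opmsim — vectorial diffraction simulation of oblique plane microscopy

Oblique plane microscopy (OPM) is a single-objective light-sheet technique:
a high-NA primary objective O1 both launches an inclined light-sheet and
collects the fluorescence, a remote-focusing relay (O1→O2, magnification
n1/n2) reproduces the sample volume aberration-free in a remote space, and a
tilted tertiary microscope (O3 + tube lens) images the oblique sheet plane
in focus. The tilted geometry clips the effective pupil (the O2∩O3
acceptance overlap) and inserts a refractive-index step in front of O3, so
both resolution and light throughput depend on the light-sheet inclination
α **and on its polarization** — s (E ⊥ tilt plane) or p (E in the tilt
plane, along the sheet normal).

`opmsim` predicts these effects quantitatively for arbitrary system
configurations:

- **Polarization ray tracing** — every element is a 3×3 Jones matrix acting
  on the full electric-field vector of each ray: azimuthal rotations,
  sine-condition lens bends with aplanatic apodization √(cos θ′/cos θ),
  polarization-resolved objective transmission masks (degree-5 polynomial
  fits of measured angle-vs-power tables), and Fresnel / anti-reflection
  interface transmission at the O2→O3 index step.
- **Dipole emitters with maximal fluorescence anisotropy** — non-rotating
  dipoles photoselected by the sheet polarization ê with probability
  |p̂·ê|²; ensemble PSFs are excitation-weighted incoherent sums, computed
  exactly through the 3×3 second-moment matrix of the ensemble.
- **FFT Debye focal fields** — the traced pupil is propagated per z-plane by
  a centered chirp-z transform so the voxel pitch equals the requested
  camera pitch exactly; the light-sheet waist profile (sinc², flat-top
  pupil fill) multiplies the detection PSF along the sheet normal.
- **Noise-aware resolution metrology** — camera model (peak scaled to N_p
  photons → Poisson → Gaussian read noise σ_RMS → bias → quantization),
  SNR = N_p/√(N_p+σ²_RMS), OTF background |η̂| = √(DC + σ²_RMS − b), and
  per-axis resolution limits from the first zero crossing of the
  background-subtracted |OTF|: lateral x/y cutoffs, on-axis kz cutoff
  (optical sectioning S) and maximum kz support extent (axial limit z),
  averaged over ten noise realizations. Ellipsoidal PSF area
  π(x/2)(y/2) and volume (4π/3)(x/2)(y/2)(S/2).
- **Optical efficiency** — pupil-integrated, excitation-weighted fraction of
  emitted photons transmitted to the camera, per polarization and
  inclination.

## Worked example

Simulate the main published configuration (1.35 NA silicone O1, 0.95 NA dry
O2, 1.0 NA glass-immersion AR-coated O3, 488/507 nm, α = 30°, 100-dipole
photoselected ensemble, 10⁴ photons at the brightest pixel):

```python
import math
from opmsim import ensemble_psf, optical_efficiency, resolution_limits
from opmsim.sweep import default_table_config

cfg = default_table_config(seed=1, alpha=math.radians(30.0))
for pol in ("p", "s"):
    c = cfg.replace(sheet_polarization=pol)
    rep = resolution_limits(ensemble_psf(c), c)
    eff = optical_efficiency(c)
    print(f"{pol}: x {rep.res_x:.0f} nm  y {rep.res_y:.0f} nm  "
          f"S {rep.sectioning:.0f} nm  V {rep.psf_volume:.4f} µm³  "
          f"L_ls {rep.sheet_length:.1f} µm  eff {eff:.3f}")
```

prints (desk-scale 129×129×257 grid)

```
p: x 189 nm  y 236 nm  S 533 nm  V 0.0125 µm³  L_ls 6.1 µm  eff 0.245
s: x 193 nm  y 234 nm  S 544 nm  V 0.0128 µm³  L_ls 6.1 µm  eff 0.275
```

x/y are the noise-limited lateral resolution limits referred to sample
space, S the optical sectioning thickness set jointly by the light-sheet
waist and the noise floor, V the ellipsoidal PSF volume, L_ls the usable
sheet length (confocal parameter), and eff the fraction of emitted photons
reaching the camera — about 12% higher for the s-polarized sheet here,
because s-excited dipoles lie perpendicular to the tilt plane and radiate
into the detection cone.

The same pipeline is scriptable from the shell:

```bash
opmsim simulate --config myscope.yaml --out run/     # PSF/OTF TIFFs + report
opmsim sweep --alphas 20,25,30,35,40 --photons 1e2,1e4
opmsim efficiency --alphas 20:60:1
opmsim fixtures --out fixtures/                      # synthetic transmission tables
opmsim validate                                      # physical invariant checks
```

Configurations are YAML (angles in degrees, lengths in nm); see
`opmsim.config.SystemConfig` for the schema and defaults, and
`docs/methods.md` for the model, its assumptions and numerical choices.

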