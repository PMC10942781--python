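# Methods

This note records the physical model, the numerical choices, and the
calibrations behind `ottlsm`, in the spirit of a simulator's methods
section: what is modelled, what is idealized, and what the synthetic
studies can and cannot say about real tissue.

## Beam and sheet model

**Representation.** The excitation beam is radially symmetric and carried
by its radial angular spectrum A(κ).  The field anywhere is the exact
scalar angular-spectrum integral

    E(r, z) = (1/2π) ∫ A(κ) J₀(κr) exp(i z √(k² − κ²)) κ dκ,  k = 2πn/λ,

evaluated by quadrature on the κ grid.  Propagation multiplies spectral
phases only, so it is unitary by construction; the power-conservation
tests integrate |E|² over the sampled real-space grid instead, which
verifies that the grid actually contains the beam's energy (radial extent
140 µm, fine pitch 0.01 µm near the axis for metrology, 0.1 µm beyond
8 µm for the envelope — the configured pitch must satisfy λ/(4NA)
Nyquist sampling).

**Bessel–Gauss parameterization.** The axicon/relay chain is not modelled
element by element; the focal-region beam is parameterized directly by
what the instrument specifies in sample space: the effective NA (0.34,
paraxially (D/2)/f for the 6.8 mm annular beam on a 10 mm focal-length
objective) and an annulus fractional width Δ — the FWHM of the spectral
intensity ring divided by κ₀ = 2πNA/λ.  The beam at focus is J₀(κ₀r)²
under a wide Gaussian envelope; the Bessel-zone length scales as 1/Δ.

**Calibration of Δ.** The instrument reports the design outcome of its
sheet (two-photon depth of field 180 µm), not its pupil ring thickness.
`scripts/calibrate_optics.py` root-finds Δ so that the simulated
two-photon sheet's on-axis FWHM along the propagation axis equals 180 µm
at NA 0.34 and λ = 770 nm, giving Δ = 0.01628, stored as the default.
This is a one-time calibration of a single scalar; the transverse physics
(lobe width, side-lobe structure) is fixed by NA alone.

**Sheet formation.** The galvo sweeps the beam along Y; the camera
integrates over the sweep, so the sheet excitation density is the
scan-axis average of the instantaneous intensity — of its square in
two-photon mode, since two-photon excitation is quadratic in intensity.
Squaring before averaging is what suppresses the Bessel side lobes: the
simulated side-lobe energy fraction at focus drops from 0.81 (one-photon)
to 0.36 (two-photon).

**Sheet thickness: two numbers, deliberately.** `sheet_metrics` reports
both

* `thickness_fwhm_um` — the FWHM of the scan-averaged two-photon
  excitation density across the sheet (0.59 µm at the defaults), and
* `beam_fwhm_um` — the central-lobe intensity FWHM of the underlying
  beam (0.81 µm; analytically 2x½λ/(2πNA) with J₀(x½)² = ½).

The nominal "sheet thickness" an instrument designer quotes is the beam
central-lobe width, and that is the number this package's regression
anchors to the instrument's stated 0.9 µm design figure.  The
scan-averaged two-photon FWHM is necessarily ≈ √2 narrower (squaring a
J₀² lobe) and cannot be 0.9 µm at NA 0.34 for any annulus width, which is
why it is reported separately rather than forced to match.

**Idealizations.** Scalar, monochromatic, aberration-free propagation; no
polarization, no femtosecond pulse structure, no spherical aberration
from the air/immersion index step (the real instrument's lateral
resolution is degraded ~28% by it; no aberration coefficients are
available to model, so the measured-resolution PSF below absorbs the
effect operationally).

## Phantoms

Phantoms are pure functions of (spec, seed): two co-registered
non-negative density fields — nuclear fluorescence and SHG collagen — on
an axis-aligned (Z, Y, X) grid, Z positive downward from the surface.
Default pitches: 0.1 µm for bead grids (resolving 0.5 µm spheres),
0.5 µm for tissue (desk-scale memory; the instrument's own pixel pitch,
0.324 µm, lies between).

Spheres are rendered with a one-voxel linear edge ramp whose effective
radius is shrunk by h²/(12R) so the integrated mass matches the analytic
sphere volume to O(h⁴) (verified to 2%).  Nuclei are placed by
dart-throwing Poisson-disc sampling (minimum separation one nuclear
diameter) — seedable and free of unrealistic overlaps.  Collagen is
random anisotropic line segments blurred by a 1-voxel Gaussian: enough
for SHG-channel contrast, with no claim to fibre physics.  The
`membrane_bright` labeling mode (shell 3× core) mimics nuclear-envelope-
dominated labeling seen with propidium iodide.  Every generator exports
its ground truth (centres, radii, boundaries), so downstream metrology
never re-detects structures blindly.

What the tissue presets do **not** emulate: histological texture,
refractive-index heterogeneity, vasculature, immune infiltrate, or any
quantitative contrast calibrated to real specimens.  Passing tests show
the pipeline's geometry and statistics are right, not that real tissue
would produce these images.

## Forward model

Frame *i*, pixel (u, v) samples world X = xᵢ + v·p·cosθ, Y = u·p,
Z = v·p·sinθ (θ = 45°, p = 600/1850 µm) by trilinear interpolation,
voxel-centre convention (index k ↦ (k+0.5)·pitch).  A point emitter at
(X₀, Z₀) is brightest in frame round((X₀ − Z₀·cotθ − x₀)/Δx).

**PSF.** The default detection PSF is an isotropic 0.9 µm-FWHM Gaussian —
the instrument's *measured* system resolution, which already includes
excitation-sheet confinement and aberration.  It is applied to the
phantom in world space: the frame axes are mutually oblique in world
coordinates (the frame-index axis advances along X only), so an
axis-aligned blur in frame space would render an anisotropic world PSF
with ~1.6× the intended X width.  Because the measured PSF subsumes the
sheet, explicit sheet weighting (axial DOF envelope plus a 3-tap
thickness integral) is applied only when a `SheetProfile` is passed in,
intended for use with a theoretical-NA PSF; the default bead study uses
the measured PSF alone, avoiding double-counted blur.  World-space
application commutes with the slowly varying attenuation factors to
excellent approximation (attenuation scale ≥ 40 µm vs 0.9 µm PSF).

**Attenuation.** Single-scattering Beer–Lambert on vertical ballistic
paths: two-photon signal ∝ exp(−2d/l_ex − d/l_em), one-photon
∝ exp(−d/l_ex − d/l_em).  No radiative transport; this reproduces the
qualitative depth ordering (long wavelengths image deeper) at desk scale.

**Noise.** Poisson shot noise on a photons-per-intensity scale plus
Gaussian read noise, seeded per (seed, channel); 16-bit clipping is
counted and warned about, never silent.  Noise off ⇒ bit-deterministic
and exactly linear in channel gain.

## Reconstruction

Deskew pull-resamples every output voxel through the inverse acquisition
mapping (gather, so no normalization holes), at the strip's native
sampling: output pitch (p, p, p·sinθ) for (X, Y, Z), half-open voxels,
0-based indices.  Out-of-swath voxels carry NaN, distinct from measured
zero, and the mask survives stitching and plane extraction.  Tilt 0° is
a pure restack (bitwise).  Stitching joins volumes on the union grid with
linear feathering; offsets come from stage metadata, optionally refined
by phase correlation on the overlap (the instrument's manual strip
joining, automated).  Interpolation (nearest/linear) and the output grid
are exposed as options because the original processing chain does not
specify them.

## Metrology

* **Resolution:** per-axis profiles through ground-truth bead centres
  (peak-refined), background-subtracted, FWHM by linear interpolation of
  the half-maximum crossings (Gaussian fit available; both agree to 2% on
  synthetic spots across σ = 0.3–1.5 µm).  Beads closer than a minimum
  separation, masked, or unresolved are excluded and counted.
  The end-to-end bead study (0.5 µm beads, 0.9 µm PSF) reports
  ~0.94–1.03 µm across axes: the analytic PSF⊗sphere FWHM is 0.94 µm, and
  the two trilinear resamplings (acquisition sampling, deskew gather) at
  the 0.32 µm instrument pitch add a few percent — the same broadening a
  real processing chain incurs.
* **Imaging depth:** deepest 5 µm depth bin whose nuclear CNR —
  (mean over ground-truth nuclear voxels − mean background)/background
  SD, background outside dilated nuclei — stays ≥ 1.  Threshold, bin
  width and the stop-at-first-failure rule are stated here because
  "imaging depth" has no standard operational definition.
* **Budgets:** strips = ⌈W/600 µm⌉, frames = strips × ⌈L/step⌉, time =
  frames/fps; bytes = frames × 1850 × 512 × 2.  GB is decimal (10⁹).  The
  printed-budget convention (bytes at the minute-rounded frame count,
  168,000 frames ⇒ 318 GB for 1 cm²) is exposed alongside the exact count
  (170,000 frames ⇒ 322 GB).  Strip overlap and stage turnaround are
  excluded by default (an overlap fraction knob inflates strips).

## Calibrated study parameters

Tissue optical properties are **calibrations, not measurements** — no
scattering lengths are published for these preparations.  The skin study
uses l_em(515 nm) = 40 µm, l_em(640 nm) = 60 µm, l_em(385 nm) = 15 µm
(monotone in wavelength by construction), l_ex(770 nm, two-photon)
= 45 µm, l_ex(~445 nm, one-photon comparison) = 4.4 µm, detector noise
floor 9 intensity units; together these put the estimated two-photon
imaging depth at 60 µm vertical and the one-photon Gaussian-sheet
comparison at 20 µm — the ~3× two-photon advantage the instrument class
exhibits.  The 80 µm-deep skin phantom uses 1.5 nuclei/1000 µm³ so every
5 µm depth bin holds enough nuclei for a stable CNR estimate.

Desk-scale problem sizes (in `ottlsm.presets`): bead study 15×30×30 µm at
0.1 µm pitch, frames stepped at the pixel pitch (characterization-grade
sampling, finer than the 1 µm tissue-survey step); skin study
80×60×60 µm at 0.5 µm pitch, 1 µm steps.  These sizes keep a full
simulate–acquire–reconstruct–measure cycle in tens of seconds on one CPU
while leaving every geometric relationship identical to the full-scale
instrument.

## Virtual staining scope

The adversarial style-transfer network that produces publication-grade
virtual H&E is a GPU-scale training artifact whose value lies in learned
weights; it is intentionally **not** implemented.  The package implements
everything up to the training hand-off — 512×512 patch cropping (row-
major, edge tiles dropped and recorded) and the exact 6× augmentation
(identity, rot90/180/270, flip_v, flip_h, fixed order, so 2,387 crops
yield 14,322 patches) with a traceable manifest — plus a deterministic
Beer–Lambert renderer using the standard H&E color-deconvolution OD
vectors (hematoxylin on the nuclear channel, eosin on the SHG channel),
so the end-to-end demo still produces an H&E-like image.  The 6×
augmentation factor is an inference from the exact divisibility of the
published patch totals by six; the crop stride used for those totals is
not stated and is exposed as a parameter.

## Known limitations

* Ballistic Beer–Lambert attenuation cannot produce the diffuse
  background haze of real deep-tissue imaging; CNR-vs-depth curves are
  cleaner than reality.
* The scalar Bessel–Gauss model omits aberration, so the simulated
  lateral resolution is the design value unless the measured-PSF mode is
  used (the default).
* Stitching registration assumes translations only; no rotation, scale
  or illumination matching.
* Tissue presets are geometric caricatures adequate for contrast and
  geometry tests, not for training or validating diagnostic models.
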