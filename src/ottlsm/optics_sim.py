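"""Scalar-diffraction model of the axicon-generated Bessel excitation sheet.

The illumination arm of an open-top two-photon light-sheet microscope
converts an expanded Gaussian laser beam into a Bessel beam with an axicon,
relays it through the objective, and sweeps it laterally with a galvo to
form a thin, extended-depth-of-field excitation sheet.  In sample space the
focal-region beam is modelled as a Bessel-Gauss beam: a thin annular
angular spectrum of half-cone transverse wavenumber ``kappa0 = 2*pi*NA/lambda``
with a Gaussian cross-section whose fractional width sets the length of the
Bessel zone (the depth of field).

The beam is represented by its radial angular spectrum ``A(kappa)``.
Propagation is exact scalar angular-spectrum propagation,

    E(r, z) = (1/2pi) * integral A(kappa) * J0(kappa r) * exp(i kz z) kappa dkappa,
    kz = sqrt(k^2 - kappa^2),   k = 2 pi n / lambda,

evaluated by quadrature on the kappa grid.  This is unitary, so optical
power is conserved under lossless propagation by construction; the tests
verify conservation on the *sampled real-space field* instead, which probes
the adequacy of the radial grid.

Units: lengths in micrometres unless a field name says otherwise
(config wavelengths in nm, pupil-side lengths in mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0

__all__ = [
    "SamplingGrid",
    "OpticalConfig",
    "BeamField",
    "SheetProfile",
    "bessel_gauss_field",
    "gaussian_field",
    "propagate",
    "make_sheet",
    "sheet_metrics",
    "effective_na",
    "bessel_lobe_fwhm",
    "J0_HALF_INTENSITY_ROOT",
    "J0_FIRST_ZERO",
]

# roots of J0(x)^2 = 1/2 and J0(x) = 0, frozen from scipy root-finding
J0_HALF_INTENSITY_ROOT = 1.1263642393772584
J0_FIRST_ZERO = 2.404825557695773

#: annulus fractional width (FWHM of |A(kappa)|^2 over kappa0) calibrated so
#: the two-photon sheet depth of field is 180 um at NA 0.34, lambda 770 nm.
#: See scripts/calibrate_optics.py.
CALIBRATED_ANNULUS_FRACTION = 0.01628


def _fwhm_interp(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum with linear interpolation of the crossings.

    ``x`` must be sorted ascending; the profile may be one-sided (symmetric
    about x=0), in which case pass the mirrored arrays.
    """
    y = np.asarray(y, dtype=float)
    if y.max() <= 0:
        raise ValueError("profile is non-positive; FWHM undefined")
    y = y / y.max()
    above = np.where(y >= 0.5)[0]
    lo, hi = above[0], above[-1]
    if lo > 0:
        xl = np.interp(0.5, [y[lo - 1], y[lo]], [x[lo - 1], x[lo]])
    else:
        xl = x[0]
    if hi < len(x) - 1:
        xr = np.interp(0.5, [y[hi + 1], y[hi]], [x[hi + 1], x[hi]])
    else:
        xr = x[-1]
    return float(xr - xl)


@dataclass(frozen=True)
class SamplingGrid:
    """Sampling of the simulated focal region.

    r axes: a fine radial grid (``r_fine_max_um`` at ``r_pitch_um``) for
    profile metrology plus a coarse extension out to ``r_max_um`` that
    captures the Bessel-Gauss envelope for power/scan-average integrals.
    s axis: propagation positions about the focus.
    """

    r_pitch_um: float = 0.01
    r_fine_max_um: float = 8.0
    r_coarse_pitch_um: float = 0.1
    r_max_um: float = 140.0
    s_pitch_um: float = 2.0
    s_max_um: float = 240.0
    n_kappa: int = 301

    def radial_axis(self) -> np.ndarray:
        fine = np.arange(0.0, self.r_fine_max_um, self.r_pitch_um)
        coarse = np.arange(self.r_fine_max_um, self.r_max_um + 1e-9,
                           self.r_coarse_pitch_um)
        return np.concatenate([fine, coarse])

    def s_axis(self) -> np.ndarray:
        return np.arange(-self.s_max_um, self.s_max_um + 1e-9, self.s_pitch_um)


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the illumination/detection arms.

    Defaults mirror the instrument: 770 nm two-photon excitation, effective
    illumination NA 0.34 (a 6.8 mm annular beam on the back aperture of a
    10 mm focal-length 20x objective), detection NA 0.42, quartz/glycerol
    immersion at refractive index 1.45.  Emission wavelengths per channel:
    proflavine ~515 nm, propidium iodide ~640 nm, SHG at half the
    excitation wavelength (385 nm).
    """

    excitation_wavelength_nm: float = 770.0
    illumination_na: float = 0.34
    illumination_na_fractional_width: float = CALIBRATED_ANNULUS_FRACTION
    detection_na: float = 0.42
    medium_ri: float = 1.45
    emission_wavelength_nm: dict = field(
        default_factory=lambda: {"proflavine": 515.0, "pi": 640.0, "shg": 385.0})
    back_aperture_ring_diameter_mm: float = 6.8
    objective_focal_length_mm: float = 10.0
    grid: SamplingGrid = field(default_factory=SamplingGrid)

    def __post_init__(self) -> None:
        if not (0.0 < self.illumination_na < self.medium_ri):
            raise ValueError("illumination NA must satisfy 0 < NA < medium RI")
        if not (0.0 < self.detection_na < self.medium_ri):
            raise ValueError("detection NA must satisfy 0 < NA < medium RI")
        if self.excitation_wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if any(v <= 0 for v in self.emission_wavelength_nm.values()):
            raise ValueError("emission wavelengths must be positive")
        lam_um = self.excitation_wavelength_nm * 1e-3
        if self.grid.r_pitch_um > lam_um / (4.0 * self.illumination_na):
            raise ValueError(
                f"radial pitch {self.grid.r_pitch_um} um too coarse: Nyquist "
                f"requires <= {lam_um / (4 * self.illumination_na):.4f} um")
        if self.back_aperture_ring_diameter_mm > 2 * self.objective_focal_length_mm:
            warnings.warn("ring diameter exceeds 2f: paraxial NA invalid",
                          stacklevel=2)

    @property
    def excitation_wavelength_um(self) -> float:
        return self.excitation_wavelength_nm * 1e-3


@dataclass
class BeamField:
    """Radially symmetric scalar beam, carried by its angular spectrum.

    ``amplitude`` holds the complex field sampled on ``r_um`` at the current
    plane ``z_um`` (z measured from focus along the propagation axis).  The
    spectrum is normalized to unit total optical power.
    """

    kappa: np.ndarray          # transverse wavenumbers, rad/um
    spectrum: np.ndarray       # complex A(kappa), unit power
    kappa_weight: np.ndarray   # quadrature weights d(kappa)
    wavelength_um: float       # vacuum wavelength
    medium_ri: float
    r_um: np.ndarray
    amplitude: np.ndarray
    z_um: float = 0.0

    @property
    def k_medium(self) -> float:
        return 2.0 * np.pi * self.medium_ri / self.wavelength_um

    def _kz(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.k_medium**2 - self.kappa**2, 0.0))

    def evaluate(self, r_um: np.ndarray, z_um: float | np.ndarray) -> np.ndarray:
        """Complex field at radii ``r_um`` and plane(s) ``z_um`` (from focus)."""
        r = np.atleast_1d(np.asarray(r_um, dtype=float))
        z = np.atleast_1d(np.asarray(z_um, dtype=float))
        kz = self._kz()
        # subtract the carrier so the phase factor stays well-conditioned
        phase = np.exp(1j * np.outer(kz - kz.mean(), z))
        coeff = self.spectrum * self.kappa * self.kappa_weight / (2.0 * np.pi)
        out = j0(np.outer(r, self.kappa)) @ (coeff[:, None] * phase)
        return out

    def intensity(self, r_um: np.ndarray, z_um: float | np.ndarray) -> np.ndarray:
        return np.abs(self.evaluate(r_um, z_um)) ** 2

    def power(self) -> float:
        """Total power from the sampled real-space amplitude, 2*pi*int |E|^2 r dr."""
        return float(2.0 * np.pi * np.trapezoid(
            np.abs(self.amplitude) ** 2 * self.r_um, self.r_um))

    def spectral_power(self) -> float:
        return float(np.sum(np.abs(self.spectrum) ** 2 * self.kappa
                            * self.kappa_weight) / (2.0 * np.pi))


def _normalize_power(kappa, spectrum, weight):
    p = np.sum(np.abs(spectrum) ** 2 * kappa * weight) / (2.0 * np.pi)
    return spectrum / np.sqrt(p)


def bessel_gauss_field(cfg: OpticalConfig) -> BeamField:
    """Focal-region Bessel-Gauss beam for the configured annular pupil.

    The angular spectrum is a Gaussian annulus centred on
    ``kappa0 = 2 pi NA / lambda`` whose intensity FWHM is
    ``illumination_na_fractional_width * kappa0``.  At focus the radial
    intensity is J0(kappa0 r)^2 under a wide Gaussian envelope, with the
    on-axis global maximum at r = 0.
    """
    lam = cfg.excitation_wavelength_um
    kappa0 = 2.0 * np.pi * cfg.illumination_na / lam
    frac = cfg.illumination_na_fractional_width
    if frac <= 0:
        raise ValueError("annulus fractional width must be positive")
    # |A|^2 = exp(-(kappa-kappa0)^2 / s_int^2) has FWHM 2*sqrt(ln 2)*s_int
    s_int = frac * kappa0 / (2.0 * np.sqrt(np.log(2.0)))
    kmax = cfg.medium_ri * 2.0 * np.pi / lam
    lo = max(kappa0 - 6 * s_int, 1e-6)
    hi = min(kappa0 + 6 * s_int, 0.999 * kmax)
    kappa = np.linspace(lo, hi, cfg.grid.n_kappa)
    weight = np.full_like(kappa, kappa[1] - kappa[0])
    spectrum = np.exp(-((kappa - kappa0) ** 2) / (2.0 * s_int ** 2))
    spectrum = _normalize_power(kappa, spectrum.astype(complex), weight)
    r = cfg.grid.radial_axis()
    fld = BeamField(kappa=kappa, spectrum=spectrum, kappa_weight=weight,
                    wavelength_um=lam, medium_ri=cfg.medium_ri,
                    r_um=r, amplitude=np.zeros_like(r, dtype=complex))
    fld.amplitude = fld.evaluate(r, 0.0)[:, 0]
    return fld


def gaussian_field(cfg: OpticalConfig, waist_um: float) -> BeamField:
    """TEM00 Gaussian beam at its waist (used as the sheet-comparison oracle).

    Angular spectrum A(kappa) = exp(-kappa^2 w0^2 / 4) gives
    E(r, 0) = exp(-r^2 / w0^2) exactly.
    """
    if waist_um <= 0:
        raise ValueError("waist must be positive")
    lam = cfg.excitation_wavelength_um
    kmax = min(6.0 / waist_um, 0.999 * 2.0 * np.pi * cfg.medium_ri / lam)
    kappa = np.linspace(1e-6, kmax, cfg.grid.n_kappa)
    weight = np.full_like(kappa, kappa[1] - kappa[0])
    spectrum = np.exp(-(kappa ** 2) * waist_um ** 2 / 4.0).astype(complex)
    spectrum = _normalize_power(kappa, spectrum, weight)
    r = cfg.grid.radial_axis()
    fld = BeamField(kappa=kappa, spectrum=spectrum, kappa_weight=weight,
                    wavelength_um=lam, medium_ri=cfg.medium_ri,
                    r_um=r, amplitude=np.zeros_like(r, dtype=complex))
    fld.amplitude = fld.evaluate(r, 0.0)[:, 0]
    return fld


def plane_wave_field(cfg: OpticalConfig) -> BeamField:
    """Uniform plane wave (single on-axis spectral component)."""
    lam = cfg.excitation_wavelength_um
    kappa = np.array([1e-9])
    weight = np.array([1.0])
    spectrum = np.array([1.0 + 0.0j])
    r = cfg.grid.radial_axis()
    fld = BeamField(kappa=kappa, spectrum=spectrum, kappa_weight=weight,
                    wavelength_um=lam, medium_ri=cfg.medium_ri,
                    r_um=r, amplitude=np.zeros_like(r, dtype=complex))
    fld.amplitude = fld.evaluate(r, 0.0)[:, 0]
    return fld


def propagate(fld: BeamField, distance_um: float) -> BeamField:
    """Angular-spectrum propagation by ``distance_um`` along the beam axis."""
    if not np.isfinite(distance_um):
        raise ValueError("propagation distance must be finite")
    new = replace(fld, z_um=fld.z_um + distance_um)
    new.amplitude = new.evaluate(new.r_um, new.z_um)[:, 0]
    return new


@dataclass
class SheetProfile:
    """Scanned excitation sheet sampled on (s = propagation, t = thickness).

    ``density`` is the scan-axis-averaged excitation density, elementwise
    the square of the instantaneous intensity in two-photon mode, peak
    normalized to 1.  ``beam_fwhm_um`` is the central-lobe intensity FWHM of
    the underlying (one-photon) beam at focus — the width instrument
    designers quote as the nominal sheet thickness.
    """

    density: np.ndarray      # (n_s, n_t), >= 0, max = 1
    s_um: np.ndarray
    t_um: np.ndarray
    mode: str                # "one_photon" | "two_photon"
    beam_fwhm_um: float
    scan_range_um: float

    @property
    def s_pitch_um(self) -> float:
        return float(self.s_um[1] - self.s_um[0])

    @property
    def t_pitch_um(self) -> float:
        return float(self.t_um[1] - self.t_um[0])

    def on_axis(self) -> np.ndarray:
        i0 = int(np.argmin(np.abs(self.t_um)))
        return self.density[:, i0]

    def focus_profile(self) -> np.ndarray:
        s_idx = int(np.argmax(self.on_axis()))
        return self.density[s_idx, :]


def make_sheet(fld: BeamField, scan_range_um: float,
               mode: str = "two_photon",
               grid: SamplingGrid | None = None) -> SheetProfile:
    """Scan-averaged excitation sheet from a beam swept along the lateral axis.

    The sheet density at (s, t) is the scan-axis average of the beam
    intensity (two-photon: of its square) over lateral offsets y in
    [-scan_range/2, scan_range/2].  ``scan_range_um = 0`` returns the
    unscanned beam cross-section, for which the two-photon map is exactly
    the elementwise square of the one-photon map.
    """
    if mode not in ("one_photon", "two_photon"):
        raise ValueError(f"unknown mode {mode!r}")
    if scan_range_um < 0:
        raise ValueError("scan range must be non-negative")
    grid = grid or SamplingGrid()
    s = grid.s_axis()
    r = fld.r_um
    I_rs = fld.intensity(r, s)          # (n_r, n_s)
    t = np.arange(0.0, grid.r_fine_max_um, grid.r_pitch_um * 4)
    if scan_range_um == 0.0:
        prof = np.array([np.interp(t, r, I_rs[:, j]) for j in range(len(s))])
        if mode == "two_photon":
            prof = prof ** 2
    else:
        half = scan_range_um / 2.0
        y = np.linspace(0.0, min(half, r.max() * 0.98), 600)
        rr = np.sqrt(t[None, :, None] ** 2 + y[None, None, :] ** 2)
        prof = np.empty((len(s), len(t)))
        for j in range(len(s)):
            Iy = np.interp(rr[0], r, I_rs[:, j])
            f = Iy ** 2 if mode == "two_photon" else Iy
            prof[j] = f.mean(axis=1)
    prof = np.maximum(prof, 0.0)
    if prof.max() > 0:
        prof = prof / prof.max()
    # mirror t to a symmetric axis
    t_full = np.concatenate([-t[::-1], t[1:]])
    dens = np.concatenate([prof[:, ::-1], prof[:, 1:]], axis=1)
    beam_fwhm = _beam_central_lobe_fwhm(fld)
    return SheetProfile(density=dens, s_um=s, t_um=t_full, mode=mode,
                        beam_fwhm_um=beam_fwhm, scan_range_um=scan_range_um)


def _beam_central_lobe_fwhm(fld: BeamField) -> float:
    r = fld.r_um
    mask = r <= min(8.0, r.max())
    rf = r[mask]
    I = np.abs(fld.evaluate(rf, 0.0)[:, 0]) ** 2
    x = np.concatenate([-rf[::-1], rf[1:]])
    y = np.concatenate([I[::-1], I[1:]])
    # restrict to the central lobe (out to the first local minimum)
    return _fwhm_interp(x, y)


def sheet_metrics(sheet: SheetProfile) -> dict:
    """Thickness, depth of field and side-lobe fraction of a sheet.

    thickness_fwhm_um: FWHM of the sheet density along t at the focal plane.
    dof_um: FWHM of the on-axis (t = 0) density along s.
    side_lobe_fraction: share of the focal t-profile's energy lying outside
    the first minima flanking the central lobe.
    beam_fwhm_um: central-lobe intensity FWHM of the underlying beam.
    """
    if sheet.density.max() <= 0:
        raise ValueError("sheet is identically zero; metrics undefined")
    axial = sheet.on_axis()
    dof = _fwhm_interp(sheet.s_um, axial)
    prof = sheet.focus_profile()
    thickness = _fwhm_interp(sheet.t_um, prof)
    side = _side_lobe_fraction(sheet.t_um, prof)
    return {
        "thickness_fwhm_um": thickness,
        "dof_um": dof,
        "side_lobe_fraction": side,
        "beam_fwhm_um": sheet.beam_fwhm_um,
    }


def _side_lobe_fraction(t: np.ndarray, prof: np.ndarray) -> float:
    i0 = int(np.argmax(prof))
    # walk outward from the peak to the first local minima
    right = i0
    while right + 1 < len(prof) and prof[right + 1] <= prof[right]:
        right += 1
    left = i0
    while left - 1 >= 0 and prof[left - 1] <= prof[left]:
        left -= 1
    total = np.trapezoid(prof, t)
    core = np.trapezoid(prof[left:right + 1], t[left:right + 1])
    return float(np.clip(1.0 - core / total, 0.0, 1.0))


def effective_na(ring_diameter_mm: float, objective_focal_length_mm: float) -> float:
    """Paraxial effective NA of an annular beam: (D/2) / f.

    A 6.8 mm ring on a 10 mm focal-length objective gives NA 0.34.  Warns
    above 0.5 where the paraxial small-angle approximation degrades.
    """
    if ring_diameter_mm < 0 or objective_focal_length_mm <= 0:
        raise ValueError("ring diameter must be >= 0 and focal length > 0")
    na = (ring_diameter_mm / 2.0) / objective_focal_length_mm
    if na > 0.5:
        warnings.warn(f"NA {na:.3f} > 0.5: paraxial approximation degrades",
                      stacklevel=2)
    return na


def bessel_lobe_fwhm(na: float, wavelength_nm: float) -> float:
    """Analytic central-lobe intensity FWHM of an ideal Bessel beam, in um.

    The lobe follows J0(2 pi NA r / lambda)^2; its half-intensity radius is
    the root of J0(x)^2 = 1/2.
    """
    lam_um = wavelength_nm * 1e-3
    return 2.0 * J0_HALF_INTENSITY_ROOT * lam_um / (2.0 * np.pi * na)


def solve_j0_half_intensity() -> float:
    """Root of J0(x)^2 = 1/2 on (0, first zero), by bracketed root-finding."""
    return brentq(lambda x: j0(x) ** 2 - 0.5, 0.5, 2.0)
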