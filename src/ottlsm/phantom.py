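"""Seeded synthetic specimens: bead grids and tissue-like two-channel volumes.

Every generator is a pure function of (spec, seed) and returns a
:class:`Phantom` with two co-registered non-negative density fields —
``fluor`` for the nuclear-label fluorescence channel and ``shg`` for
second-harmonic-emitting collagen — plus the ground truth (object centres,
radii, boundaries) needed by downstream metrology, so nothing has to be
re-detected blindly.

Array axis order is (Z, Y, X) with Z the depth below the tissue surface,
positive downward; all oblique acquisition geometry lives elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["Phantom", "PhantomSpec", "generate_beads", "generate_tissue"]

PRESETS = ("beads", "skin", "pancreas_normal", "pancreas_duct", "pdac",
           "prostate_gland", "bcc_nest")


@dataclass
class Phantom:
    fluor: np.ndarray                 # (Z, Y, X) density, a.u.
    shg: np.ndarray                   # same grid
    voxel_pitch_um: tuple             # (dz, dy, dx)
    surface_z_um: float = 0.0
    provenance: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fluor.shape != self.shg.shape:
            raise ValueError("fluor and shg fields must share one grid")
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise ValueError("voxel pitch must be positive")
        if (self.fluor < 0).any() or (self.shg < 0).any():
            raise ValueError("density fields must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.fluor.shape

    def extent_um(self) -> tuple:
        return tuple(n * p for n, p in zip(self.shape, self.voxel_pitch_um))

    def channel(self, name: str) -> np.ndarray:
        return {"fluor": self.fluor, "shg": self.shg}[name]


@dataclass
class PhantomSpec:
    """Geometric parameters for one preset.

    Lengths in micrometres.  ``shape_um`` is the (Z, Y, X) extent of the
    voxel grid.  Tissue presets default to 0.5 um voxels (desk-scale
    memory); bead phantoms to 0.1 um so 0.5 um microspheres are resolved.
    """

    preset: str = "beads"
    shape_um: tuple | None = None    # (Z, Y, X) um; preset-dependent default
    voxel_pitch_um: float | None = None
    # beads
    bead_diameter_um: float = 0.5
    bead_count: int = 20
    bead_min_separation_um: float = 6.0
    bead_intensity: float = 1000.0
    # tissue
    nucleus_radius_um: float = 3.0
    nucleus_intensity: float = 1000.0
    nuclei_per_1000_um3: float = 0.25
    labeling: str = "uniform"           # "uniform" | "membrane_bright"
    membrane_contrast: float = 3.0      # shell / core intensity ratio
    epidermis_thickness_um: float = 15.0
    collagen_fiber_count: int = 120
    collagen_intensity: float = 600.0
    duct_radius_um: float = 20.0
    wall_cells: int = 24
    nest_count: int = 4
    nest_radius_um: float = 15.0
    nest_density_factor: float = 4.0    # nuclear density in nests / background

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"choose one of {PRESETS}")
        if self.voxel_pitch_um is None:
            self.voxel_pitch_um = 0.1 if self.preset == "beads" else 0.5
        if self.shape_um is None:
            # bead grids are finely sampled, so keep them small by default
            self.shape_um = ((15.0, 30.0, 30.0) if self.preset == "beads"
                             else (40.0, 80.0, 80.0))
        if self.voxel_pitch_um <= 0 or any(s <= 0 for s in self.shape_um):
            raise ValueError("lengths must be positive")

    def grid_shape(self) -> tuple:
        return tuple(int(round(s / self.voxel_pitch_um)) for s in self.shape_um)


def _render_spheres(grid: np.ndarray, centers_um: np.ndarray, radius_um: float,
                    intensity: float, pitch: float,
                    style: str = "uniform", membrane_contrast: float = 3.0,
                    ) -> list[float]:
    """Add antialiased spheres in place; returns per-sphere integrated mass.

    The edge is a linear ramp of width one voxel centred on the nominal
    radius, so the integrated mass matches the analytic sphere volume to
    second order in the pitch.  ``membrane_bright`` style brightens a shell
    of the outer third of the radius relative to the core.
    """
    masses = []
    rad_vox = radius_um / pitch
    # a unit-width linear edge ramp adds pi*R*h^2/3 of spurious mass; shrink
    # the effective radius by h^2/(12 R) to cancel it to O(h^4)
    rad_eff = rad_vox - 1.0 / (12.0 * rad_vox)
    pad = int(np.ceil(rad_vox)) + 2
    for c in np.atleast_2d(centers_um):
        cv = np.asarray(c) / pitch
        lo = np.maximum(np.floor(cv).astype(int) - pad, 0)
        hi = np.minimum(np.floor(cv).astype(int) + pad + 1, grid.shape)
        if (hi <= lo).any():
            masses.append(0.0)
            continue
        zz, yy, xx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)),
                                 indexing="ij")
        d = np.sqrt((zz + 0.5 - cv[0]) ** 2 + (yy + 0.5 - cv[1]) ** 2
                    + (xx + 0.5 - cv[2]) ** 2)
        frac = np.clip(rad_eff - d + 0.5, 0.0, 1.0)
        if style == "membrane_bright":
            shell = np.clip((d - (2.0 / 3.0) * rad_vox)
                            / (rad_vox / 6.0), 0.0, 1.0)
            profile = 1.0 + (membrane_contrast - 1.0) * shell
            vals = intensity * frac * profile
        else:
            vals = intensity * frac
        grid[zz, yy, xx] += vals
        masses.append(float(vals.sum()))
    return masses


def _poisson_disc(rng: np.random.Generator, shape_um, count, min_sep,
                  z_range=None, max_tries=20000) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling of ``count`` points, seeded."""
    zlo, zhi = z_range if z_range is not None else (0.0, shape_um[0])
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < count and tries < max_tries:
        p = np.array([rng.uniform(zlo, zhi),
                      rng.uniform(0, shape_um[1]),
                      rng.uniform(0, shape_um[2])])
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
        tries += 1
    if len(pts) < count:
        warnings.warn(f"placed only {len(pts)}/{count} points at separation "
                      f"{min_sep} um; region too crowded", stacklevel=2)
    return np.array(pts) if pts else np.empty((0, 3))


def generate_beads(spec: PhantomSpec, seed: int) -> Phantom:
    """Fluorescent-microsphere phantom for resolution metrology.

    Beads (default 0.5 um diameter, mimicking the calibration microspheres
    embedded in index-matched agarose) are placed by Poisson-disc sampling
    with a minimum separation that keeps point-spread functions disjoint.
    Bead centres are returned in ``truth['bead_centers_um']``.
    """
    if spec.bead_count < 0:
        raise ValueError("bead count must be >= 0")
    pitch = spec.voxel_pitch_um
    if spec.bead_diameter_um < pitch:
        raise ValueError("bead diameter below one voxel; use a finer pitch")
    shape = spec.grid_shape()
    fluor = np.zeros(shape, dtype=np.float64)
    shg = np.zeros(shape, dtype=np.float64)
    rng = np.random.default_rng(seed)
    margin = spec.bead_diameter_um + 4.0
    if spec.bead_count > 0:
        inner = [s - 2 * margin for s in spec.shape_um]
        if any(s <= 0 for s in inner):
            raise ValueError("grid too small for bead margin; enlarge shape_um")
        centers = _poisson_disc(rng, spec.shape_um, spec.bead_count,
                                spec.bead_min_separation_um,
                                z_range=(margin, spec.shape_um[0] - margin))
        centers[:, 1] = margin + centers[:, 1] * (inner[1] / spec.shape_um[1])
        centers[:, 2] = margin + centers[:, 2] * (inner[2] / spec.shape_um[2])
    else:
        centers = np.empty((0, 3))
    masses = _render_spheres(fluor, centers, spec.bead_diameter_um / 2.0,
                             spec.bead_intensity, pitch)
    return Phantom(
        fluor=fluor, shg=shg, voxel_pitch_um=(pitch,) * 3,
        provenance={"generator": "beads", "seed": seed,
                    "spec": vars(spec).copy()},
        truth={"bead_centers_um": centers, "bead_masses": masses,
               "bead_radius_um": spec.bead_diameter_um / 2.0})


def _collagen_fibers(rng, shape_vox, count, intensity, pitch,
                     z_min_vox=0) -> np.ndarray:
    """Random anisotropic line segments blurred by a 1-voxel Gaussian."""
    vol = np.zeros(shape_vox, dtype=np.float64)
    nz, ny, nx = shape_vox
    for _ in range(count):
        p0 = np.array([rng.uniform(z_min_vox, nz), rng.uniform(0, ny),
                       rng.uniform(0, nx)])
        theta = rng.uniform(0, 2 * np.pi)
        dip = rng.normal(0.0, 0.15)        # fibres run mostly in-plane
        direction = np.array([dip, np.sin(theta), np.cos(theta)])
        direction /= np.linalg.norm(direction)
        length = rng.uniform(10.0, 40.0) / pitch
        n_steps = max(int(length), 2)
        ts = np.linspace(0, length, n_steps)
        pts = p0[None, :] + ts[:, None] * direction[None, :]
        idx = np.round(pts).astype(int)
        ok = ((idx[:, 0] >= z_min_vox) & (idx[:, 0] < nz)
              & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
              & (idx[:, 2] >= 0) & (idx[:, 2] < nx))
        idx = idx[ok]
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] += intensity
    return gaussian_filter(vol, 1.0)


def _ring_centers(rng, center_um, radius_um, n, jitter_um=0.0) -> np.ndarray:
    """``n`` points on a circle in a horizontal plane (single-cell ring wall)."""
    phase = rng.uniform(0, 2 * np.pi)
    ang = phase + 2 * np.pi * np.arange(n) / n
    pts = np.stack([np.full(n, center_um[0]),
                    center_um[1] + radius_um * np.sin(ang),
                    center_um[2] + radius_um * np.cos(ang)], axis=1)
    if jitter_um > 0:
        pts += rng.normal(0, jitter_um, pts.shape)
    return pts


def generate_tissue(spec: PhantomSpec, seed: int) -> Phantom:
    """Tissue-like phantom for one of the organ presets.

    skin            epidermis (dense nuclei, no collagen) above a dermis with
                    SHG collagen; SHG is zero above the boundary by
                    construction.
    bcc_nest        skin plus basal-cell-carcinoma-like nests: ellipsoids in
                    the dermis whose nuclear density is
                    ``nest_density_factor`` times background.
    pancreas_normal acinar clusters of nuclei with sparse stroma.
    pancreas_duct   a duct: ``wall_cells`` nuclei on a single ring
                    surrounded by dense fibrous SHG.
    pdac            disorganized multilayered gland rings amid heavy
                    desmoplastic stroma.
    prostate_gland  several gland rings with thin peripheral stroma.

    ``truth`` carries nuclei centres/radius and preset-specific geometry.
    """
    if spec.preset == "beads":
        raise ValueError("use generate_beads for the bead preset")
    pitch = spec.voxel_pitch_um
    shape = spec.grid_shape()
    fluor = np.zeros(shape, dtype=np.float64)
    shg = np.zeros(shape, dtype=np.float64)
    rng = np.random.default_rng(seed)
    truth: dict = {"nucleus_radius_um": spec.nucleus_radius_um}
    nuc_r = spec.nucleus_radius_um
    min_sep = 2.0 * nuc_r
    Zext, Yext, Xext = spec.shape_um

    if spec.preset in ("skin", "bcc_nest"):
        boundary = spec.epidermis_thickness_um
        n_epi = max(int(spec.nuclei_per_1000_um3 * 1.4
                        * boundary * Yext * Xext / 1000.0), 1)
        epi = _poisson_disc(rng, spec.shape_um, n_epi, min_sep,
                            z_range=(nuc_r, max(boundary - nuc_r, nuc_r + 0.1)))
        n_derm = max(int(spec.nuclei_per_1000_um3 * 0.5
                         * (Zext - boundary) * Yext * Xext / 1000.0), 1)
        derm = _poisson_disc(rng, spec.shape_um, n_derm, min_sep,
                             z_range=(boundary + nuc_r, Zext - nuc_r))
        centers = np.vstack([c for c in (epi, derm) if len(c)])
        nests = []
        if spec.preset == "bcc_nest":
            bg_density = n_derm / ((Zext - boundary) * Yext * Xext)
            for _ in range(spec.nest_count):
                nc = np.array([rng.uniform(boundary + spec.nest_radius_um,
                                           Zext - spec.nest_radius_um),
                               rng.uniform(spec.nest_radius_um,
                                           Yext - spec.nest_radius_um),
                               rng.uniform(spec.nest_radius_um,
                                           Xext - spec.nest_radius_um)])
                vol_nest = 4.0 / 3.0 * np.pi * spec.nest_radius_um ** 3
                n_nest = max(int(spec.nest_density_factor * bg_density
                                 * vol_nest), 3)
                local = []
                tries = 0
                while len(local) < n_nest and tries < 20000:
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    p = nc + u * (spec.nest_radius_um - nuc_r) \
                        * rng.uniform() ** (1 / 3)
                    if all(np.linalg.norm(p - q) >= min_sep * 0.75
                           for q in local):
                        local.append(p)
                    tries += 1
                nests.append({"center_um": nc,
                              "radius_um": spec.nest_radius_um,
                              "n_nuclei": len(local)})
                centers = np.vstack([centers, np.array(local)])
            truth["nests"] = nests
            truth["background_density_per_um3"] = bg_density
        z_min_vox = int(round(boundary / pitch))
        shg += _collagen_fibers(rng, shape, spec.collagen_fiber_count,
                                spec.collagen_intensity, pitch,
                                z_min_vox=z_min_vox)
        shg[:z_min_vox] = 0.0           # epidermis holds no collagen
        truth["epidermis_dermis_boundary_um"] = boundary

    elif spec.preset in ("pancreas_duct", "prostate_gland"):
        n_rings = 1 if spec.preset == "pancreas_duct" else 3
        centers_list, rings = [], []
        for i in range(n_rings):
            c = np.array([Zext / 2.0,
                          Yext * (i + 1) / (n_rings + 1.0),
                          rng.uniform(0.35, 0.65) * Xext])
            ring = _ring_centers(rng, c, spec.duct_radius_um, spec.wall_cells)
            rings.append({"center_um": c, "radius_um": spec.duct_radius_um,
                          "n_cells": spec.wall_cells})
            centers_list.append(ring)
        centers = np.vstack(centers_list)
        truth["rings"] = rings
        fiber_n = spec.collagen_fiber_count * (2 if spec.preset ==
                                               "pancreas_duct" else 1)
        shg += _collagen_fibers(rng, shape, fiber_n,
                                spec.collagen_intensity, pitch)

    elif spec.preset == "pancreas_normal":
        n_acini = max(int(Yext * Xext / 1500.0), 2)
        centers_list = []
        for _ in range(n_acini):
            c = np.array([rng.uniform(nuc_r * 3, Zext - nuc_r * 3),
                          rng.uniform(nuc_r * 3, Yext - nuc_r * 3),
                          rng.uniform(nuc_r * 3, Xext - nuc_r * 3)])
            ring = _ring_centers(rng, c, 2.5 * nuc_r, 6, jitter_um=0.5)
            centers_list.append(ring)
        centers = np.vstack(centers_list)
        shg += _collagen_fibers(rng, shape, spec.collagen_fiber_count // 3,
                                spec.collagen_intensity * 0.5, pitch)

    elif spec.preset == "pdac":
        centers_list = []
        n_glands = 4
        for _ in range(n_glands):
            c = np.array([rng.uniform(0.25, 0.75) * Zext,
                          rng.uniform(0.2, 0.8) * Yext,
                          rng.uniform(0.2, 0.8) * Xext])
            for layer in range(2):      # multilayered, disorganized walls
                r_l = spec.duct_radius_um * (0.8 + 0.4 * layer)
                ring = _ring_centers(rng, c, r_l, spec.wall_cells,
                                     jitter_um=nuc_r)
                centers_list.append(ring)
        centers = np.vstack(centers_list)
        shg += _collagen_fibers(rng, shape, spec.collagen_fiber_count * 3,
                                spec.collagen_intensity * 1.5, pitch)
    else:  # pragma: no cover - guarded by PhantomSpec validation
        raise ValueError(spec.preset)

    keep = ((centers[:, 0] > 0) & (centers[:, 0] < Zext)
            & (centers[:, 1] > 0) & (centers[:, 1] < Yext)
            & (centers[:, 2] > 0) & (centers[:, 2] < Xext))
    centers = centers[keep]
    masses = _render_spheres(fluor, centers, nuc_r, spec.nucleus_intensity,
                             pitch, style=spec.labeling,
                             membrane_contrast=spec.membrane_contrast)
    truth["nuclei_centers_um"] = centers
    truth["nuclei_masses"] = masses
    return Phantom(
        fluor=fluor, shg=shg, voxel_pitch_um=(pitch,) * 3,
        provenance={"generator": spec.preset, "seed": seed,
                    "spec": vars(spec).copy()},
        truth=truth)
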