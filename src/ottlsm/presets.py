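"""Canonical study configurations used by the characterization pipelines.

These bundle the calibrated defaults for the two instrument-characterization
experiments — bead-grid resolution metrology and the skin two-photon vs
one-photon imaging-depth comparison — so tests, the CLI and the acceptance
script all run the identical study.  Scattering lengths and the detector
noise floor are calibrations (the tissue values are not published
measurements); see docs/methods.md.
"""

from __future__ import annotations

from .acquisition import AcquisitionGeometry, AttenuationConfig, ChannelModel
from .phantom import PhantomSpec

PIXEL_PITCH_UM = 600.0 / 1850.0

#: skin-study Beer-Lambert lengths, um (calibrated, not measured)
SKIN_L_EX_TWO_PHOTON_UM = 45.0     # 770 nm excitation
SKIN_L_EX_ONE_PHOTON_UM = 4.4      # ~445 nm excitation of the 1P comparison
SKIN_L_EM_PROFLAVINE_UM = 40.0     # 515 nm emission
SKIN_L_EM_PI_UM = 60.0             # 640 nm emission (images deeper)
SKIN_L_EM_SHG_UM = 15.0            # 385 nm emission
SKIN_READ_NOISE = 9.0              # intensity units; sets the CNR floor


def characterization_geometry(n_u: int, n_v: int,
                              step_um: float = 1.0) -> AcquisitionGeometry:
    """Instrument pixel pitch with a desk-scale frame size."""
    return AcquisitionGeometry(
        step_um=step_um, frame_shape=(n_u, n_v),
        pixel_pitch_um=PIXEL_PITCH_UM,
        strip_width_um=n_u * PIXEL_PITCH_UM,
        oblique_extent_um=n_v * PIXEL_PITCH_UM)


def bead_study(n_beads: int = 8, seed: int = 1):
    """0.5 um microspheres in an index-matched gel: resolution metrology.

    Returns (PhantomSpec, AcquisitionGeometry, AttenuationConfig); the gel
    is treated as non-scattering and frames are stepped at the pixel pitch
    (characterization-grade sampling, finer than the 1 um tissue-survey
    step).
    """
    spec = PhantomSpec(preset="beads", shape_um=(15.0, 30.0, 30.0),
                       bead_count=n_beads, bead_min_separation_um=6.0)
    geom = characterization_geometry(n_u=93, n_v=70, step_um=PIXEL_PITCH_UM)
    atten = AttenuationConfig(enabled=False)
    return spec, geom, atten


def skin_depth_study(depth_um: float = 80.0):
    """Skin phantom plus the 2P and 1P acquisition configs whose estimated
    imaging depths emulate the instrument's ~64 um vs ~20 um comparison.

    Returns (PhantomSpec, AcquisitionGeometry, atten_2p, atten_1p).
    """
    spec = PhantomSpec(preset="skin", shape_um=(depth_um, 60.0, 60.0),
                       nuclei_per_1000_um3=1.5, epidermis_thickness_um=15.0,
                       nucleus_radius_um=3.0)
    n_v = int(depth_um / (PIXEL_PITCH_UM * 0.7071)) + 8
    geom = characterization_geometry(n_u=186, n_v=n_v, step_um=1.0)
    channels = (
        ChannelModel("proflavine", "fluor", 515.0, SKIN_L_EM_PROFLAVINE_UM),
        ChannelModel("shg", "shg", 385.0, SKIN_L_EM_SHG_UM),
    )
    atten_2p = AttenuationConfig(
        excitation_scattering_length_um=SKIN_L_EX_TWO_PHOTON_UM,
        excitation_mode="two_photon", channels=channels,
        read_noise_sigma=SKIN_READ_NOISE, photon_scale=0.05)
    atten_1p = AttenuationConfig(
        excitation_scattering_length_um=SKIN_L_EX_ONE_PHOTON_UM,
        excitation_mode="one_photon", channels=channels,
        read_noise_sigma=SKIN_READ_NOISE, photon_scale=0.05)
    return spec, geom, atten_2p, atten_1p
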