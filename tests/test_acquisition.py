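"""Forward model: attenuation law, plane geometry, linearity, noise seeding."""

import numpy as np
import pytest

from ottlsm import (AcquisitionGeometry, AttenuationConfig, ChannelModel,
                    Phantom, PhantomSpec, acquire_strip, attenuated_signal,
                    generate_tissue)
from ottlsm.acquisition import predicted_frame_index


def small_geom(n_u=120, n_v=120, pitch=0.5, step=1.0):
    return AcquisitionGeometry(step_um=step, frame_shape=(n_u, n_v),
                               pixel_pitch_um=pitch,
                               strip_width_um=n_u * pitch,
                               oblique_extent_um=n_v * pitch)


class TestAttenuatedSignal:
    def test_surface_is_unity(self):
        assert attenuated_signal(0.0, AttenuationConfig()) == 1.0

    def test_emission_only_closed_form(self):
        """With no excitation loss, depth = l_em gives exactly 1/e."""
        cfg = AttenuationConfig(
            excitation_scattering_length_um=1e12,
            channels=(ChannelModel("c", "fluor", 515.0, 30.0),))
        assert attenuated_signal(30.0, cfg) == pytest.approx(np.exp(-1.0),
                                                             rel=1e-9)

    def test_two_photon_doubles_excitation_exponent(self):
        ch = ChannelModel("c", "fluor", 515.0, 1e12)
        c2 = AttenuationConfig(excitation_scattering_length_um=50.0,
                               excitation_mode="two_photon", channels=(ch,))
        c1 = AttenuationConfig(excitation_scattering_length_um=50.0,
                               excitation_mode="one_photon", channels=(ch,))
        d = 25.0
        assert attenuated_signal(d, c2) == pytest.approx(
            attenuated_signal(d, c1) ** 2, rel=1e-9)

    def test_strictly_decreasing_and_monotone_in_lem(self):
        cfg = AttenuationConfig()
        d = np.linspace(0, 100, 51)
        s = attenuated_signal(d, cfg)
        assert np.all(np.diff(s) < 0)
        longer = AttenuationConfig(channels=(
            ChannelModel("c", "fluor", 515.0, 80.0),
            ChannelModel("shg", "shg", 385.0, 15.0))[::-1])
        # doubling l_em raises the signal at any fixed positive depth
        base = attenuated_signal(37.0, cfg, cfg.channels[0])
        deeper = attenuated_signal(
            37.0, cfg, ChannelModel("c", "fluor", 515.0, 80.0))
        assert deeper > base

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            attenuated_signal(-1.0, AttenuationConfig())

    def test_emission_length_ordering_enforced(self):
        with pytest.raises(ValueError):
            AttenuationConfig(channels=(
                ChannelModel("proflavine", "fluor", 515.0, 10.0),
                ChannelModel("shg", "shg", 385.0, 50.0)))


class TestAcquireStrip:
    def test_empty_phantom_noise_off_is_zero(self):
        ph = Phantom(fluor=np.zeros((40, 60, 80)), shg=np.zeros((40, 60, 80)),
                     voxel_pitch_um=(0.5, 0.5, 0.5))
        strips = acquire_strip(ph, small_geom(n_u=60, n_v=60),
                               AttenuationConfig(enabled=False), noise=False)
        for s in strips.values():
            assert np.all(s.frames == 0.0)

    def test_point_emitter_brightest_frame(self, point_phantom):
        """Emitter at (X=50, Z=20) um with 1 um steps peaks in frame 30."""
        geom = small_geom()
        strips = acquire_strip(point_phantom, geom,
                               AttenuationConfig(enabled=False), noise=False)
        s = strips["proflavine"]
        i = np.unravel_index(np.argmax(s.frames), s.frames.shape)[0]
        assert predicted_frame_index(50.0, 20.0, geom) == 30
        assert i == 30

    def test_gain_linearity_noise_free(self, point_phantom):
        base = AttenuationConfig(enabled=False)
        doubled = AttenuationConfig(enabled=False, channels=tuple(
            ChannelModel(c.name, c.source, c.emission_wavelength_nm,
                         c.emission_scattering_length_um, gain=2.0)
            for c in base.channels))
        g = small_geom()
        a = acquire_strip(point_phantom, g, base, noise=False)["proflavine"]
        b = acquire_strip(point_phantom, g, doubled, noise=False)["proflavine"]
        np.testing.assert_allclose(b.frames, 2.0 * a.frames, rtol=1e-6)

    def test_forward_mapping_geometric_consistency(self):
        """Random point emitters peak at the predicted (frame, u, v)."""
        rng = np.random.default_rng(42)
        n = 25
        shape = (60, 80, 120)
        pitch = 0.5
        fluor = np.zeros(shape)
        z = rng.uniform(6, 24, n)
        # stay out of the leading wedge X < Z cot(theta) that a sweep
        # starting at x0 = 0 never crosses
        centers = np.stack([z, rng.uniform(6, 34, n),
                            z + rng.uniform(5, 30, n)], axis=1)
        # greedy minimum separation so neighbouring peaks cannot shadow
        # each other inside the search window
        kept = []
        for c in centers:
            if all(np.linalg.norm(c - q) >= 5.0 for q in kept):
                kept.append(c)
        centers = np.array(kept)
        idx = np.round(centers / pitch).astype(int)
        centers = (idx + 0.5) * pitch  # voxel-centre-aligned emitters
        fluor[idx[:, 0], idx[:, 1], idx[:, 2]] = 1000.0
        ph = Phantom(fluor=fluor, shg=np.zeros(shape),
                     voxel_pitch_um=(pitch,) * 3)
        geom = small_geom(n_u=80, n_v=90)
        s = acquire_strip(ph, geom, AttenuationConfig(enabled=False),
                          noise=False, psf_fwhm_um=0.9)["proflavine"]
        theta = geom.tilt_rad
        p = geom.pixel_pitch_um
        for c in centers:
            i_pred = predicted_frame_index(c[2], c[0], geom)
            v_pred = int(round(c[0] / (p * np.sin(theta))))
            u_pred = int(round(c[1] / p))
            # the local peak around the prediction must sit within one
            # pixel of it in every axis
            lo = np.array([i_pred - 3, v_pred - 3, u_pred - 3])
            win = s.frames[lo[0]:i_pred + 4, lo[1]:v_pred + 4,
                           lo[2]:u_pred + 4]
            peak = np.array(np.unravel_index(np.argmax(win), win.shape)) + lo
            assert abs(peak[0] - i_pred) <= 1
            assert abs(peak[1] - v_pred) <= 1
            assert abs(peak[2] - u_pred) <= 1

    def test_noise_seeded_reproducibly(self, point_phantom):
        g = small_geom()
        att = AttenuationConfig()
        a = acquire_strip(point_phantom, g, att, seed=5)["proflavine"]
        b = acquire_strip(point_phantom, g, att, seed=5)["proflavine"]
        c = acquire_strip(point_phantom, g, att, seed=6)["proflavine"]
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_depth_fading_with_attenuation(self):
        """Mean nuclear signal decreases across depth bins when on."""
        spec = PhantomSpec(preset="skin", shape_um=(50.0, 30.0, 30.0),
                           nuclei_per_1000_um3=1.0)
        ph = generate_tissue(spec, seed=3)
        geom = small_geom(n_u=60, n_v=160)
        s = acquire_strip(ph, geom, AttenuationConfig(), noise=False,
                          psf_fwhm_um=0.9)["proflavine"]
        theta = geom.tilt_rad
        depth = np.arange(s.frames.shape[1]) * geom.pixel_pitch_um \
            * np.sin(theta)
        prof = s.frames.max(axis=(0, 2))
        shallow = prof[(depth > 5) & (depth < 20)].mean()
        deep = prof[(depth > 30) & (depth < 45)].mean()
        assert deep < shallow

    def test_fov_mismatch_raises(self, point_phantom):
        geom = small_geom(n_v=20)      # oblique extent too small for 40 um Z
        with pytest.raises(ValueError):
            acquire_strip(point_phantom, geom, AttenuationConfig(),
                          noise=False)

    def test_stage_positions_exact(self, point_phantom):
        s = acquire_strip(point_phantom, small_geom(),
                          AttenuationConfig(enabled=False),
                          noise=False)["proflavine"]
        np.testing.assert_array_equal(
            np.diff(s.stage_x_um), np.full(len(s.stage_x_um) - 1, 1.0))
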