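"""Deskew inverse geometry, depth conversion, stitching, plane extraction."""

import numpy as np
import pytest

from ottlsm import (AcquisitionGeometry, AttenuationConfig, Volume,
                    acquire_strip, deskew, extract_enface, stitch,
                    tilted_depth_to_vertical)
from ottlsm.acquisition import RawStrip
from ottlsm.reconstruct import round_depth_um


def make_strip(frames, step=1.0, pitch=0.5, tilt=45.0, x0=0.0):
    n, n_v, n_u = frames.shape
    geom = AcquisitionGeometry(tilt_deg=tilt, step_um=step,
                               frame_shape=(n_u, n_v), pixel_pitch_um=pitch,
                               strip_width_um=n_u * pitch,
                               oblique_extent_um=n_v * pitch)
    return RawStrip(frames=frames.astype(np.float32),
                    stage_x_um=x0 + np.arange(n) * step, geometry=geom)


class TestTiltedDepth:
    def test_instrument_depth_conversions(self):
        """90 um tilted -> 64 um vertical; 28 um -> 20 um, at 45 degrees."""
        assert round_depth_um(tilted_depth_to_vertical(90.0, 45.0)) == 64
        assert round_depth_um(tilted_depth_to_vertical(28.0, 45.0)) == 20
        assert tilted_depth_to_vertical(90.0, 45.0) == pytest.approx(63.64,
                                                                     abs=0.01)

    def test_vertical_plane_is_identity(self):
        assert tilted_depth_to_vertical(37.5, 90.0) == pytest.approx(37.5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tilted_depth_to_vertical(-1.0, 45.0)
        with pytest.raises(ValueError):
            tilted_depth_to_vertical(10.0, 0.0)
        with pytest.raises(ValueError):
            tilted_depth_to_vertical(10.0, 120.0)


class TestDeskew:
    def test_zero_tilt_is_bitwise_restack(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 1000, size=(12, 16, 20)).astype(np.float32)
        vol = deskew(make_strip(frames, tilt=0.0), interp="nearest")
        np.testing.assert_array_equal(vol.data, frames)

    def test_point_emitter_round_trip(self, point_phantom):
        """Forward render then deskew localizes the emitter to its voxel."""
        geom = AcquisitionGeometry(step_um=0.5, frame_shape=(120, 120),
                                   pixel_pitch_um=0.5, strip_width_um=60.0,
                                   oblique_extent_um=60.0)
        strips = acquire_strip(point_phantom, geom,
                               AttenuationConfig(enabled=False), noise=False)
        vol = deskew(strips["proflavine"], interp="linear")
        d = np.nan_to_num(vol.data)
        zi, yi, xi = np.unravel_index(np.argmax(d), d.shape)
        world = (np.array(vol.origin_um)
                 + np.array([zi, yi, xi]) * np.array(vol.pitch_um))
        np.testing.assert_allclose(world, (20.25, 30.25, 50.25),
                                   atol=np.max(vol.pitch_um))

    def test_flat_field_invariance(self):
        """A constant slab stays constant in the deskewed interior."""
        frames = np.full((40, 30, 10), 500.0)
        vol = deskew(make_strip(frames, step=0.5, pitch=0.5), interp="linear")
        interior = vol.data[5:-5, :, 20:-20]
        interior = interior[~np.isnan(interior)]
        assert interior.size
        np.testing.assert_allclose(interior, 500.0, rtol=0.005)

    def test_intensity_conserved_interior(self):
        """Total deskewed intensity matches strip total within 1% when the
        frame stepping equals the reconstruction pitch."""
        rng = np.random.default_rng(1)
        frames = rng.uniform(100, 200, size=(80, 24, 12))
        # pad the ends so edge effects do not leak intensity
        frames[:8] = 0
        frames[-8:] = 0
        strip = make_strip(frames, step=0.5, pitch=0.5)
        vol = deskew(strip, interp="linear")
        total = np.nansum(vol.data)
        assert total == pytest.approx(frames.sum(), rel=0.01)

    def test_masked_voxels_are_nan_not_zero(self):
        frames = np.full((10, 12, 6), 7.0)
        vol = deskew(make_strip(frames), interp="nearest")
        assert np.isnan(vol.data).any()
        measured = vol.data[vol.mask]
        assert (measured > 0).all()

    def test_nonmonotone_stage_positions_rejected(self):
        frames = np.zeros((5, 8, 4), dtype=np.float32)
        strip = make_strip(frames)
        strip.stage_x_um = strip.stage_x_um[::-1].copy()
        with pytest.raises(ValueError):
            deskew(strip)


class TestStitch:
    def make_vol(self, data, origin=(0, 0, 0)):
        return Volume(data=np.asarray(data, dtype=np.float32),
                      pitch_um=(1.0, 1.0, 1.0), origin_um=origin)

    def test_single_volume_identity(self):
        v = self.make_vol(np.random.default_rng(0).uniform(size=(4, 8, 8)))
        out = stitch([v])
        np.testing.assert_array_equal(out.data, v.data)

    def test_constant_volumes_blend_seamlessly(self):
        a = self.make_vol(np.full((4, 10, 10), 3.0))
        b = self.make_vol(np.full((4, 10, 10), 3.0), origin=(0, 6, 0))
        out = stitch([a, b])
        np.testing.assert_allclose(out.data[out.mask], 3.0, rtol=1e-6)
        assert out.data.shape == (4, 16, 10)

    def test_stitch_associative_on_constants(self):
        vols = [self.make_vol(np.full((3, 8, 8), 2.0), origin=(0, 6 * i, 0))
                for i in range(3)]
        ab_c = stitch([stitch(vols[:2]), vols[2]])
        abc = stitch(vols)
        np.testing.assert_allclose(ab_c.data[abc.mask], abc.data[abc.mask],
                                   rtol=1e-6)

    def test_xcorr_recovers_true_offset(self):
        """Nominal offset off by 2 um; cross-correlation recovers truth."""
        rng = np.random.default_rng(7)
        big = rng.uniform(0, 100, size=(6, 20, 60)).astype(np.float32)
        a = self.make_vol(big[:, :, :40])
        true_shift = 20
        b = self.make_vol(big[:, :, true_shift:true_shift + 40])
        nominal = [(0.0, 0.0, 0.0), (0.0, 0.0, float(true_shift - 2))]
        out = stitch([a, b], nominal_offsets_um=nominal,
                     registration="xcorr")
        refined = out.meta["refined_offsets_um"][1]
        assert abs(refined[2] - true_shift) <= 1.0
        assert abs(refined[0]) <= 1.0 and abs(refined[1]) <= 1.0

    def test_no_overlap_falls_back_with_warning(self):
        a = self.make_vol(np.ones((3, 8, 8)))
        b = self.make_vol(np.ones((3, 8, 8)), origin=(0.0, 0.0, 50.0))
        with pytest.warns(UserWarning):
            out = stitch([a, b], registration="xcorr")
        assert out.meta["refined_offsets_um"][1][2] == 50.0

    def test_mismatched_pitch_rejected(self):
        a = self.make_vol(np.ones((3, 4, 4)))
        b = Volume(data=np.ones((3, 4, 4), dtype=np.float32),
                   pitch_um=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            stitch([a, b])


class TestEnface:
    def ramp_volume(self):
        data = np.tile(np.arange(10, dtype=np.float32)[:, None, None],
                       (1, 4, 4))
        return Volume(data=data, pitch_um=(2.0, 1.0, 1.0))

    def test_exact_plane_is_bitwise(self):
        vol = self.ramp_volume()
        np.testing.assert_array_equal(extract_enface(vol, 6.0), vol.data[3])

    def test_midway_depth_averages_neighbours(self):
        """On a linear-in-Z ramp the midway plane is the exact average."""
        vol = self.ramp_volume()
        np.testing.assert_allclose(extract_enface(vol, 5.0),
                                   np.full((4, 4), 2.5))

    def test_mask_propagates(self):
        vol = self.ramp_volume()
        vol.data[:, 0, 0] = np.nan
        plane = extract_enface(vol, 5.0)
        assert np.isnan(plane[0, 0])
        assert np.isfinite(plane[1:, 1:]).all()

    def test_out_of_extent_rejected(self):
        with pytest.raises(ValueError):
            extract_enface(self.ramp_volume(), 50.0)
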