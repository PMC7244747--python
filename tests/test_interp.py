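"""Time-of-flight mapping and pixel-wise interpolation properties."""

import numpy as np
import pytest

from paxel.interp import (
    compute_tof_map,
    delay_and_sum,
    interp_for_mdirect,
    pixel_wise_interpolate,
)
from paxel.simulate import (
    Medium,
    SensorTimeSeries,
    make_semicircle_array,
    make_ring_array,
    simulate_forward,
)


def brute_force_interpolate(data: np.ndarray, tof: np.ndarray, dt: float) -> np.ndarray:
    """Naive per-pixel reference: linear interpolation one value at a time."""
    h, w, n = tof.shape
    t = data.shape[1]
    out = np.zeros((h, w, n))
    for r in range(h):
        for c in range(w):
            for i in range(n):
                s = tof[r, c, i] / dt
                if s < 0 or s > t - 1:
                    continue
                i0 = int(np.floor(s))
                f = s - i0
                i1 = min(i0 + 1, t - 1)
                out[r, c, i] = (1.0 - f) * data[i, i0] + f * data[i, i1]
    return out


class TestTofMap:
    def test_zero_at_sensor_node(self, medium64, geo16):
        tof = compute_tof_map(geo16, medium64)
        for i, (r, c) in enumerate(geo16.positions):
            assert tof.tof[r, c, i] == 0.0

    def test_known_distance(self):
        med = Medium()
        geo = make_semicircle_array(3, med)
        tof = compute_tof_map(geo, med)
        r, c = geo.positions[1]              # (4, 64): 60 px above center
        val = tof.tof[r + 64, c, 1]          # pixel 64 px below that sensor
        assert val == pytest.approx(64 * 1e-4 / 1500, rel=1e-12)

    def test_matches_brute_force_distances(self, medium64, geo16):
        tof = compute_tof_map(geo16, medium64)
        rng = np.random.default_rng(0)
        pos = geo16.as_array()
        for _ in range(50):
            r, c, i = rng.integers(64), rng.integers(64), rng.integers(16)
            d = np.hypot(r - pos[i, 0], c - pos[i, 1])
            assert tof.tof[r, c, i] == pytest.approx(
                d * medium64.dx / medium64.sound_speed, rel=1e-12)

    def test_center_equidistant_on_arc(self):
        """All sensors on the semicircle are one radius from the grid center,
        up to the <=1 px grid-snapping of sensor positions."""
        med = Medium()
        geo = make_semicircle_array(32, med)
        tof = compute_tof_map(geo, med)
        center = tof.tof[64, 64, :]
        px_time = med.dx / med.sound_speed
        assert center.max() - center.min() <= 1.0 * px_time

    def test_mirror_symmetry(self):
        """Reflecting the grid and the sensor array about the vertical axis
        leaves the TOF map unchanged (up to channel reordering)."""
        med = Medium(grid_shape=(64, 64))
        geo = make_semicircle_array(8, med)
        tof = compute_tof_map(geo, med).tof
        mirrored = tof[:, ::-1, ::-1]
        # even grid: mirror pixel col c -> 63 - c, sensor i -> N-1-i; positions
        # snap symmetrically only up to rounding, allow one-pixel travel time
        px_time = med.dx / med.sound_speed
        assert np.abs(tof - mirrored).max() <= 1.5 * px_time

    def test_monotone_in_distance(self, medium64, geo16):
        tof = compute_tof_map(geo16, medium64).tof
        r0, c0 = geo16.positions[0]
        line = tof[r0, :, 0]
        left, right = line[:c0], line[c0:]
        assert np.all(np.diff(left) < 0) and np.all(np.diff(right[1:]) > 0)


class TestPixelWiseInterpolate:
    def _small_case(self, seed=0, impulse=None):
        med = Medium(grid_shape=(32, 32))
        geo = make_semicircle_array(4, med)
        tof = compute_tof_map(geo, med)
        t = 200
        if impulse is None:
            data = np.random.default_rng(seed).standard_normal((4, t))
        else:
            data = np.zeros((4, t))
            data[impulse[0], impulse[1]] = 1.0
        dt = 0.3 * med.dx / med.sound_speed
        y = SensorTimeSeries(data, dt, geo, med)
        return y, tof, med

    def test_zero_data_zero_volume(self):
        y, tof, _ = self._small_case()
        y.data[:] = 0
        vol = pixel_wise_interpolate(y, tof)
        assert np.all(vol.volume == 0)

    def test_matches_brute_force_bit_for_bit(self):
        for seed in range(3):
            y, tof, _ = self._small_case(seed=seed)
            vol = pixel_wise_interpolate(y, tof).volume
            ref = brute_force_interpolate(y.data, tof.tof, y.dt)
            np.testing.assert_array_equal(vol, ref)

    def test_linearity(self):
        y1, tof, med = self._small_case(seed=1)
        y2, _, _ = self._small_case(seed=2)
        a, b = 1.7, -0.4
        y12 = SensorTimeSeries(a * y1.data + b * y2.data, y1.dt, y1.geometry, med)
        v12 = pixel_wise_interpolate(y12, tof).volume
        v1 = pixel_wise_interpolate(y1, tof).volume
        v2 = pixel_wise_interpolate(y2, tof).volume
        assert np.allclose(v12, a * v1 + b * v2, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_impulse_maps_to_arc(self, trial):
        """A unit impulse at sample k in channel i lights up exactly the pixels
        whose TOF falls within one sample of k: an arc at radius c0 k dt / dx."""
        rng = np.random.default_rng(100 + trial)
        sensor = int(rng.integers(4))
        k = int(rng.integers(30, 110))
        y, tof, med = self._small_case(impulse=(sensor, k))
        vol = pixel_wise_interpolate(y, tof).volume
        others = [i for i in range(4) if i != sensor]
        assert np.all(vol[:, :, others] == 0)
        nz = np.argwhere(vol[:, :, sensor] != 0)
        if len(nz) == 0:
            pytest.skip("arc radius outside the 32 px grid for this draw")
        pos = y.geometry.as_array()[sensor]
        radii = np.hypot(nz[:, 0] - pos[0], nz[:, 1] - pos[1])
        predicted = med.sound_speed * k * y.dt / med.dx
        assert np.all(np.abs(radii - predicted) <= 1.0)

    def test_out_of_window_zero_filled(self):
        med = Medium(grid_shape=(32, 32))
        geo = make_semicircle_array(4, med)
        tof = compute_tof_map(geo, med)
        dt = 0.3 * med.dx / med.sound_speed
        t_short = 30                    # window covers only 9 px of travel
        data = np.ones((4, t_short))
        vol = pixel_wise_interpolate(SensorTimeSeries(data, dt, geo, med), tof).volume
        pos = geo.as_array()
        rr, cc = np.mgrid[:32, :32]
        for i in range(4):
            d = np.hypot(rr - pos[i, 0], cc - pos[i, 1])
            outside = d > (t_short - 1) * 0.3
            assert np.all(vol[:, :, i][outside] == 0)
            assert np.all(vol[:, :, i][~outside] == 1)

    def test_geometry_mismatch_rejected(self, medium64):
        med32 = Medium(grid_shape=(32, 32))
        geo32 = make_semicircle_array(4, med32)
        geo64 = make_semicircle_array(4, medium64)
        tof = compute_tof_map(geo64, medium64)
        y = SensorTimeSeries(np.zeros((4, 50)), 1e-8, geo32, med32)
        with pytest.raises(ValueError):
            pixel_wise_interpolate(y, tof)


class TestDelayAndSum:
    def test_constant_channels_give_constant_mean(self):
        from paxel.interp import PixelInterpolatedVolume

        med = Medium(grid_shape=(32, 32))
        geo = make_semicircle_array(4, med)
        vol = PixelInterpolatedVolume(np.ones((32, 32, 4)), geo, 1e-8)
        raw_mean = vol.volume.mean(axis=2)
        assert np.all(raw_mean == 1.0)
        img = delay_and_sum(vol)
        assert np.all(img == 1.0)

    def test_point_source_focus(self, medium64, tcfg64):
        geo = make_semicircle_array(16, medium64)
        tof = compute_tof_map(geo, medium64)
        x = np.zeros((64, 64))
        x[40, 25] = 1.0
        y = simulate_forward(x, medium64, geo, tcfg64)
        img = delay_and_sum(pixel_wise_interpolate(y, tof))
        peak = np.unravel_index(img.argmax(), img.shape)
        assert np.hypot(peak[0] - 40, peak[1] - 25) <= 1.0


class TestMdirectResample:
    def _series(self, data):
        med = Medium(grid_shape=(128, 128))
        geo = make_ring_array(data.shape[0], med) if data.shape[0] >= 3 else None
        if geo is None or geo.n_sensors != data.shape[0]:
            geo = make_semicircle_array(data.shape[0], med)
        return SensorTimeSeries(data, 1e-8, geo, med)

    def test_constant_preserved(self):
        y = self._series(np.full((32, 500), 3.25))
        out = interp_for_mdirect(y, (128, 128))
        assert out.shape == (128, 128)
        assert np.allclose(out, 3.25)

    def test_identity_when_already_sized(self):
        data = np.random.default_rng(5).standard_normal((128, 128))
        y = self._series(data)
        assert np.allclose(interp_for_mdirect(y, (128, 128)), data, atol=1e-12)

    def test_column_means_match_block_average(self):
        n, t = 32, 2048
        ii, kk = np.mgrid[:n, :t]
        data = np.sin(2 * np.pi * kk / 400 + ii / 5.0) * np.exp(
            -((kk - 800) / 500.0) ** 2) + 0.5
        y = self._series(data)
        out = interp_for_mdirect(y, (128, 128))
        blocks = data.reshape(n, 128, t // 128).mean(axis=2)
        rel = np.abs(out.mean(axis=0) - blocks.mean(axis=0)) / np.abs(blocks.mean(axis=0))
        assert rel.max() < 0.05
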