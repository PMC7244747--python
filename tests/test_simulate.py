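"""Forward operator, adjoint, and time-reversal properties."""

import numpy as np
import pytest

from paxel.simulate import (
    Medium,
    SensorGeometry,
    SensorTimeSeries,
    TimeConfig,
    apply_adjoint,
    make_ring_array,
    make_semicircle_array,
    simulate_forward,
    time_reversal,
)


class TestSensorArrays:
    def test_two_sensor_semicircle_is_diametric(self):
        med = Medium(grid_shape=(64, 64))
        geo = make_semicircle_array(2, med, diameter_px=60)
        (r0, c0), (r1, c1) = geo.positions
        assert r0 == r1 == 32          # both on the horizontal axis through center
        assert c0 == 32 + 30 and c1 == 32 - 30

    def test_three_sensor_middle_is_topmost(self):
        med = Medium()
        geo = make_semicircle_array(3, med)   # 120 px diameter on the 128 grid
        mid = geo.positions[1]
        assert mid == (64 - 60, 64)           # 60 px above center

    def test_arc_spacing_uniform_after_snapping(self):
        med = Medium()
        geo = make_semicircle_array(32, med)
        pos = geo.as_array().astype(float)
        gaps = np.hypot(*(pos[1:] - pos[:-1]).T)
        assert gaps.max() - gaps.min() < 2.0   # within snap tolerance (1 px each end)

    def test_sensor_outside_grid_rejected(self):
        med = Medium(grid_shape=(32, 32))
        with pytest.raises(ValueError):
            make_semicircle_array(16, med, diameter_px=100)

    def test_geometry_position_bounds_checked(self):
        with pytest.raises(ValueError):
            SensorGeometry(positions=((200, 0),), grid_shape=(64, 64))


class TestForward:
    def test_zero_input_gives_zero_data(self, medium64, geo16, tcfg64):
        y = simulate_forward(np.zeros((64, 64)), medium64, geo16, tcfg64)
        assert np.all(y.data == 0)

    def test_linearity(self, medium64, geo16, tcfg64):
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal((64, 64))
        x2 = rng.standard_normal((64, 64))
        a, b = 2.3, -0.7
        y12 = simulate_forward(a * x1 + b * x2, medium64, geo16, tcfg64).data
        y1 = simulate_forward(x1, medium64, geo16, tcfg64).data
        y2 = simulate_forward(x2, medium64, geo16, tcfg64).data
        assert np.allclose(y12, a * y1 + b * y2, rtol=1e-8, atol=1e-10)

    def test_point_source_arrival_time(self, medium64, geo16, tcfg64):
        """Leading wavefront reaches each sensor at distance / (c0 dt)."""
        x = np.zeros((64, 64))
        x[40, 30] = 1.0
        y = simulate_forward(x, medium64, geo16, tcfg64)
        pos = geo16.as_array()
        for i in (0, 5, 10, 15):
            d = np.hypot(pos[i, 0] - 40, pos[i, 1] - 30)
            predicted = d * medium64.dx / (medium64.sound_speed * tcfg64.dt)
            observed = np.argmax(np.abs(y.data[i]))
            assert abs(observed - predicted) <= 3

    def test_reciprocity_of_delay(self, medium64, tcfg64):
        """Arrival time pixel -> sensor equals sensor -> pixel."""
        geo = make_semicircle_array(4, medium64)
        p_src, s_idx = (40, 22), 2
        x = np.zeros((64, 64))
        x[p_src] = 1.0
        y1 = simulate_forward(x, medium64, geo, tcfg64)
        t1 = np.argmax(np.abs(y1.data[s_idx]))

        x2 = np.zeros((64, 64))
        x2[geo.positions[s_idx]] = 1.0
        rev_geo = SensorGeometry(positions=(p_src,), grid_shape=(64, 64))
        y2 = simulate_forward(x2, medium64, rev_geo, tcfg64)
        t2 = np.argmax(np.abs(y2.data[0]))
        assert abs(int(t1) - int(t2)) <= 3

    def test_energy_absorbed_at_late_times(self, medium64, geo16, tcfg64, blob_phantom64):
        """With the absorbing boundary, interior field energy decays after the
        source has radiated out of the domain."""
        from paxel.simulate import _solver_for

        sv = _solver_for(medium64, tcfg64)
        a = sv.embed(blob_phantom64)
        b = a
        a = sv.W * sv.prop(b, sv.Ch)
        energies = []
        for n in range(2, tcfg64.n_steps):
            a, b = sv.W * sv.prop(a, sv.C) - sv.W2 * b, a
            if n % 10 == 0:
                energies.append(sv.field_energy(a, b))
        assert all(e2 <= e1 * (1 + 1e-9) for e1, e2 in zip(energies, energies[1:]))
        assert energies[-1] < 0.1 * energies[0]

    def test_cfl_violation_rejected(self, medium64, geo16):
        bad = TimeConfig(dt=1e-6, n_steps=100, cfl=0.3)   # far above cfl*dx/c0
        with pytest.raises(ValueError, match="CFL"):
            simulate_forward(np.zeros((64, 64)), medium64, geo16, bad)


class TestAdjoint:
    def test_zero_data_zero_adjoint(self, medium64, geo16, tcfg64):
        y = SensorTimeSeries(np.zeros((16, tcfg64.n_steps)), tcfg64.dt, geo16, medium64)
        assert np.all(apply_adjoint(y, medium64, geo16, tcfg64) == 0)

    def test_dot_product_identity(self, medium64, geo16, tcfg64):
        rng = np.random.default_rng(11)
        for _ in range(3):
            x = rng.standard_normal((64, 64))
            ax = simulate_forward(x, medium64, geo16, tcfg64).data
            u = rng.standard_normal(ax.shape)
            atu = apply_adjoint(SensorTimeSeries(u, tcfg64.dt, geo16, medium64),
                                medium64, geo16, tcfg64)
            rel = abs(np.vdot(ax, u) - np.vdot(x, atu))
            rel /= np.linalg.norm(ax) * np.linalg.norm(u)
            assert rel < 1e-10

    def test_backprojection_focuses_on_source(self, medium64, tcfg64):
        geo = make_semicircle_array(32, medium64)
        x = np.zeros((64, 64))
        x[38, 28] = 1.0
        y = simulate_forward(x, medium64, geo, tcfg64)
        bp = apply_adjoint(y, medium64, geo, tcfg64)
        peak = np.unravel_index(np.argmax(bp), bp.shape)
        assert np.hypot(peak[0] - 38, peak[1] - 28) <= 2


class TestTimeReversal:
    def test_zero_data_zero_image(self, medium64, geo16, tcfg64):
        y = SensorTimeSeries(np.zeros((16, tcfg64.n_steps)), tcfg64.dt, geo16, medium64)
        assert np.all(time_reversal(y, medium64, geo16, tcfg64) == 0)

    def test_output_nonnegative_normalized(self, medium64, geo16, tcfg64, blob_phantom64):
        y = simulate_forward(blob_phantom64, medium64, geo16, tcfg64)
        img = time_reversal(y, medium64, geo16, tcfg64)
        assert img.min() >= 0 and img.max() == pytest.approx(1.0)

    def test_more_sensors_reconstruct_better(self, medium64, tcfg64, blob_phantom64):
        from paxel.metrics import psnr

        scores = []
        for n in (16, 64):
            geo = make_semicircle_array(n, medium64)
            y = simulate_forward(blob_phantom64, medium64, geo, tcfg64)
            scores.append(psnr(time_reversal(y, medium64, geo, tcfg64), blob_phantom64))
        assert scores[1] > scores[0]

    def test_full_ring_recovers_smooth_phantom(self):
        from paxel.metrics import psnr

        med = Medium()
        tcfg = TimeConfig.for_medium(med)
        geo = make_ring_array(128, med)
        yy, xx = np.mgrid[:128, :128]
        disc = np.clip(1 - (np.hypot(yy - 64, xx - 64) / 20) ** 2, 0, 1) ** 1.5
        y = simulate_forward(disc, med, geo, tcfg)
        img = time_reversal(y, med, geo, tcfg)
        assert psnr(img, disc) > 30.0
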