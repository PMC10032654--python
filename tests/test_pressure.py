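"""Pressure-gradient estimation, path-integral polling, head pressure."""

import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from thrustwake.pressure import (PressureConfig, PressureField, drag_force,
                                 head_box_mask, head_pressure,
                                 integrate_pressure, pressure_gradient,
                                 subtract_mean_flow, vortex_centers, vorticity)
from thrustwake.synth import (WakeSpec, analytic_flow, lamb_oseen_vtheta,
                              simulate_wake)

RHO = 1000.0
CFG = PressureConfig(rho=RHO)


def lamb_oseen_pressure_oracle(r, gamma, r_c, rho=RHO):
    """Radial ODE oracle: integrate dp/dr = rho v_theta^2 / r, p(inf) = 0."""
    rr = np.linspace(1e-6, max(3.0 * np.max(r), 0.2), 6000)
    dpdr = rho * lamb_oseen_vtheta(rr, gamma, r_c) ** 2 / rr
    p = cumulative_trapezoid(dpdr, rr, initial=0.0)
    p -= p[-1]
    return np.interp(r, rr, p)


class TestPressureGradient:
    def test_steady_uniform_flow_has_zero_gradient(self, oracle_grid):
        seq = analytic_flow("uniform", {"u0": 0.3, "rho": RHO}, oracle_grid)
        gx, gy = pressure_gradient(seq, 0, CFG)
        np.testing.assert_allclose(gx, 0.0, atol=1e-12)
        np.testing.assert_allclose(gy, 0.0, atol=1e-12)

    def test_solid_rotation_gradient_is_centripetal(self, oracle_grid):
        omega = 5.0
        seq = analytic_flow("solid_rotation", {"omega": omega, "rho": RHO},
                            oracle_grid)
        gx, gy = pressure_gradient(seq, 0, CFG)
        X, Y = np.meshgrid(*oracle_grid)
        r = np.hypot(X, Y)
        interior = (r > 0.01) & (np.abs(X) < 0.045) & (np.abs(Y) < 0.045)
        mag = np.hypot(gx, gy)
        np.testing.assert_allclose(mag[interior], RHO * omega**2 * r[interior],
                                   rtol=0.02)
        # points outward: away from the rotation centre (low p at centre)
        outward = (gx * X + gy * Y)[interior]
        assert np.all(outward > 0.0)

    def test_lamb_oseen_radial_gradient_matches_closed_form(self):
        gamma, r_c = 0.02, 0.008
        grid = (np.linspace(-0.064, 0.064, 101),) * 2
        seq = analytic_flow("lamb_oseen", {"gamma": gamma, "r_c": r_c,
                                           "rho": RHO}, grid)
        gx, gy = pressure_gradient(seq, 0, CFG)
        X, Y = np.meshgrid(*grid)
        r = np.hypot(X, Y)
        h = float(np.diff(grid[0]).mean())
        ring = (r > 2.0 * h) & (r < 0.05)
        with np.errstate(invalid="ignore"):
            expected = RHO * lamb_oseen_vtheta(r, gamma, r_c) ** 2 / r
            measured = (gx * X + gy * Y) / r  # radial component
        np.testing.assert_allclose(measured[ring], expected[ring], rtol=0.05)

    def test_single_frame_sequence_rejected(self, oracle_grid):
        seq = analytic_flow("uniform", {"u0": 0.3, "n_frames": 1}, oracle_grid)
        with pytest.raises(ValueError):
            pressure_gradient(seq, 0, CFG)

    def test_central_scheme_needs_both_neighbours(self, oracle_grid):
        seq = analytic_flow("uniform", {"u0": 0.3}, oracle_grid)
        cfg = PressureConfig(rho=RHO, time_scheme="central")
        with pytest.raises(ValueError):
            pressure_gradient(seq, 0, cfg)
        gx, _ = pressure_gradient(seq, 1, cfg)
        np.testing.assert_allclose(gx, 0.0, atol=1e-12)


class TestIntegratePressure:
    def test_zero_gradient_gives_zero_field(self, oracle_grid):
        x, y = oracle_grid
        z = np.zeros((y.size, x.size))
        for boundary in ("edge", "zero"):
            field = integrate_pressure(z, z, x, y, boundary=boundary)
            np.testing.assert_allclose(field.p, 0.0, atol=1e-12)
            assert field.defined.all()

    def test_conservative_gradient_candidates_agree(self, oracle_grid):
        # All eight families must agree for a conservative gradient and
        # the median must match the analytic pressure differences.
        x, y = oracle_grid
        omega = 5.0
        seq = analytic_flow("solid_rotation", {"omega": omega, "rho": RHO},
                            (x, y))
        gx, gy = pressure_gradient(seq, 0, CFG)
        field = integrate_pressure(gx, gy, x, y)
        X, Y = np.meshgrid(x, y)
        p_true = 0.5 * RHO * omega**2 * (X**2 + Y**2)
        rng = p_true.max() - p_true.min()
        assert np.nanmax(field.spread) <= 0.05 * rng
        err = (field.p - field.p.mean()) - (p_true - p_true.mean())
        assert np.abs(err).max() <= 0.05 * rng

    def test_enclosed_node_is_undefined_and_filled(self):
        x = np.linspace(0.0, 1.0, 11)
        y = np.linspace(0.0, 1.0, 11)
        gx = np.zeros((11, 11))
        gx[:, 6:] = 7.0  # constant gradient east of the ring
        gy = np.zeros_like(gx)
        mask = np.zeros((11, 11), dtype=bool)
        mask[4:7, 4:7] = True
        mask[5, 5] = False  # fluid node enclosed on all eight sides
        field = integrate_pressure(gx, gy, x, y, mask=mask)
        assert not field.defined[5, 5]
        assert np.isfinite(field.p[5, 5])
        # filled from the nearest defined fluid node
        neighbours = [field.p[3, 5], field.p[7, 5], field.p[5, 3], field.p[5, 7]]
        assert any(field.p[5, 5] == pytest.approx(v) for v in neighbours)
        assert np.isnan(field.p[mask]).all()

    def test_fully_masked_domain_rejected(self, oracle_grid):
        x, y = oracle_grid
        z = np.zeros((y.size, x.size))
        with pytest.raises(ValueError):
            integrate_pressure(z, z, x, y, mask=np.ones_like(z, dtype=bool))

    def test_gauge_shift_moves_median_uniformly(self, oracle_grid):
        x, y = oracle_grid
        seq = analytic_flow("solid_rotation", {"omega": 3.0, "rho": RHO}, (x, y))
        gx, gy = pressure_gradient(seq, 0, CFG)
        field, cand = integrate_pressure(gx, gy, x, y, return_candidates=True)
        shifted = np.nanmedian(cand + 11.5, axis=0)
        np.testing.assert_allclose(shifted, field.p + 11.5, atol=1e-9)

    def test_median_more_robust_than_mean_to_one_corrupt_family(self, oracle_grid):
        x, y = oracle_grid
        seq = analytic_flow("solid_rotation", {"omega": 3.0, "rho": RHO}, (x, y))
        gx, gy = pressure_gradient(seq, 0, CFG)
        field, cand = integrate_pressure(gx, gy, x, y, return_candidates=True)
        rng = np.random.default_rng(0)
        corrupt = cand.copy()
        corrupt[3] += rng.normal(0.0, 50.0, size=corrupt[3].shape)
        med_change = np.abs(np.nanmedian(corrupt, axis=0) - field.p).mean()
        mean_change = np.abs(np.nanmean(corrupt, axis=0)
                             - np.nanmean(cand, axis=0)).mean()
        assert med_change < mean_change


class TestLambOseenOracle:
    def test_reconstruction_matches_radial_ode(self):
        gamma, r_c = 0.02, 0.008
        grid = (np.linspace(-8 * r_c, 8 * r_c, 101),) * 2
        seq = analytic_flow("lamb_oseen", {"gamma": gamma, "r_c": r_c,
                                           "rho": RHO}, grid)
        gx, gy = pressure_gradient(seq, 0, CFG)
        field = integrate_pressure(gx, gy, *grid)
        X, Y = np.meshgrid(*grid)
        p_true = lamb_oseen_pressure_oracle(np.hypot(X, Y), gamma, r_c)
        rng = p_true.max() - p_true.min()
        err = (field.p - field.p.mean()) - (p_true - p_true.mean())
        assert np.sqrt(np.mean(err**2)) <= 0.05 * rng


class TestHeadPressure:
    def _uniform_field(self, p0):
        x = np.linspace(0.0, 0.3, 151)
        y = np.linspace(-0.05, 0.05, 51)
        p = np.full((51, 151), p0)
        return PressureField(x, y, p, np.ones_like(p, dtype=bool))

    def test_uniform_and_zero_fields(self):
        assert head_pressure(self._uniform_field(7.5), (0.15, 0.0), math.pi,
                             0.19, 0.03) == pytest.approx(7.5)
        assert head_pressure(self._uniform_field(0.0), (0.15, 0.0), math.pi,
                             0.19, 0.03) == 0.0

    def test_box_node_count_matches_area(self):
        field = self._uniform_field(1.0)
        BL, width = 0.19, 0.03
        box = head_box_mask(field, (0.15, 0.0), math.pi, BL, width)
        cell = 0.002 * 0.002
        expected = 0.1 * BL * width / cell
        row = 0.1 * BL / 0.002  # one row of cells
        assert abs(box.sum() - expected) <= row + width / 0.002 + 1

    def test_box_outside_grid_rejected(self):
        field = self._uniform_field(1.0)
        with pytest.raises(ValueError):
            head_pressure(field, (10.0, 10.0), 0.0, 0.19, 0.03)

    def test_drag_force_is_pressure_times_area(self):
        assert drag_force(12.0, 0.5e-3) == pytest.approx(6e-3)


class TestSubtractMeanFlow:
    def test_uniform_flow_becomes_zero(self, oracle_grid):
        seq = analytic_flow("uniform", {"u0": 0.3}, oracle_grid)
        out = subtract_mean_flow(seq)
        np.testing.assert_allclose(out.u, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.v, 0.0, atol=1e-12)
        assert out.meta["subtracted_mean_u"] == pytest.approx(0.3)

    def test_mean_removed_and_vorticity_preserved(self, small_wake):
        seq = simulate_wake(small_wake, duration=2.0 / small_wake.fps)
        out = subtract_mean_flow(seq)
        assert abs(out.u.mean()) < 1e-12
        w0 = vorticity(seq.u[0], seq.v[0], seq.x, seq.y)
        w1 = vorticity(out.u[0], out.v[0], out.x, out.y)
        np.testing.assert_allclose(w0, w1, atol=1e-12)


class TestVortexCenters:
    def test_uniform_flow_has_no_centres(self, oracle_grid):
        seq = analytic_flow("uniform", {"u0": 0.3}, oracle_grid)
        assert vortex_centers(seq.u[0], seq.v[0], seq.x, seq.y) == []

    def test_single_vortex_located_within_one_cell(self):
        grid = (np.linspace(-0.05, 0.05, 101),) * 2
        seq = analytic_flow("lamb_oseen", {"gamma": 0.02, "r_c": 0.008,
                                           "center": (0.011, -0.004)}, grid)
        centres = vortex_centers(seq.u[0], seq.v[0], seq.x, seq.y)
        assert len(centres) == 1
        cx, cy, sign = centres[0]
        cell = float(np.diff(grid[0]).mean())
        assert abs(cx - 0.011) <= cell and abs(cy + 0.004) <= cell
        assert sign == 1
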