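"""Cone construction, transition rows, backprojection, sensitivity map."""

import math

import numpy as np
import pytest

from comptoncam import ArmModel, ImageGrid
from comptoncam.events import ComptonEvent, DetectorSpec, EventList
from comptoncam.grid import normalize
from comptoncam.phantoms import two_point_phantom
from comptoncam.projection import (
    ConeRecord,
    ConeSystem,
    angular_residual,
    backproject,
    cones_from_events,
    event_to_cone,
    sensitivity_map,
    si_solid_angle,
    signed_angular_residual,
    transition_row,
)
from comptoncam.simulate import SimConfig, simulate_events


def _random_cones(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        apex = rng.uniform(-16, 16, 3) * [1, 1, 0]
        axis = rng.normal(size=3)
        axis[2] = abs(axis[2]) + 0.3
        axis /= np.linalg.norm(axis)
        out.append(ConeRecord(apex, axis, rng.uniform(10.0, 120.0)))
    return out


class TestEventToCone:
    def test_symmetric_split_straight_up(self):
        ev = ComptonEvent((0.0, 0.0, 0.0), (0.0, 0.0, -5.0), 255.5, 255.5)
        cone = event_to_cone(ev)
        np.testing.assert_allclose(cone.apex, [0, 0, 0])
        np.testing.assert_allclose(cone.axis, [0, 0, 1])
        assert cone.half_angle == pytest.approx(90.0)

    def test_axis_unit_norm(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scat = rng.uniform(-16, 16, 3) * [1, 1, 0]
            absorb = np.append(rng.uniform(-16, 16, 2), rng.uniform(-15, -4))
            ev = ComptonEvent(tuple(scat), tuple(absorb), 200.0, 311.0)
            assert np.linalg.norm(event_to_cone(ev).axis) == pytest.approx(1.0, abs=1e-12)

    def test_forbidden_kinematics_flagged(self):
        ev = ComptonEvent((0.0, 0.0, 0.0), (0.0, 0.0, -5.0), 450.0, 61.0)
        cone = event_to_cone(ev)
        assert not cone.valid


class TestAngularResidual:
    def test_point_on_surface_and_on_axis(self):
        cone = ConeRecord(np.zeros(3), np.array([0.0, 0.0, 1.0]), 30.0)
        on_surface = np.array([100 * math.tan(math.radians(30.0)), 0.0, 100.0])
        assert angular_residual(cone, on_surface) == pytest.approx(0.0, abs=1e-9)
        assert angular_residual(cone, np.array([0.0, 0.0, 50.0])) == pytest.approx(30.0)

    def test_signed_variant_sign(self):
        cone = ConeRecord(np.zeros(3), np.array([0.0, 0.0, 1.0]), 30.0)
        inside = np.array([10.0, 0.0, 100.0])  # alpha < 30
        outside = np.array([100.0, 0.0, 100.0])  # alpha > 30
        assert signed_angular_residual(cone, inside) < 0
        assert signed_angular_residual(cone, outside) > 0

    def test_brute_force_surface_minimum(self):
        # residual must equal the minimum angle to any cone-surface direction
        rng = np.random.default_rng(2)
        phis = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
        for cone in _random_cones(20, seed=3):
            point = np.append(rng.uniform(-150, 150, 2), 100.0)
            w = math.radians(cone.half_angle)
            # orthonormal frame around the axis
            helper = np.array([1.0, 0.0, 0.0])
            if abs(cone.axis[0]) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            u = np.cross(cone.axis, helper)
            u /= np.linalg.norm(u)
            v = np.cross(cone.axis, u)
            dirs = (
                math.cos(w) * cone.axis[None, :]
                + math.sin(w) * (np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * v)
            )
            d = point - cone.apex
            d /= np.linalg.norm(d)
            brute = np.degrees(np.arccos(np.clip(dirs @ d, -1, 1))).min()
            assert angular_residual(cone, point) == pytest.approx(brute, abs=1e-3)


class TestTransitionRow:
    def test_matches_scalar_reevaluation(self, small_grid, arm):
        from comptoncam.grid import pixel_center

        for cone in _random_cones(5, seed=4):
            row = transition_row(cone, small_grid, arm)
            rng = np.random.default_rng(0)
            for _ in range(50):
                i = rng.integers(0, small_grid.nx)
                j = rng.integers(0, small_grid.ny)
                p = pixel_center(small_grid, i, j)
                d = p - cone.apex
                r2 = float(d @ d)
                alpha = math.degrees(
                    math.acos(min(1.0, max(-1.0, float(d @ cone.axis) / math.sqrt(r2))))
                )
                resid = abs(alpha - cone.half_angle)
                if resid <= 5 * arm.fwhm:
                    expected = (
                        math.exp(-0.5 * (resid / arm.sigma) ** 2)
                        / (arm.sigma * math.sqrt(2 * math.pi))
                        / r2
                    )
                else:
                    expected = 0.0
                assert row[i * small_grid.ny + j] == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_peak_on_cone_surface(self, small_grid, arm):
        cone = ConeRecord(np.zeros(3), np.array([0.0, 0.0, 1.0]), 8.0)
        row = transition_row(cone, small_grid, arm)
        centers = small_grid.pixel_centers()
        resid = np.array([angular_residual(cone, c) for c in centers])
        r2 = np.einsum("ij,ij->i", centers, centers)
        # dividing out the distance factor must leave the kernel maximal
        # at the smallest residual
        kern = row * r2
        assert np.argmax(kern) == np.argmin(resid)

    def test_rotation_equivariance(self, arm):
        grid = ImageGrid(fov_x=41, fov_y=41, pixel=1.0)
        cone = _random_cones(1, seed=6)[0]
        rot = ConeRecord(
            np.array([-cone.apex[1], cone.apex[0], cone.apex[2]]),
            np.array([-cone.axis[1], cone.axis[0], cone.axis[2]]),
            cone.half_angle,
        )
        row = transition_row(cone, grid, arm).reshape(grid.shape)
        row_rot = transition_row(rot, grid, arm).reshape(grid.shape)
        np.testing.assert_allclose(row_rot, np.rot90(row, 1), atol=1e-12)

    def test_invalid_cone_rejected(self, small_grid, arm):
        cone = ConeRecord(np.zeros(3), np.array([0.0, 0.0, 1.0]), float("nan"))
        with pytest.raises(ValueError):
            transition_row(cone, small_grid, arm)


class TestConeSystem:
    def test_sparse_rows_match_dense_transition_rows(self, small_grid, arm):
        ph = two_point_phantom(8.0, ImageGrid(fov_x=41, fov_y=41, pixel=1.0))
        ev = simulate_events(
            ph, DetectorSpec(), SimConfig(40, seed=0, mode="ideal-cone"), arm
        )
        system = ConeSystem(ev, small_grid, arm, dtype=np.float64)
        cones = cones_from_events(ev)
        for i in range(len(ev)):
            if not system.valid[i]:
                continue
            dense = transition_row(cones[i], small_grid, arm)
            # numba (libm) vs numpy vectorized transcendentals differ by
            # ~1 ulp, amplified ~100x in the far Gaussian tail
            np.testing.assert_allclose(
                system.matrix[i].toarray().ravel(), dense, rtol=1e-9, atol=0
            )

    def test_candidate_sets_match_residual_band(self, small_grid, arm):
        ph = two_point_phantom(8.0, ImageGrid(fov_x=41, fov_y=41, pixel=1.0))
        ev = simulate_events(
            ph, DetectorSpec(), SimConfig(20, seed=1, mode="ideal-cone"), arm
        )
        band = arm.fwhm / 2
        system = ConeSystem(ev, small_grid, arm, candidate_band=band)
        cones = cones_from_events(ev)
        centers = small_grid.pixel_centers()
        for i in range(len(ev)):
            got = np.sort(system.cand_idx[system.cand_ptr[i] : system.cand_ptr[i + 1]])
            resid = np.abs(signed_angular_residual(cones[i], centers))
            expected = np.flatnonzero(resid <= band)
            np.testing.assert_array_equal(got, expected)


class TestBackproject:
    def test_single_event_is_normalized_row(self, small_grid, arm):
        from comptoncam.physics import energies_from_angle

        # a forward (8 deg) cone whose section lies inside the small FOV
        e1, e2 = energies_from_angle(511.0, 8.0)
        ev = EventList(
            np.array([[1.0, -2.0, 0.0]]), np.array([[0.5, 1.0, -5.0]]), [e1], [e2]
        )
        img = backproject(ev, small_grid, arm, system=ConeSystem(ev, small_grid, arm, dtype=np.float64))
        row = transition_row(cones_from_events(ev)[0], small_grid, arm)
        np.testing.assert_allclose(img.values.ravel(), row / row.sum(), rtol=1e-12)

    def test_order_independence(self, twopoint_2k):
        ev = twopoint_2k["events"].select(np.arange(200))
        grid, arm = twopoint_2k["grid"], twopoint_2k["arm"]
        fwd = backproject(ev, grid, arm)
        perm = np.random.default_rng(0).permutation(200)
        rev = backproject(ev.select(perm), grid, arm)
        np.testing.assert_allclose(fwd.values, rev.values, atol=1e-12)

    def test_two_point_maxima_near_sources(self, arm, det):
        # BP blurs ~9 mm at this ARM, so test at a clearly separated pair
        grid = ImageGrid(fov_x=101, fov_y=101, pixel=1.0)
        ph = two_point_phantom(20.0, grid)
        ev = simulate_events(ph, det, SimConfig(2000, seed=0, mode="ideal-cone"), arm)
        img = backproject(ev, grid, arm)
        prof = img.profile_y0()
        x = grid.x_centers()
        left_peak = x[x < 0][np.argmax(prof[x < 0])]
        right_peak = x[x > 0][np.argmax(prof[x > 0])]
        assert abs(left_peak + 10.0) <= 2.0
        assert abs(right_peak - 10.0) <= 2.0

    def test_no_valid_events_rejected(self, small_grid, arm):
        ev = EventList(
            np.array([[0.0, 0.0, 0.0]]), np.array([[0.0, 0.0, -5.0]]), [450.0], [61.0]
        )
        with pytest.raises(ValueError):
            backproject(ev, small_grid, arm)


class TestSensitivity:
    def test_center_has_maximal_solid_angle(self, det):
        grid = ImageGrid(fov_x=41, fov_y=41, pixel=1.0)
        s = si_solid_angle(grid.pixel_centers(), det)
        center = np.argmin(np.einsum("ij,ij->i", grid.pixel_centers()[:, :2], grid.pixel_centers()[:, :2]))
        assert np.argmax(s) == center

    def test_mirror_symmetry(self, det):
        grid = ImageGrid(fov_x=21, fov_y=21, pixel=1.0)
        s = sensitivity_map(grid, det).values.reshape(grid.shape)
        np.testing.assert_allclose(s, s[::-1, :], rtol=1e-6)
        np.testing.assert_allclose(s, s[:, ::-1], rtol=1e-6)

    def test_on_axis_closed_form(self, det):
        # pyramid solid angle of a square of half-width a seen on-axis
        # from distance d: 4 arcsin(a^2 / (a^2 + d^2)), a = 16, d = 100
        a_half = det.half_extent
        d = 100.0
        expected = 4.0 * math.asin((a_half * a_half) / (a_half * a_half + d * d))
        got = float(si_solid_angle(np.array([[0.0, 0.0, d]]), det, m_sub=64)[0])
        assert got == pytest.approx(expected, abs=1e-6)

    def test_strictly_positive_and_variant_flag(self, det):
        grid = ImageGrid(fov_x=41, fov_y=41, pixel=1.0)
        full = sensitivity_map(grid, det)
        solid_only = sensitivity_map(grid, det, include_absorber=False)
        assert np.all(full.values > 0)
        # absorber acceptance < 1 everywhere
        assert np.all(full.values < solid_only.values)
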