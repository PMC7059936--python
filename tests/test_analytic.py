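"""Legendre-series cone-transform inversion."""

import numpy as np
import pytest
from scipy.integrate import quad

from comptoncam import ArmModel, ImageGrid
from comptoncam.analytic import (
    AngleBands,
    LegendreCoeffs,
    SphereGrid,
    analytic_reconstruct,
    bin_projection,
    evaluate_inversion,
    inverse_kernel,
    legendre_hn,
    reconstruct_from_projection,
)
from comptoncam.events import DetectorSpec, EventList
from comptoncam.phantoms import point_phantom
from comptoncam.physics import klein_nishina_weight
from comptoncam.simulate import SimConfig, simulate_events


class TestAngleBands:
    def test_edges_partition_cos_range(self):
        bands = AngleBands(5.0, 90.0, 16)
        e = bands.edges()
        assert e[0] == pytest.approx(0.0)
        assert e[-1] == pytest.approx(np.cos(np.radians(5.0)))
        assert np.all(np.diff(e) > 0)

    def test_band_of_boundaries(self):
        bands = AngleBands(5.0, 90.0, 8)
        lo, hi = bands.cos_range
        assert bands.band_of(np.array([lo]))[0] == 0
        assert bands.band_of(np.array([hi]))[0] == bands.n_bands - 1
        assert bands.band_of(np.array([np.cos(np.radians(4.0))]))[0] == -1


class TestSphereGrid:
    def test_solid_angles_sum(self):
        hemi = SphereGrid(40, 80)
        assert hemi.n_cells * hemi.cell_solid_angle == pytest.approx(2 * np.pi, abs=1e-6)
        full = SphereGrid(40, 80, hemisphere=False)
        assert full.n_cells * full.cell_solid_angle == pytest.approx(4 * np.pi, abs=1e-6)

    def test_cell_of_own_directions(self):
        g = SphereGrid(20, 40)
        dirs = g.directions()
        np.testing.assert_array_equal(g.cell_of(dirs), np.arange(g.n_cells))

    def test_below_hemisphere_excluded(self):
        g = SphereGrid(10, 10)
        assert g.cell_of(np.array([[0.0, 0.0, -1.0]]))[0] == -1


class TestLegendreHn:
    def test_unit_weight_full_range_orthogonality(self):
        bands = AngleBands(0.0, 180.0, 4)
        coeffs = legendre_hn(bands, n_max=50, weight_fn=lambda c: np.ones_like(c))
        n = np.arange(51)
        np.testing.assert_allclose(coeffs.h, 2.0 / (2 * n + 1), atol=1e-10)

    def test_h0_matches_adaptive_quadrature(self):
        bands = AngleBands(5.0, 90.0, 16)
        coeffs = legendre_hn(bands, 511.0, n_max=8)
        lo, hi = bands.cos_range
        expected, _ = quad(lambda c: klein_nishina_weight(c, 511.0), lo, hi, epsabs=1e-12)
        assert coeffs.h[0] == pytest.approx(expected, abs=1e-8)

    def test_all_positive(self):
        coeffs = legendre_hn(AngleBands(), 511.0, n_max=60)
        assert np.all(coeffs.h > 0)

    def test_apodization_attached(self):
        coeffs = legendre_hn(AngleBands(), 511.0, n_max=10, apod_sigma_rad=0.05)
        assert coeffs.apod[0] == 1.0
        assert np.all(np.diff(coeffs.apod) < 0)


class TestInverseKernel:
    def test_order_zero_constant(self):
        bands = AngleBands(5.0, 90.0, 4)
        coeffs = legendre_hn(bands, 511.0, n_max=0)
        x = np.linspace(-1, 1, 11)
        expected = 1.0 / (4 * np.pi * coeffs.h[0])
        np.testing.assert_allclose(inverse_kernel(x, 0.5, coeffs), expected)

    def test_argument_symmetry(self):
        coeffs = legendre_hn(AngleBands(), 511.0, n_max=20)
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(-1, 1, 2)
            assert inverse_kernel(a, b, coeffs) == pytest.approx(
                inverse_kernel(b, a, coeffs), rel=1e-12
            )

    def test_truncation_stability_with_apodization(self):
        sigma_b = np.radians(ArmModel.from_fwhm(4.9).fwhm)
        bands = AngleBands()
        k40 = legendre_hn(bands, 511.0, n_max=40, apod_sigma_rad=sigma_b)
        k60 = legendre_hn(bands, 511.0, n_max=60, apod_sigma_rad=sigma_b)
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, 100)
        w = rng.uniform(*bands.cos_range, 100)
        v40 = np.array([inverse_kernel(xi, wi, k40) for xi, wi in zip(x, w)])
        v60 = np.array([inverse_kernel(xi, wi, k60) for xi, wi in zip(x, w)])
        scale = np.abs(v60).max()
        assert np.max(np.abs(v40 - v60)) / scale < 0.01

    def test_domain_checked(self):
        coeffs = legendre_hn(AngleBands(), 511.0, n_max=5)
        with pytest.raises(ValueError):
            inverse_kernel(1.5, 0.0, coeffs)


def _ideal_events(n, seed, det, arm, grid):
    ph = point_phantom(grid)
    return simulate_events(ph, det, SimConfig(n, seed=seed, mode="ideal-cone"), arm)


class TestBinProjection:
    def test_single_event_single_cell(self, det, arm, twopoint_grid):
        ev = _ideal_events(1, 0, det, arm, twopoint_grid)
        sphere = SphereGrid(20, 40)
        bands = AngleBands(0.5, 179.0, 8)
        g = bin_projection(ev, sphere, bands)
        assert np.count_nonzero(g) == 1

    def test_count_conservation(self, det, arm, twopoint_grid):
        ev = _ideal_events(500, 1, det, arm, twopoint_grid)
        sphere = SphereGrid(20, 40)
        bands = AngleBands(5.0, 90.0, 16)
        g = bin_projection(ev, sphere, bands)
        total = g.sum() * sphere.cell_solid_angle * bands.width
        from comptoncam.projection import cones_from_events

        cones = cones_from_events(ev)
        w = cones.half_angle[cones.valid]
        in_range = np.sum((w >= 5.0) & (w <= 90.0))
        assert total == pytest.approx(in_range)

    def test_out_of_band_events_excluded(self, twopoint_grid):
        # a 4-degree cone with omega_min = 5 deg contributes nothing
        e1, _ = 511.0 - 1.0, None
        from comptoncam.physics import energies_from_angle

        e1, e2 = energies_from_angle(511.0, 4.0)
        ev = EventList(
            np.array([[0.0, 0.0, 0.0]]), np.array([[0.0, 0.0, -5.0]]), [e1], [e2]
        )
        with pytest.raises(ValueError):
            bin_projection(ev, SphereGrid(20, 40), AngleBands(5.0, 90.0, 8))


class TestReconstruction:
    def test_linearity_in_projection_data(self, twopoint_grid):
        sphere = SphereGrid(10, 20)
        bands = AngleBands(5.0, 90.0, 4)
        coeffs = legendre_hn(bands, 511.0, n_max=20, apod_sigma_rad=0.04)
        grid = ImageGrid(fov_x=21, fov_y=21, pixel=1.0)
        rng = np.random.default_rng(0)
        g1 = rng.random((4, sphere.n_cells))
        g2 = rng.random((4, sphere.n_cells))
        a = evaluate_inversion(g1, sphere, bands, coeffs, grid)
        b = evaluate_inversion(g2, sphere, bands, coeffs, grid)
        ab = evaluate_inversion(g1 + g2, sphere, bands, coeffs, grid)
        np.testing.assert_allclose(ab, a + b, atol=1e-10 * np.abs(ab).max())

    def test_uniform_projection_gives_uniform_image(self):
        # the cone transform of a uniform sphere function is constant in
        # (t, omega); inverting it on a full-sphere grid must return a
        # uniform direction distribution (only the n = 0 term survives)
        sphere = SphereGrid(60, 240, hemisphere=False)
        bands = AngleBands(10.0, 90.0, 4)
        coeffs = legendre_hn(bands, 511.0, n_max=60, apod_sigma_rad=0.0855)
        grid = ImageGrid(fov_x=41, fov_y=41, pixel=1.0)
        g = np.full((4, sphere.n_cells), 2 * np.pi)
        lam = evaluate_inversion(g, sphere, bands, coeffs, grid)
        assert lam.min() > 0
        assert (lam.max() - lam.min()) / lam.mean() < 0.05

    def test_point_source_recovered_on_axis(self, det):
        grid = ImageGrid(fov_x=61, fov_y=61, pixel=1.0)
        sharp = ArmModel.from_fwhm(0.5)
        ev = _ideal_events(10_000, 2, det, sharp, grid)
        img = analytic_reconstruct(ev, grid, arm=sharp)
        i, j = np.unravel_index(np.argmax(img.values), img.values.shape)
        x, y = grid.x_centers()[i], grid.y_centers()[j]
        assert np.hypot(x, y) <= 3.0

    def test_rotation_equivariance(self, det, arm):
        grid = ImageGrid(fov_x=41, fov_y=41, pixel=1.0)
        ph = point_phantom(grid, 8.0, 3.0)
        ev = simulate_events(ph, det, SimConfig(400, seed=3, mode="ideal-cone"), arm)
        # rotate the whole scene by 90 degrees about the detector normal
        rot = lambda v: np.column_stack([-v[:, 1], v[:, 0], v[:, 2]])
        ev_rot = EventList(rot(ev.scatter), rot(ev.absorber), ev.e1, ev.e2)
        sphere = SphereGrid(25, 100)  # n_phi divisible by 4: exact cell mapping
        bands = AngleBands(5.0, 90.0, 8)
        img = analytic_reconstruct(ev, grid, bands=bands, sphere=sphere, arm=arm)
        img_rot = analytic_reconstruct(ev_rot, grid, bands=bands, sphere=sphere, arm=arm)
        np.testing.assert_allclose(
            img_rot.values, np.rot90(img.values, 1), atol=1e-9
        )

    def test_normalized_nonnegative_output(self, det, arm, twopoint_grid):
        ev = _ideal_events(300, 4, det, arm, twopoint_grid)
        img = analytic_reconstruct(ev, twopoint_grid, arm=arm)
        assert np.all(img.values >= 0)
        assert abs(img.values.sum() - 1.0) < 1e-12
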