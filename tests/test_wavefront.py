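"""Zernike modes, modal solve, zonal integration and correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import holodop as hd
from holodop.shack_hartmann import ReferenceMode, ShiftField
from holodop.wavefront import poisson_solve_neumann
from holodop.zernike import radial_polynomial, validate_nm
from tests.conftest import make_random_field


def gauss_legendre_disk_inner(mode_a, mode_b, n_r=64, n_t=256) -> float:
    """Area-averaged inner product of two Zernike modes over the unit
    disk by Gauss-Legendre (radial) x trapezoid (angular) quadrature;
    exact to machine precision for polynomial x trigonometric factors."""
    nodes, weights = np.polynomial.legendre.leggauss(n_r)
    r = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    theta = 2.0 * np.pi * np.arange(n_t) / n_t
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    x, y = rr * np.cos(tt), rr * np.sin(tt)
    za = hd.zernike_eval(*mode_a, x, y)
    zb = hd.zernike_eval(*mode_b, x, y)
    integrand = (za * zb).mean(axis=1) * r * w
    return 2.0 * integrand.sum()  # (1/pi) * int = 2 * int r ... dr


def synthetic_shift_field(tm: hd.TransitionMatrix,
                          c: np.ndarray) -> ShiftField:
    """Noiseless shifts a coefficient vector would produce."""
    grid = tm.grid
    pred = tm.entries @ c
    shifts = np.zeros((grid.n_subapertures, 2))
    shifts[tm.subaperture_map, 0] = pred[0::2]
    shifts[tm.subaperture_map, 1] = pred[1::2]
    valid = np.zeros(grid.n_subapertures, dtype=bool)
    valid[tm.subaperture_map] = True
    return ShiftField(shifts, np.ones(grid.n_subapertures), valid,
                      ReferenceMode.CENTRAL)


class TestZernike:
    def test_piston_is_unity_on_the_disk(self):
        x, y = np.meshgrid(np.linspace(-1, 1, 33), np.linspace(-1, 1, 33))
        z = hd.zernike_eval(0, 0, x, y)
        np.testing.assert_allclose(z, 1.0)

    @pytest.mark.parametrize("mode_a,mode_b", [
        ((2, 0), (2, 2)), ((2, 0), (4, 0)), ((3, 1), (3, 3)),
        ((1, 1), (3, 1)), ((2, -2), (2, 2)), ((3, -1), (3, 1)),
    ])
    def test_distinct_modes_orthogonal_by_quadrature(self, mode_a, mode_b):
        assert abs(gauss_legendre_disk_inner(mode_a, mode_b)) < 1e-10

    @pytest.mark.parametrize("mode", [(1, 1), (2, 0), (2, -2), (3, 1),
                                      (4, 0), (5, -3)])
    def test_modes_are_unit_norm_by_quadrature(self, mode):
        assert gauss_legendre_disk_inner(mode, mode) == \
            pytest.approx(1.0, abs=1e-10)

    def test_defocus_is_even_along_any_axis(self):
        r = np.linspace(0, 1, 11)
        assert hd.zernike_eval(2, 0, r, 0 * r) == \
            pytest.approx(hd.zernike_eval(2, 0, -r, 0 * r))

    def test_invalid_mode_pairs_rejected(self):
        for n, m in [(2, 1), (1, -2), (-1, 1), (3, 5)]:
            with pytest.raises(ValueError):
                validate_nm(n, m)

    def test_radial_polynomial_known_values(self):
        r = np.array([0.0, 0.5, 1.0])
        np.testing.assert_allclose(radial_polynomial(2, 0, r),
                                   2 * r**2 - 1)
        np.testing.assert_allclose(radial_polynomial(3, 1, r),
                                   3 * r**3 - 2 * r)

    def test_mode_count_by_radial_orders(self):
        assert hd.mode_count(2, 5) == 18
        assert hd.mode_count(2, 3) == 7
        assert hd.mode_count(0, 0) == 1
        with pytest.raises(ValueError):
            hd.mode_count(3, 2)

    def test_micrometre_radian_round_trip(self):
        c = np.array([0.3, -1.2, 2.5])
        np.testing.assert_allclose(hd.rad_to_um(hd.um_to_rad(c)), c,
                                   rtol=1e-12)


class TestTransitionMatrix:
    GRID = hd.SubapertureGrid.for_pupil(160, 5)

    def test_tilt_column_is_constant(self):
        modes = hd.ZernikeModeSet(((1, 1),))
        tm = hd.build_transition_matrix(self.GRID, modes)
        x_rows = tm.entries[0::2, 0]
        y_rows = tm.entries[1::2, 0]
        np.testing.assert_allclose(x_rows, x_rows[0], rtol=1e-6)
        np.testing.assert_allclose(y_rows, 0.0, atol=1e-9 * abs(x_rows[0]))

    def test_defocus_x_entries_proportional_to_centre_x(self):
        modes = hd.ZernikeModeSet(((2, 0),))
        tm = hd.build_transition_matrix(self.GRID, modes)
        centers_x = self.GRID.centers[tm.subaperture_map, 0]
        x_rows = tm.entries[0::2, 0]
        # gradient of sqrt(3)(2r^2 - 1) along x is 4 sqrt(3) x
        keep = np.abs(centers_x) > 1e-9
        ratio = x_rows[keep] / centers_x[keep]
        np.testing.assert_allclose(ratio, ratio[0], rtol=0.02)

    def test_corner_rows_absent(self):
        grid = hd.SubapertureGrid.for_pupil(252, 7)
        modes = hd.ZernikeModeSet.from_radial_orders(2, 3)
        tm = hd.build_transition_matrix(grid, modes)
        assert tm.n == 2 * 45
        assert len(tm.subaperture_map) == 45

    def test_underdetermined_grid_rejected(self):
        grid = hd.SubapertureGrid.for_pupil(64, 3)  # 18 shift components
        modes = hd.ZernikeModeSet.from_radial_orders(2, 6)  # 25 modes
        with pytest.raises(ValueError, match="underdetermined"):
            hd.build_transition_matrix(grid, modes)


class TestSolveZernike:
    GRID = hd.SubapertureGrid.for_pupil(160, 5)
    MODES = hd.ZernikeModeSet.from_radial_orders(2, 3)

    def test_zero_shifts_give_zero_coefficients(self):
        tm = hd.build_transition_matrix(self.GRID, self.MODES)
        field = synthetic_shift_field(tm, np.zeros(self.MODES.p))
        c = hd.solve_zernike(tm, field)
        np.testing.assert_allclose(c.c, 0.0, atol=1e-12)

    def test_in_range_coefficients_recovered_exactly(self, rng):
        tm = hd.build_transition_matrix(self.GRID, self.MODES)
        c_true = rng.uniform(-1, 1, self.MODES.p)
        field = synthetic_shift_field(tm, c_true)
        c = hd.solve_zernike(tm, field)
        np.testing.assert_allclose(c.c, c_true, atol=1e-8)

    @given(st.floats(0.25, 4.0))
    @settings(max_examples=10, deadline=None)
    def test_solution_is_linear_in_the_shifts(self, scale):
        tm = hd.build_transition_matrix(self.GRID, self.MODES)
        rng = np.random.default_rng(7)
        c_true = rng.uniform(-1, 1, self.MODES.p)
        field = synthetic_shift_field(tm, c_true)
        scaled = ShiftField(field.shifts * scale, field.peak_value,
                            field.valid, field.reference_mode)
        c = hd.solve_zernike(tm, scaled)
        np.testing.assert_allclose(c.c, scale * c_true, atol=1e-8)

    def test_constant_shift_offset_is_ignored(self, rng):
        """The reference image fixes the shift origin only up to a
        constant, which must not leak into the coefficients."""
        tm = hd.build_transition_matrix(self.GRID, self.MODES)
        c_true = rng.uniform(-1, 1, self.MODES.p)
        field = synthetic_shift_field(tm, c_true)
        offset = ShiftField(field.shifts + np.array([1.7, -0.9]),
                            field.peak_value, field.valid,
                            field.reference_mode)
        c = hd.solve_zernike(tm, offset)
        np.testing.assert_allclose(c.c, c_true, atol=1e-8)

    def test_too_few_valid_subapertures_rejected(self):
        tm = hd.build_transition_matrix(self.GRID, self.MODES)
        field = synthetic_shift_field(tm, np.zeros(self.MODES.p))
        field.valid[:] = False
        field.valid[:2] = True
        with pytest.raises(ValueError):
            hd.solve_zernike(tm, field)


class TestZonalIntegration:
    def test_paraboloid_slopes_integrate_to_paraboloid(self):
        n = 192
        yy, xx = np.mgrid[0:n, 0:n] - n // 2
        w_true = 2e-3 * (xx**2 + yy**2)
        gx = np.gradient(w_true, axis=1)
        gy = np.gradient(w_true, axis=0)
        w = poisson_solve_neumann(gx, gy)
        err = (w - w.mean()) - (w_true - w_true.mean())
        rms_true = np.sqrt(((w_true - w_true.mean())**2).mean())
        assert np.sqrt((err**2).mean()) / rms_true <= 0.02

    def test_all_zero_shifts_give_flat_wavefront(self):
        grid = hd.SubapertureGrid.for_pupil(160, 5)
        field = ShiftField(np.zeros((25, 2)), np.ones(25),
                           np.ones(25, dtype=bool), ReferenceMode.CENTRAL)
        w = hd.integrate_gradient(field, grid, 160)
        assert np.abs(w.phase).max() < 1e-10

    def test_modal_and_zonal_reconstructions_agree_in_basis(self, rng):
        """For a screen inside the fitted mode set, gradient integration
        matches the Zernike reconstruction to 5% RMS."""
        grid = hd.SubapertureGrid.for_pupil(256, 7)
        modes = hd.ZernikeModeSet.from_radial_orders(2, 3)
        tm = hd.build_transition_matrix(grid, modes)
        c = rng.uniform(-1, 1, modes.p)
        field = synthetic_shift_field(tm, c)
        zonal = hd.integrate_gradient(field, grid, 256)
        modal = hd.ZernikeCoefficients(c, modes).to_wavefront(
            256, grid.span_px / 2.0)
        report = hd.residual_metrics(modal, zonal)
        assert report.fraction <= 0.05

    def test_invalid_subaperture_filled_from_neighbours(self, rng):
        grid = hd.SubapertureGrid.for_pupil(256, 7)
        modes = hd.ZernikeModeSet.from_radial_orders(2, 2)
        tm = hd.build_transition_matrix(grid, modes)
        c = rng.uniform(-1, 1, modes.p)
        field = synthetic_shift_field(tm, c)
        broken = ShiftField(field.shifts.copy(), field.peak_value,
                            field.valid.copy(), field.reference_mode)
        victim = 3 * 7 + 3
        broken.shifts[victim] = (37.0, -12.0)  # garbage to be ignored
        broken.valid[victim] = False
        a = hd.integrate_gradient(field, grid, 256)
        b = hd.integrate_gradient(broken, grid, 256)
        rel = np.abs(b.phase - a.phase).max() / np.abs(a.phase).max()
        assert rel < 0.05

    def test_outlier_stays_more_local_than_in_the_modal_path(self, rng):
        """One corrupted slope: the zonal far-field error decays (dipole
        response of least-squares integration) while the modal path
        spreads the same outlier over the whole pupil."""
        grid = hd.SubapertureGrid.for_pupil(256, 7)
        modes = hd.ZernikeModeSet.from_radial_orders(2, 3)
        tm = hd.build_transition_matrix(grid, modes)
        c = rng.uniform(-1, 1, modes.p)
        field = synthetic_shift_field(tm, c)
        broken = ShiftField(field.shifts.copy(), field.peak_value,
                            field.valid, field.reference_mode)
        cell = 3 * 7 + 1
        broken.shifts[cell, 0] += 5.0
        w_ref = hd.integrate_gradient(field, grid, 256)
        w_bad = hd.integrate_gradient(broken, grid, 256)
        diff = hd.remove_tip_tilt(hd.WavefrontEstimate(
            w_bad.phase - w_ref.phase, w_bad.source, w_bad.pupil_mask))
        s = grid.aperture_px
        start = (256 - grid.span_px) // 2
        cy = start + 3 * s + (s - 1) / 2
        cx = start + 1 * s + (s - 1) / 2
        yy, xx = np.mgrid[0:256, 0:256]
        r = np.hypot(yy - cy, xx - cx)
        near = (r <= 2 * s) & diff.pupil_mask
        far = (r > 2 * s) & diff.pupil_mask
        zonal_ratio = np.abs(diff.phase[far]).max() \
            / np.abs(diff.phase[near]).max()
        assert zonal_ratio <= 0.3
        # same outlier through the modal path corrupts globally
        c_bad = hd.solve_zernike(tm, broken)
        m_diff = hd.ZernikeCoefficients(c_bad.c - c, modes).to_wavefront(
            256, grid.span_px / 2.0)
        m_diff = hd.remove_tip_tilt(m_diff)
        modal_ratio = np.abs(m_diff.phase[far & m_diff.pupil_mask]).max() \
            / np.abs(m_diff.phase[near & m_diff.pupil_mask]).max()
        assert modal_ratio > 2 * zonal_ratio

    def test_too_few_valid_cells_rejected(self):
        grid = hd.SubapertureGrid.for_pupil(160, 5)
        field = ShiftField(np.zeros((25, 2)), np.ones(25),
                           np.zeros(25, dtype=bool),
                           ReferenceMode.CENTRAL)
        field.valid[:3] = True
        with pytest.raises(ValueError):
            hd.integrate_gradient(field, grid, 160)


class TestTipTiltAndCorrection:
    def test_pure_plane_removed_completely(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        mask = np.hypot(yy - 32, xx - 32) <= 30
        w = hd.WavefrontEstimate(0.3 + 0.01 * xx - 0.02 * yy,
                                 "gradient_integration", mask)
        out = hd.remove_tip_tilt(w)
        assert np.abs(out.phase).max() < 1e-10

    def test_defocus_preserved_under_tip_tilt_removal(self):
        n = 129  # odd grid: the disk mask is symmetric about the origin
        modes = hd.ZernikeModeSet(((2, 0),))
        w = hd.ZernikeCoefficients(np.array([0.7]), modes).to_wavefront(n)
        tilted = hd.WavefrontEstimate(
            w.phase + 0.05 * np.arange(n)[None, :], w.source, w.pupil_mask)
        out = hd.remove_tip_tilt(tilted)
        # compare modulo piston: the rasterised disk gives the defocus
        # map a small nonzero pixel mean, which tip/tilt removal strips
        expected = w.phase - w.phase[w.pupil_mask].mean()
        err = np.abs(out.phase - expected)[w.pupil_mask].max()
        assert err <= 1e-8 * np.abs(w.phase).max() + 1e-10

    def test_idempotent(self, rng):
        mask = np.ones((32, 32), dtype=bool)
        w = hd.WavefrontEstimate(rng.standard_normal((32, 32)),
                                 "gradient_integration", mask)
        once = hd.remove_tip_tilt(w)
        twice = hd.remove_tip_tilt(once)
        np.testing.assert_allclose(twice.phase, once.phase, atol=1e-10)

    def test_correction_conserves_energy_and_inverts_imposition(
            self, rng, small_config):
        stack = make_random_field(rng, n=64, config=small_config)
        modes = hd.ZernikeModeSet.from_radial_orders(2, 3)
        c = rng.uniform(-1, 1, modes.p)
        w = hd.ZernikeCoefficients(c, modes).to_wavefront(64)
        pupil = hd.to_pupil(stack)
        full_phase = hd.WavefrontEstimate(
            hd.ZernikeCoefficients(c, modes).to_wavefront(64).phase,
            "zernike", np.ones((64, 64), dtype=bool))
        aberrated = hd.ComplexFieldStack(
            pupil.field * np.exp(1j * full_phase.phase),
            hd.Plane.PUPIL, 0.0, small_config)
        corrected = hd.apply_correction(aberrated, full_phase)
        np.testing.assert_allclose(corrected.energy(), aberrated.energy(),
                                   rtol=1e-12)
        err = np.linalg.norm(corrected.field - pupil.field) \
            / np.linalg.norm(pupil.field)
        assert err <= 1e-6

    def test_zero_corrector_is_identity(self, rng, small_config):
        pupil = hd.to_pupil(make_random_field(rng, n=64,
                                              config=small_config))
        out = hd.apply_correction(pupil, np.zeros((64, 64)))
        np.testing.assert_array_equal(out.field, pupil.field)


class TestResidualMetrics:
    MODES = hd.ZernikeModeSet.from_radial_orders(2, 3)

    def coeffs(self, values):
        c = np.zeros(self.MODES.p)
        c[:len(values)] = values
        return hd.ZernikeCoefficients(c, self.MODES)

    def test_perfect_estimate_gives_zero_fraction(self):
        a = self.coeffs([1.0, -0.5])
        report = hd.residual_metrics(a, a)
        assert report.rms_residual == 0.0
        assert report.fraction == 0.0

    def test_null_estimate_gives_fraction_one(self):
        a = self.coeffs([1.0, -0.5])
        report = hd.residual_metrics(a, self.coeffs([]))
        assert report.fraction == pytest.approx(1.0)

    def test_partial_estimate_arithmetic(self):
        report = hd.residual_metrics(self.coeffs([1.0]),
                                     self.coeffs([0.8]))
        assert report.rms_imposed == pytest.approx(1.0)
        assert report.rms_residual == pytest.approx(0.2)
        assert report.fraction == pytest.approx(0.2)

    def test_zero_imposed_flagged_undefined(self):
        with pytest.warns(RuntimeWarning):
            report = hd.residual_metrics(self.coeffs([]), self.coeffs([]))
        assert not report.fraction_defined
        assert np.isnan(report.fraction)

    def test_mismatched_mode_sets_rejected(self):
        other = hd.ZernikeCoefficients(np.zeros(1),
                                       hd.ZernikeModeSet(((2, 0),)))
        with pytest.raises(ValueError):
            hd.residual_metrics(self.coeffs([1.0]), other)
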