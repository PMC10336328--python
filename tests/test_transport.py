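import numpy as np
import pytest

from thrombosim.histology import Label
from thrombosim.transport import (
    REGION_ABLATED,
    REGION_EXTERIOR,
    REGION_INTACT,
    CoefficientFields,
    ConcentrationField,
    PolarGrid,
    TransportParameters,
    build_coefficients,
    cartesian_to_polar,
    dispersion_coefficients,
    infusion_rate_ml_s,
    peclet,
    penetration_depth,
    solve,
    stability_timestep,
)
from tests.conftest import uniform_section

DEFAULTS = TransportParameters()


class TestScalars:
    def test_peclet_from_printed_constants(self):
        # U d / (n D) = 0.87e-4 / (0.15 * 2.5e-6)
        assert peclet() == pytest.approx(232.0, rel=1e-6)

    def test_peclet_linear_in_diameter(self):
        p2 = TransportParameters(particulate_diameter_cm=2e-4)
        assert peclet(p2) == pytest.approx(2 * peclet())

    def test_peclet_zero_velocity(self):
        assert peclet(TransportParameters(u_cm_s=0.0)) == 0.0

    def test_infusion_rate_conversion(self):
        assert infusion_rate_ml_s(12.5) == pytest.approx(0.0035, abs=5e-5)

    def test_derived_catheter_to_edge_distance(self):
        # B = Q/(2 pi n U r_cath) ~ 0.05 cm keeps U consistent with Q
        assert DEFAULTS.catheter_to_edge_cm == pytest.approx(0.0508, rel=0.01)


class TestDispersion:
    def test_tabulated_values(self):
        assert dispersion_coefficients() == (9.4e-6, 3.4e-6)

    @pytest.mark.parametrize("mode", ["tabulated", "correlation"])
    def test_longitudinal_exceeds_transverse(self, mode):
        for d in (1e-5, 5e-5, 1e-4):
            a_l, a_t = dispersion_coefficients(
                TransportParameters(particulate_diameter_cm=d), mode)
            assert a_l > a_t

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            dispersion_coefficients(mode="nope")

    def test_steady_field_insensitive_to_diameter(self):
        """Sub-5% steady-state change for d over 1e-5..1e-4 cm."""
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.4)
        fields = []
        for d in (1e-5, 1e-4):
            p = TransportParameters(particulate_diameter_cm=d)
            cf = solve(None, None, p, grid, duration_s=20.0,
                       dispersion_mode="correlation")
            fields.append(cf.c_nmol)
        diff = np.max(np.abs(fields[0] - fields[1])) / DEFAULTS.c_source_nmol
        assert diff < 0.05


class TestRegions:
    def _small_section(self):
        return uniform_section(Label.RBC, n=40, pixel_size_um=100.0)  # 4 mm square

    def test_all_intact_without_mask(self):
        sec = self._small_section()
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.15)
        region = cartesian_to_polar(None, sec, grid)
        assert (region == REGION_INTACT).all()

    def test_half_plane_split_by_theta(self):
        sec = self._small_section()
        mask = np.zeros(sec.shape, dtype=bool)
        mask[20:, :] = True  # +row half-plane ablated (theta near 0)
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.15)
        region = cartesian_to_polar(mask, sec, grid)
        th = grid.theta
        interior = slice(1, -1)
        ahead = np.abs(np.cos(th)) > np.sin(grid.dtheta)  # away from the boundary
        downstream = np.cos(th) > 0
        assert (region[interior][:, ahead & downstream] == REGION_ABLATED).all()
        assert (region[interior][:, ahead & ~downstream] == REGION_INTACT).all()

    def test_disk_mask_maps_to_radial_band(self):
        sec = self._small_section()
        cy, cx = sec.centroid_px()
        yy, xx = np.mgrid[0:40, 0:40]
        disk_r_cm = 0.1
        mask = (np.hypot(yy - cy, xx - cx) * 0.01) <= disk_r_cm
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.15, dr_cm=0.002)
        region = cartesian_to_polar(mask, sec, grid)
        r = grid.r_cm
        assert (region[r <= disk_r_cm - 0.01] == REGION_ABLATED).all()
        assert (region[(r >= disk_r_cm + 0.01) & (r <= 0.15)] == REGION_INTACT).all()

    def test_outside_section_is_exterior(self):
        sec = self._small_section()
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.4)  # beyond the 2-mm half-width
        region = cartesian_to_polar(None, sec, grid)
        assert (region[-1] == REGION_EXTERIOR).all()

    def test_coefficient_values(self):
        sec = self._small_section()
        mask = np.ones(sec.shape, dtype=bool)  # fully ablated
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.15)
        c = build_coefficients(sec, mask, grid)
        assert (c.d_r == 25e-6).all() and (c.d_t == 25e-6).all()
        c0 = build_coefficients(sec, None, grid)
        assert (c0.d_r == 9.4e-6).all()
        # v at the catheter surface equals the printed 0.87 cm/s
        assert c0.v[0, 0] == pytest.approx(0.87)
        assert c0.quench[1, 0] == pytest.approx(29.0 * 0.7)


class TestStability:
    def _homog_coeffs(self, grid, d=9.4e-6, d_t=3.4e-6, v=0.87):
        shape = (grid.nr + 2, grid.ntheta)
        return CoefficientFields(
            d_r=np.full(shape, d), d_t=np.full(shape, d_t),
            v=np.full(shape, v), quench=np.zeros(shape),
            region=np.full(shape, REGION_INTACT, dtype=np.uint8))

    def test_reference_grid_advective_bound(self):
        # dr = 0.001 mm with v = 0.87 cm/s gives dt ~ 1.1e-4 s
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.086, dr_cm=1e-4)
        dt = stability_timestep(grid, self._homog_coeffs(grid), safety=1.0)
        assert dt == pytest.approx(1e-4 / 0.87, rel=1e-6)
        assert dt == pytest.approx(1.1e-4, rel=0.05)

    def test_pure_diffusion_scaling(self):
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.3, dr_cm=0.002, dtheta=np.pi / 2)
        c = self._homog_coeffs(grid, d=1e-4, d_t=0.0, v=0.0)
        dt = stability_timestep(grid, c, safety=1.0)
        assert dt == pytest.approx(grid.dr_cm**2 / (2 * 1e-4), rel=1e-9)

    def test_halving_dr_halves_advective_bound(self):
        g1 = PolarGrid(r_min_cm=0.084, r_max_cm=0.3, dr_cm=0.002)
        g2 = PolarGrid(r_min_cm=0.084, r_max_cm=0.3, dr_cm=0.001)
        d1 = stability_timestep(g1, self._homog_coeffs(g1))
        d2 = stability_timestep(g2, self._homog_coeffs(g2))
        assert d2 == pytest.approx(d1 / 2, rel=1e-6)

    def test_solver_refuses_large_dt(self):
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.2)
        with pytest.raises(ValueError, match="CFL"):
            solve(None, None, None, grid, duration_s=1.0, dt_s=1.0)


class TestSolve:
    def test_zero_source_zero_field(self):
        p = TransportParameters(c_source_nmol=0.0)
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.2)
        cf = solve(None, None, p, grid, duration_s=0.5, steady_tol=None)
        assert not cf.c_nmol.any()
        assert penetration_depth(cf) == 0.0

    def test_steady_profile_matches_closed_form(self):
        """Quench off, homogeneous: C(r) = Cs (rb^(b+1)-r^(b+1))/(rb^(b+1)-ra^(b+1)),
        b = U r_cath / D, the exact steady advection-dispersion annulus profile."""
        p = TransportParameters(u_cm_s=0.05, a_long_cm2_s=1e-3,
                                a_trans_cm2_s=1e-3, c_pai_um=0.0)
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.2, dr_cm=0.001, dtheta=np.pi / 2)
        cf = solve(None, None, p, grid, duration_s=60.0, steady_tol=1e-7)
        r = grid.r_cm
        b = p.u_cm_s * p.catheter_radius_cm / p.a_long_cm2_s
        exact = p.c_source_nmol * (0.2 ** (b + 1) - r ** (b + 1)) \
            / (0.2 ** (b + 1) - 0.084 ** (b + 1))
        err = np.max(np.abs(cf.c_nmol[:, 0] - exact)) / p.c_source_nmol
        assert err < 0.02

    def test_discrete_mass_balance_without_quench(self):
        p = TransportParameters(c_pai_um=0.0)
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.5)
        cf = solve(None, None, p, grid, duration_s=0.5, steady_tol=None)
        net_in = cf.cumulative_inflow - cf.cumulative_outflow - cf.cumulative_quenched
        assert cf.cumulative_quenched == 0.0
        assert abs(cf.mass() - net_in) <= 0.01 * cf.cumulative_inflow

    def test_bounded_and_nonnegative_with_quench(self):
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.5)
        cf = solve(None, None, None, grid, duration_s=5.0)
        assert cf.c_nmol.min() >= 0.0
        assert cf.c_nmol.max() <= DEFAULTS.c_source_nmol * (1 + 1e-12)

    def test_steady_profile_radially_non_increasing(self):
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.5)
        cf = solve(None, None, None, grid, duration_s=10.0)
        prof = cf.c_nmol.max(axis=1)
        assert np.all(np.diff(prof) <= 1e-9 * DEFAULTS.c_source_nmol)

    def test_quenched_field_reaches_steady_within_10s(self):
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.8)
        cf = solve(None, None, None, grid, duration_s=20.0)
        assert cf.steady_time_s is not None and cf.steady_time_s <= 10.0

    def test_penetration_depth_limited_to_2mm(self):
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.8)
        cf = solve(None, None, None, grid, duration_s=20.0)
        assert 0.0 < penetration_depth(cf) <= 2.0

    def test_grid_convergence_of_penetration_depth(self):
        pens = []
        for dr in (0.002, 0.001):
            grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.8, dr_cm=dr)
            pens.append(penetration_depth(solve(None, None, None, grid,
                                                duration_s=20.0)))
        assert abs(pens[1] - pens[0]) / pens[0] < 0.05

    def test_uniform_field_full_penetration(self):
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.2)
        cf = ConcentrationField(
            c_nmol=np.full((grid.nr + 2, grid.ntheta), DEFAULTS.c_source_nmol),
            t_s=0.0, grid=grid, params=DEFAULTS)
        assert penetration_depth(cf) == pytest.approx((0.2 - 0.084) * 10.0)

    def test_ablated_channel_extends_drug_delivery(self):
        """A liquefied wedge lets rt-PA reach deeper than intact thrombus."""
        sec = uniform_section(Label.RBC, n=100, pixel_size_um=100.0)  # 10 mm
        cy, cx = sec.centroid_px()
        yy, xx = np.mgrid[0:100, 0:100]
        mask = (np.abs(xx - cx) * 0.1 <= 0.35) & (np.abs(yy - cy) * 0.1 <= 2.0)
        grid = PolarGrid(r_min_cm=0.084, r_max_cm=0.45)
        cf0 = solve(sec, None, grid=grid, duration_s=20.0)
        cf1 = solve(sec, mask, grid=grid, duration_s=20.0)
        assert penetration_depth(cf1) > penetration_depth(cf0)
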