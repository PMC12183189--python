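"""Kinematics: rates, logistic fitting, REL, expansion profiles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from rootkin.kinematics import (
    AxialLengthCohort,
    CellLengthProfile,
    DiameterProfile,
    ExpansionProfileSet,
    KinematicsError,
    VelocityProfile,
    area_profile,
    cell_flux,
    elongation_rate,
    fit_logistic,
    growth_zone_extent,
    logistic_velocity,
    mature_cell_length,
    radtan_rate,
    region_summaries,
    rel_profile,
    velocity_profile,
    volumetric_profiles,
)
from rootkin.synthetic import make_cell_profile, make_diameter_profile


def _cohort(m15, m17, n=4):
    return AxialLengthCohort(
        plant=[f"p{i}" for i in range(2 * n)],
        day=[15] * n + [17] * n,
        treatment=["WW"] * 2 * n,
        length_cm=[m15] * n + [m17] * n,
    )


class TestElongationRate:
    @pytest.mark.parametrize("m15, m17, cm_day, mm_h", [
        (10.00, 16.16, 3.08, 1.28333),   # well-watered worked example
        (10.00, 16.26, 3.13, 1.30417),   # water-deficit worked example
        (10.00, 10.00, 0.0, 0.0),
    ])
    def test_two_day_mean_difference(self, m15, m17, cm_day, mm_h):
        rate_cm, rate_mm = elongation_rate(_cohort(m15, m17))
        assert rate_cm == pytest.approx(cm_day, abs=1e-9)
        assert rate_mm == pytest.approx(mm_h, abs=1e-5)

    def test_missing_day_is_an_error(self):
        cohort = AxialLengthCohort(["a"], [15], ["WW"], [10.0])
        with pytest.raises(KinematicsError):
            elongation_rate(cohort)

    def test_negative_rate_warns_but_returns(self):
        with pytest.warns(UserWarning):
            rate_cm, _ = elongation_rate(_cohort(16.0, 10.0))
        assert rate_cm == pytest.approx(-3.0)


class TestMatureCellLengthAndFlux:
    def test_constant_profile_mean(self):
        x = np.linspace(0, 12, 50)
        prof = CellLengthProfile(x, np.full(50, 150.0))
        assert mature_cell_length(prof) == 150.0

    def test_mean_of_window_points(self):
        prof = CellLengthProfile([10.0, 11.0, 12.0], [150.0, 160.0, 170.0])
        assert mature_cell_length(prof) == pytest.approx(160.0)

    def test_empty_window_is_an_error(self):
        prof = CellLengthProfile([1.0, 2.0], [100.0, 120.0])
        with pytest.raises(KinematicsError):
            mature_cell_length(prof)

    @pytest.mark.parametrize("rate, l_final, flux", [
        (1.28333, 156.9, 8.18),  # printed well-watered flux
        (1.30417, 169.8, 7.68),  # printed water-deficit flux
        (0.0, 156.9, 0.0),
    ])
    def test_flux_worked_examples_to_three_significant_figures(self, rate, l_final, flux):
        assert cell_flux(rate, l_final) == pytest.approx(flux, abs=0.005)

    def test_nonpositive_final_length_rejected(self):
        with pytest.raises(KinematicsError):
            cell_flux(1.0, 0.0)


class TestVelocityProfile:
    def test_mature_cells_move_at_overall_rate(self):
        x = np.linspace(0, 12, 60)
        prof = CellLengthProfile(x, np.full(60, 160.0))
        vel = velocity_profile(prof, 1.2)
        np.testing.assert_allclose(vel.velocity_mm_h, 1.2)

    def test_half_length_cells_move_at_half_rate(self):
        x = np.linspace(0, 12, 60)
        lengths = np.where(x < 9, 80.0, 160.0)
        vel = velocity_profile(CellLengthProfile(x, lengths), 1.2)
        np.testing.assert_allclose(vel.velocity_mm_h[x < 9], 0.6)

    def test_flux_constancy_along_noiseless_profile(self, tiny_scenario, grid):
        prof = make_cell_profile(tiny_scenario, grid)
        vel = velocity_profile(prof, tiny_scenario.elong_rate_mm_per_h)
        ratio = vel.velocity_mm_h / (prof.cell_length_um / 1000.0)
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)


class TestLogisticFit:
    TRUTH = (0.05, 1.283, 3.0, 4.0)

    def test_exact_model_recovered_to_high_precision(self):
        x = np.linspace(0.25, 12, 25)
        vel = VelocityProfile(x, logistic_velocity(x, *self.TRUTH))
        fit = fit_logistic(vel)
        for got, want in zip((fit.a1, fit.a2, fit.x0, fit.p), self.TRUTH):
            assert got == pytest.approx(want, rel=1e-6)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_two_percent_noise_keeps_r_above_098(self):
        x = np.linspace(0.25, 12, 25)
        rng = np.random.default_rng(3)
        y = logistic_velocity(x, *self.TRUTH) * (1 + 0.02 * rng.standard_normal(25))
        fit = fit_logistic(VelocityProfile(x, y))
        assert fit.r >= 0.98

    def test_matches_grid_search_oracle(self):
        """Coarse 4-D grid search plus Nelder-Mead polish on the SSE must
        land on the same optimum as the bounded least-squares fit."""
        x = np.linspace(0.25, 12, 25)
        rng = np.random.default_rng(9)
        y = logistic_velocity(x, *self.TRUTH) * (1 + 0.03 * rng.standard_normal(25))

        def sse(theta):
            a1, a2, x0, p = theta
            if not (0 <= a1 < a2 and x0 > 0 and p > 0):
                return np.inf
            return float(np.sum((y - logistic_velocity(x, a1, a2, x0, p)) ** 2))

        best, best_val = None, np.inf
        for a1 in np.linspace(0.0, 0.2, 5):
            for a2 in np.linspace(1.0, 1.6, 7):
                for x0 in np.linspace(1.5, 5.0, 8):
                    for p in np.linspace(2.0, 7.0, 11):
                        v = sse((a1, a2, x0, p))
                        if v < best_val:
                            best, best_val = (a1, a2, x0, p), v
        polished = minimize(sse, best, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        fit = fit_logistic(VelocityProfile(x, y))
        assert sse((fit.a1, fit.a2, fit.x0, fit.p)) == pytest.approx(polished.fun, rel=1e-6)
        for got, want in zip((fit.a1, fit.a2, fit.x0, fit.p), polished.x):
            assert got == pytest.approx(want, rel=1e-3, abs=1e-4)

    def test_parameter_recovery_over_seeded_noisy_replicates(self):
        """x0 and p within 10%, a2 within 3%, across 50 noisy profiles
        sampled at the package's standard 0.1 mm density."""
        x = np.linspace(0.25, 12, 121)
        clean = logistic_velocity(x, *self.TRUTH)
        rng = np.random.default_rng(17)
        for _ in range(50):
            noise = rng.uniform(0.02, 0.05)
            fit = fit_logistic(VelocityProfile(x, clean * (1 + noise * rng.standard_normal(x.size))))
            assert fit.x0 == pytest.approx(self.TRUTH[2], rel=0.10)
            assert fit.p == pytest.approx(self.TRUTH[3], rel=0.10)
            assert fit.a2 == pytest.approx(self.TRUTH[1], rel=0.03)

    def test_flat_data_rejected(self):
        x = np.linspace(0, 12, 20)
        with pytest.raises(KinematicsError):
            fit_logistic(VelocityProfile(x, np.full(20, 1.0)))

    def test_too_few_points_rejected(self):
        with pytest.raises(KinematicsError):
            fit_logistic(VelocityProfile([1.0, 2.0, 3.0, 4.0], [0.1, 0.5, 1.0, 1.2]))


class TestRelProfile:
    def _fit(self, a1=0.0, a2=1.28, x0=3.0, p=4.0):
        from rootkin.kinematics import LogisticFit
        return LogisticFit(a1=a1, a2=a2, x0=x0, p=p, r=1.0)

    def test_closed_form_at_midpoint(self):
        # at x = x0 the derivative is (a2 - a1) p / (4 x0)
        fit = self._fit()
        assert rel_profile(fit, [3.0])[0] == pytest.approx(1.28 * 4 / 12, abs=1e-9)
        assert rel_profile(fit, [3.0])[0] == pytest.approx(0.42667, abs=1e-5)

    def test_vanishes_far_from_tip(self):
        assert rel_profile(self._fit(), [1e6])[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_differences_of_fitted_curve(self):
        fit = self._fit(a1=0.05, a2=1.283, x0=3.0, p=4.0)
        x = np.linspace(0.1, 12, 200)
        h = 1e-6
        numeric = (fit.velocity(x + h) - fit.velocity(x - h)) / (2 * h)
        np.testing.assert_allclose(rel_profile(fit, x), numeric, atol=1e-6)

    def test_negative_position_rejected(self):
        with pytest.raises(KinematicsError):
            rel_profile(self._fit(), [-1.0])


class TestGrowthZone:
    def test_constant_rel_has_no_deceleration(self, grid):
        with pytest.raises(KinematicsError):
            growth_zone_extent(grid, np.full(grid.size, 0.2))

    def test_extent_and_peak_of_calibrated_scenario(self, tiny_scenario, grid):
        """The packaged well-watered calibration, measured end to end
        (noiseless profile -> velocity -> fit -> REL), places the REL peak
        at ~2.5 mm and elongation cessation at ~10 mm."""
        prof = make_cell_profile(tiny_scenario, grid)
        vel = velocity_profile(prof, tiny_scenario.elong_rate_mm_per_h)
        rel = rel_profile(fit_logistic(vel), grid)
        extent, peak_x, peak = growth_zone_extent(grid, rel)
        assert peak_x == pytest.approx(2.5, abs=0.1)
        assert extent == pytest.approx(10.0, abs=0.15)


class TestExpansion:
    def test_area_of_unit_and_double_diameter(self, grid):
        d1 = DiameterProfile(grid, np.full(grid.size, 1.0))
        d2 = DiameterProfile(grid, np.full(grid.size, 2.0))
        np.testing.assert_allclose(area_profile(d1), np.pi / 4)
        np.testing.assert_allclose(area_profile(d2), 4 * area_profile(d1))

    def test_constant_area_has_no_radial_expansion(self, grid):
        vel = VelocityProfile(grid, np.linspace(0.1, 1.2, grid.size))
        r = radtan_rate(vel, np.full(grid.size, 0.8))
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_exponential_area_gives_k_times_velocity(self, grid):
        k = 0.07
        vel = VelocityProfile(grid, np.linspace(0.1, 1.2, grid.size))
        r = radtan_rate(vel, 0.5 * np.exp(k * grid), smooth=1)
        np.testing.assert_allclose(r, k * vel.velocity_mm_h, rtol=1e-9)

    def test_polynomial_area_matches_symbolic_derivative(self):
        import sympy as sp
        xs = sp.symbols("x")
        A_expr = 0.6 + 0.08 * xs + 0.01 * xs ** 2
        dlnA = sp.lambdify(xs, sp.diff(sp.log(A_expr), xs), "numpy")
        x = np.linspace(0.0, 12.0, 1201)  # fine grid for central differences
        A = 0.6 + 0.08 * x + 0.01 * x ** 2
        v = np.linspace(0.1, 1.2, x.size)
        r = radtan_rate(VelocityProfile(x, v), A, smooth=1)
        interior = slice(2, -2)
        np.testing.assert_allclose(r[interior], (v * dlnA(x))[interior], rtol=1e-4)

    def test_mismatched_grids_rejected(self, grid):
        vel = VelocityProfile(grid, np.linspace(0.1, 1.2, grid.size))
        with pytest.raises(KinematicsError):
            radtan_rate(vel, np.ones(grid.size - 1))

    def test_volumetric_identities_enforced(self, grid):
        rel = np.linspace(0.3, 0.0, grid.size)
        radtan = np.full(grid.size, 0.02)
        area = np.full(grid.size, 0.8)
        prof = volumetric_profiles(grid, rel, radtan, area)
        np.testing.assert_allclose(prof.relvol, rel + radtan)
        np.testing.assert_allclose(prof.volrate, (rel + radtan) * area)
        with pytest.raises(KinematicsError):
            ExpansionProfileSet(grid, rel, radtan, rel, area, prof.volrate)

    def test_zero_radtan_reduces_to_rel(self, grid):
        rel = np.linspace(0.3, 0.0, grid.size)
        prof = volumetric_profiles(grid, rel, np.zeros(grid.size), np.ones(grid.size))
        np.testing.assert_allclose(prof.relvol, rel)

    def test_volrate_integral_matches_direct_growth_rate(self, tiny_scenario, grid):
        """Conservation: the integral of the volumetric expansion rate over
        the growth zone equals the rate of volume production computed
        directly from the truth, d/dt \\int A dx = \\int (rel+radtan) A dx."""
        from rootkin.kinematics import LogisticFit
        t = tiny_scenario.logistic_truth
        fit = LogisticFit(a1=t.a1, a2=t.a2, x0=t.x0, p=t.p, r=1.0)
        x = np.round(np.arange(0.0, 10.0 + 1e-9, 0.01), 10)
        rel = rel_profile(fit, x)
        vel = VelocityProfile(x, fit.velocity(x))
        diam = make_diameter_profile(tiny_scenario, x)
        area = area_profile(diam)
        radtan = radtan_rate(vel, area, smooth=1)
        prof = volumetric_profiles(x, rel, radtan, area)
        got = np.trapezoid(prof.volrate, x)
        # oracle: d(A v)/dx integrated = [A v] difference (product rule:
        # (rel + radtan) A = v dA/dx + A dv/dx = d(Av)/dx)
        want = area[-1] * vel.velocity_mm_h[-1] - area[0] * vel.velocity_mm_h[0]
        assert got == pytest.approx(want, rel=1e-4)


class TestRegionSummaries:
    def test_constant_profile_has_constant_region_means(self, grid):
        out = region_summaries(grid, {"c": np.full(grid.size, 2.5)})
        for region in ("R1", "R2", "R3"):
            assert out[region]["c"]["mean"] == pytest.approx(2.5)

    def test_region_integrals_are_additive(self, grid):
        y = np.sin(grid / 3.0) + 1.2
        out = region_summaries(grid, {"y": y})
        total = sum(out[r]["y"]["integral"] for r in ("R1", "R2", "R3"))
        mask = grid <= 9.5
        assert total == pytest.approx(np.trapezoid(y[mask], grid[mask]), rel=1e-9)

    def test_piecewise_linear_profile_matches_hand_trapezoid(self):
        x = np.array([0.0, 3.0, 6.0, 9.5])
        y = np.array([0.0, 6.0, 6.0, 0.0])
        out = region_summaries(x, {"y": y})
        assert out["R1"]["y"]["integral"] == pytest.approx(9.0)    # triangle 0..3
        assert out["R2"]["y"]["integral"] == pytest.approx(18.0)   # rectangle 3..6
        assert out["R3"]["y"]["integral"] == pytest.approx(10.5)   # trapezoid 6..9.5

    def test_region_outside_grid_rejected(self):
        with pytest.raises(KinematicsError):
            region_summaries(np.linspace(0, 5, 10), {"y": np.ones(10)})
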