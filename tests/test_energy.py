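import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccpkit.energy import (KBT_JOULES, ModelParams, StiffnessInput,
                           boundary_optimum_radius, clath_bend_energy,
                           clath_poly_energy, critical_tension,
                           estimate_a_from_Rmean, kappa_from_stiffness,
                           landscape, memb_bend_energy, memb_tension_energy,
                           minimize_energy, per_arm_bend_energy,
                           relax_at_constant_area, total_energy)

caps = st.tuples(st.floats(5.0, 500.0), st.floats(1e-3, 2.0)).map(
    lambda t: (2 * math.pi * t[0] * t[0] * t[1], t[0]))  # (A, R) valid pairs


class TestModelParams:
    def test_defaults_match_reference_values(self, params):
        assert params.kappa_memb == 15.0
        assert math.isinf(params.R_memb)
        assert (params.gamma, params.kappa_clath, params.R_clath) == (0.01, 373.0, 40.0)
        assert (params.a, params.A_clath) == (30.0, 218.0)

    @pytest.mark.parametrize("kw", [
        {"kappa_memb": -1}, {"gamma": 0}, {"R_clath": -5}, {"A_clath": 0}, {"R_memb": -1},
    ])
    def test_rejects_nonphysical(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)


class TestMembraneBending:
    def test_closed_vesicle_is_size_independent_8pi_kappa(self, params):
        for R in (20.0, 55.0, 300.0):
            A = 4 * math.pi * R**2
            assert memb_bend_energy(A, R, params) == pytest.approx(
                8 * math.pi * 15.0, rel=1e-12)

    def test_hemisphere(self, params):
        R = 80.0
        A = 2 * math.pi * R**2
        assert memb_bend_energy(A, R, params) == pytest.approx(4 * math.pi * 15.0, rel=1e-12)

    def test_flat_lattice_costs_nothing(self, params):
        assert memb_bend_energy(1e4, 1e9, params) == pytest.approx(0.0, abs=1e-4)

    @given(caps, st.floats(0.1, 1.9))
    @settings(max_examples=200, deadline=None)
    def test_depends_only_on_aspect_ratio(self, cap, scale):
        """Caps sharing h/R share E_memb_bend (equal-energy contours)."""
        p = ModelParams()
        A, R = cap
        h = A / (2 * math.pi * R)
        R2 = R * scale
        A2 = 2 * math.pi * R2 * (h * scale)  # same h/R
        e1 = memb_bend_energy(A, R, p)
        e2 = memb_bend_energy(A2, R2, p)
        assert e2 == pytest.approx(e1, rel=1e-9)

    def test_finite_intrinsic_curvature_shifts_minimum(self):
        p = ModelParams(R_memb=100.0)
        A = 1000.0
        assert memb_bend_energy(A, 100.0, p) == pytest.approx(0.0, abs=1e-12)
        assert memb_bend_energy(A, 50.0, p) > 0


class TestMembraneTension:
    def test_zero_height_costs_nothing(self, params):
        assert memb_tension_energy(0.0, 50.0, params) == 0.0

    def test_closed_sphere(self, params):
        A = 4 * math.pi * 55.0**2
        assert memb_tension_energy(A, 55.0, params) == pytest.approx(
            0.01 * A, rel=1e-12)

    @given(caps)
    @settings(max_examples=200, deadline=None)
    def test_equals_gamma_pi_h_squared(self, cap):
        p = ModelParams()
        A, R = cap
        h = A / (2 * math.pi * R)
        assert memb_tension_energy(A, R, p) == pytest.approx(
            p.gamma * math.pi * h**2, rel=1e-9)


class TestClathrinBending:
    def test_zero_only_at_intrinsic_curvature(self, params):
        assert clath_bend_energy(1000.0, 40.0, params) == 0.0
        assert clath_bend_energy(1000.0, 39.0, params) > 0
        assert clath_bend_energy(1000.0, 41.0, params) > 0

    def test_frozen_value(self, params):
        # A=1000, R=20: 1000 * 186.5 * (0.1 - 0.05)^2 = 466.25
        assert clath_bend_energy(1000.0, 20.0, params) == pytest.approx(466.25, rel=1e-12)

    def test_flat_limit_density(self, params):
        # per unit area: kappa_clath/2 * (2/R_clath)^2 = 0.46625 kBT/nm^2
        e = clath_bend_energy(1.0, 1e12, params)
        assert e == pytest.approx(0.46625, rel=1e-6)

    def test_strictly_increasing_in_curvature_deviation(self, params):
        devs = [clath_bend_energy(1000.0, R, params) for R in (40.0, 50.0, 80.0, 1e6)]
        assert devs == sorted(devs)


class TestPolymerization:
    def test_single_interaction(self, params):
        assert clath_poly_energy(218.0, params) == pytest.approx(-30.0)

    def test_empty_lattice(self, params):
        assert clath_poly_energy(0.0, params) == 0.0

    def test_open_arm_correction(self, params):
        assert clath_poly_energy(218.0, params, n_open_arms=1) == pytest.approx(0.0)

    def test_negative_area_rejected(self, params):
        with pytest.raises(ValueError):
            clath_poly_energy(-1.0, params)


class TestTotalEnergy:
    @given(caps)
    @settings(max_examples=300, deadline=None)
    def test_total_is_exact_sum_of_terms(self, cap):
        p = ModelParams()
        A, R = cap
        bd = total_energy(A, R, p)
        s = bd.E_memb_bend + bd.E_memb_tension + bd.E_clath_bend + bd.E_clath_poly
        assert bd.E_total == s  # bit-for-bit

    def test_terms_match_individual_ops(self, params):
        A, R = 5000.0, 70.0
        bd = total_energy(A, R, params)
        assert bd.E_memb_bend == memb_bend_energy(A, R, params)
        assert bd.E_memb_tension == memb_tension_energy(A, R, params)
        assert bd.E_clath_bend == clath_bend_energy(A, R, params)
        assert bd.E_clath_poly == clath_poly_energy(A, params)

    def test_at_intrinsic_curvature_no_coat_bending(self, params):
        bd = total_energy(218.0, 40.0, params)
        assert bd.E_clath_bend == 0.0
        assert bd.E_total == pytest.approx(
            bd.E_memb_bend + bd.E_memb_tension - 30.0)

    def test_boundary_optimum_value(self, params):
        """Closed form at R = 55.07: ~ -3155 kBT."""
        R = boundary_optimum_radius(params)
        bd = total_energy(4 * math.pi * R**2, R, params)
        assert bd.E_total == pytest.approx(-3155.0, abs=5.0)

    def test_invalid_cap_rejected(self, params):
        with pytest.raises(ValueError):
            total_energy(4 * math.pi * 100.0 * 1.01 * 100.0, 100.0, params)


class TestPerArmEnergetics:
    def test_zero_at_intrinsic_radius(self, params):
        assert per_arm_bend_energy(40.0, params) == 0.0

    def test_flat_lattice_stores_tens_of_kBT_per_arm(self, params):
        assert per_arm_bend_energy(math.inf, params) == pytest.approx(101.6425, rel=1e-9)

    def test_balance_estimate_at_mean_radius(self, params):
        # 218 * 186.5 * (2/92 - 2/40)^2
        expect = 218 * 186.5 * (2 / 92 - 2 / 40) ** 2
        assert estimate_a_from_Rmean(92.0, params) == pytest.approx(expect, rel=1e-12)
        assert estimate_a_from_Rmean(92.0, params) == pytest.approx(30.0, abs=5.0)

    def test_estimate_at_60nm(self, params):
        assert estimate_a_from_Rmean(60.0, params) == pytest.approx(
            218 * 186.5 * (2 / 60 - 2 / 40) ** 2, rel=1e-12)


class TestLandscape:
    def test_mask_is_sphere_constraint(self, params):
        grid = landscape(params, resolution=(60, 60))
        AA, RR = np.meshgrid(grid.A, grid.R, indexing="ij")
        np.testing.assert_array_equal(grid.valid, AA <= 4 * math.pi * RR**2)
        assert np.isfinite(grid.E[grid.valid]).all()
        assert np.isnan(grid.E[~grid.valid]).all()

    def test_min_cell_near_boundary_optimum(self, params):
        grid = landscape(params, resolution=(300, 300))
        A, R, E = grid.min_cell()
        assert R == pytest.approx(55.0, rel=0.05)
        assert A == pytest.approx(4 * math.pi * R**2, rel=0.05)

    def test_high_tension_minimum_moves_interior(self, params):
        grid = landscape(params.replace(gamma=0.1), resolution=(300, 300))
        A, R, E = grid.min_cell()
        assert A < 4 * math.pi * R**2 * 0.9

    def test_empty_range_rejected(self, params):
        with pytest.raises(ValueError):
            landscape(params, A_range=(100.0, 100.0))


class TestMinimizeEnergy:
    def test_default_optimum_is_closed_sphere_near_55nm(self, params):
        res = minimize_energy(params)
        assert res.branch == "boundary"
        assert res.R == pytest.approx(55.07, abs=0.5)
        assert res.A == pytest.approx(4 * math.pi * res.R**2, rel=1e-6)

    def test_grid_search_agrees_with_closed_form(self, params):
        res = minimize_energy(params)
        assert abs(res.R - boundary_optimum_radius(params)) < 0.5

    def test_no_polymerization_drive_gives_empty_reference(self, params):
        res = minimize_energy(params.replace(a=1e-12))
        assert res.branch == "empty"
        assert res.E == 0.0

    def test_unbounded_parameters_reported_not_crashed(self, params):
        res = minimize_energy(params.replace(a=200.0))
        assert res.branch == "unbounded"
        assert res.E == -math.inf

    def test_minimizer_respects_constraint(self, params):
        for g in (0.002, 0.02, 0.08, 0.15):
            res = minimize_energy(params.replace(gamma=g))
            assert res.A <= 4 * math.pi * res.R**2 * (1 + 1e-6)


class TestCriticalTension:
    def test_coarse_grid_value(self, params):
        res = critical_tension(params, np.arange(0.005, 0.1501, 0.005))
        assert res.gamma_c == pytest.approx(0.06, abs=0.005)
        assert res.bracketed

    def test_fine_grid_brackets_paper_range(self, params):
        res = critical_tension(params, np.arange(0.04, 0.0801, 0.001))
        assert 0.05 < res.gamma_c < 0.065

    def test_branches_partition_cleanly(self, params):
        res = critical_tension(params, np.arange(0.02, 0.1201, 0.01))
        below = [b for g, b in zip(res.gammas, res.branches) if g < res.gamma_c]
        above = [b for g, b in zip(res.gammas, res.branches) if g >= res.gamma_c]
        assert all(b == "boundary" for b in below)
        assert all(b == "interior" for b in above)

    def test_low_tension_always_boundary(self, params):
        res = minimize_energy(params.replace(gamma=0.001))
        assert res.branch == "boundary"

    def test_not_bracketed_reported(self, params):
        res = critical_tension(params, np.arange(0.001, 0.0101, 0.001))
        assert not res.bracketed and math.isnan(res.gamma_c)


class TestConstantAreaRelaxation:
    @pytest.mark.parametrize("A,expected", [
        (1e4, 42.0), (3e4, math.sqrt(3e4 / (4 * math.pi))),
    ])
    def test_closed_form_and_clamp(self, params, A, expected):
        assert relax_at_constant_area(A, params) == pytest.approx(expected, abs=0.1)

    def test_small_area_limit(self, params):
        # denominator -> 4(kappa_m + kappa_c), so R -> 1552/37.3 = 41.6 nm
        assert relax_at_constant_area(1e-9, params) == pytest.approx(41.61, abs=0.05)

    def test_monotone_nondecreasing_in_area(self, params):
        areas = np.logspace(1, 5, 40)
        radii = [relax_at_constant_area(A, params) for A in areas]
        assert all(b >= a - 1e-12 for a, b in zip(radii, radii[1:]))

    @given(st.floats(500.0, 5e4), st.floats(0.02, 1.9))
    @settings(max_examples=100, deadline=None)
    def test_relaxation_never_increases_energy(self, A, frac):
        """E_total at the relaxed radius <= E_total at any feasible start."""
        p = ModelParams()
        R_min = math.sqrt(A / (4 * math.pi))
        R_start = R_min / min(frac, 1.0) if frac < 1 else R_min * frac * 10
        R_relaxed = relax_at_constant_area(A, p)
        e_start = total_energy(A, max(R_start, R_min), p).E_total
        e_rel = total_energy(A, R_relaxed, p).E_total
        assert e_rel <= e_start + 1e-6


class TestStiffnessConversion:
    def test_reference_calibration(self):
        """k = 0.08 N/m on a 40-nm cage maps to ~373 kBT."""
        assert kappa_from_stiffness(StiffnessInput(k=0.08)) == pytest.approx(373.0, rel=0.01)

    def test_zero_stiffness(self):
        assert kappa_from_stiffness(StiffnessInput(k=0.0)) == 0.0

    def test_linear_in_stiffness(self):
        k1 = kappa_from_stiffness(StiffnessInput(k=0.05))
        k2 = kappa_from_stiffness(StiffnessInput(k=0.10))
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_rejects_bad_poisson_ratio(self):
        with pytest.raises(ValueError):
            StiffnessInput(k=0.08, nu=0.7)
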