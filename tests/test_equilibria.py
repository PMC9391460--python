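"""Coupled tetramer-dimer-ligand equilibrium solver."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect, fsolve

from oligobind.equilibria import (CoupledEquilibrium, EquilibriumParams,
                                  SolverError, UncertainValue,
                                  klig_from_ec50, model_ec50,
                                  propagate_klig_error, solve_species)

PHI = (math.sqrt(5.0) - 1.0) / 2.0  # golden-ratio root of x^2 + x - 1 = 0


def dimer_by_bisection(k_tet, p_total):
    """Independent oracle: bisect 2d + 4d^2/k_tet = p_total for d."""
    return bisect(lambda d: 2 * d + 4 * d * d / k_tet - p_total,
                  0.0, p_total, xtol=1e-15)


class TestSolveSpecies:
    def test_dimer_fraction_at_mst_conditions(self):
        # oracle: positive root of 2d + 2.5 d^2 = 0.1
        d = dimer_by_bisection(1.6, 0.1)
        model = CoupledEquilibrium(1.6)
        assert model.dimer_fraction(0.1) == pytest.approx(2 * d / 0.1, rel=1e-9)
        assert model.dimer_fraction(0.1) == pytest.approx(0.94427191, abs=1e-6)

    def test_dimer_fraction_exceeds_94_percent(self):
        assert CoupledEquilibrium(1.6).dimer_fraction(0.1) >= 0.94

    def test_infinite_dilution_all_dimer(self):
        assert CoupledEquilibrium(1.6).dimer_fraction(1e-9) == pytest.approx(
            1.0, abs=1e-4)

    def test_tetramer_fraction_at_high_protein(self):
        # oracle: positive root of 2.5 d^2 + 2 d - 35 = 0
        d = (-2 + math.sqrt(4 + 350)) / 5
        s = CoupledEquilibrium(1.6).solve_species(35.0)
        assert s.tetramer_fraction == pytest.approx(1 - 2 * d / 35, rel=1e-9)
        assert s.tetramer_fraction == pytest.approx(0.808, abs=2e-3)

    def test_dissociation_limit_no_tetramer(self):
        s = CoupledEquilibrium(1e12).solve_species(10.0)
        assert s.conc_T == pytest.approx(0.0, abs=1e-10)
        assert s.dimer_fraction == pytest.approx(1.0, rel=1e-9)

    def test_matches_full_system_oracle(self, rng):
        """Independent 2-variable nonlinear solve of both balances."""
        for _ in range(100):
            k_tet = 10.0 ** rng.uniform(-2, 2)
            k_lig = 10.0 ** rng.uniform(-2, 2)
            p = 10.0 ** rng.uniform(-2, 2)
            lt = 10.0 ** rng.uniform(-2, 2)
            model = CoupledEquilibrium(k_tet, k_lig)
            s = model.solve_species(p, lt)

            def balances(v):
                d, l = np.abs(v)
                t = d * d / k_tet
                dl = d * l / k_lig
                dll = dl * l / k_lig
                return [4 * t + 2 * (d + dl + dll) - p,
                        l + dl + 2 * dll - lt]

            d0, l0 = fsolve(balances, [p / 4, lt / 2], full_output=False)
            assert s.conc_D == pytest.approx(abs(d0), rel=1e-6)
            assert s.conc_L_free == pytest.approx(abs(l0), rel=1e-6, abs=1e-12)

    def test_mass_conservation_random_draws(self, rng):
        model_cache = {}
        for _ in range(10_000):
            k_tet = 10.0 ** rng.uniform(-3, 3)
            k_lig = 10.0 ** rng.uniform(-3, 3)
            p = 10.0 ** rng.uniform(-3, 3)
            lt = rng.choice([0.0, 10.0 ** rng.uniform(-3, 3)])
            key = (k_tet, k_lig)
            model = model_cache.setdefault(key, CoupledEquilibrium(k_tet, k_lig))
            s = model.solve_species(p, lt)
            rp, rl = s.mass_balance_residuals()
            assert abs(rp) < 1e-9 and abs(rl) < 1e-9
            assert min(s.conc_T, s.conc_D, s.conc_DL, s.conc_DLL,
                       s.conc_L_free) >= 0
            if s.conc_T > 0:
                assert s.conc_D ** 2 / s.conc_T == pytest.approx(
                    k_tet, rel=1e-9)

    def test_invalid_inputs(self):
        m = CoupledEquilibrium(1.6, 3.75)
        with pytest.raises(ValueError):
            m.solve_species(-1.0, 0.0)
        with pytest.raises(ValueError):
            m.solve_species(1.0, -0.5)
        with pytest.raises(ValueError):
            EquilibriumParams(k_tet=-1.0, k_lig=1.0)


class TestBoundFraction:
    def test_limits(self):
        m = CoupledEquilibrium(1.6, 3.75)
        assert m.bound_fraction(0.1, 0.0) == 0.0
        assert m.bound_fraction(0.1, 1e7) == pytest.approx(1.0, abs=1e-5)

    def test_against_fixed_point_oracle(self):
        """Self-consistent iteration on free ligand, independent of brentq."""
        k_tet, k, p, lt = 1.6, 3.75, 0.1, 2.5
        l = lt
        for _ in range(200):
            beta = 1 + l / k + (l / k) ** 2
            d = (-2 * beta + math.sqrt(4 * beta ** 2 + 16 * p / k_tet)) / (
                8 / k_tet)
            l = lt - d * (l / k + 2 * (l / k) ** 2)
        dl, dll = d * l / k, d * (l / k) ** 2
        f_oracle = 2 * (dl + dll) / p
        f = CoupledEquilibrium(k_tet, k).bound_fraction(p, lt)
        assert f == pytest.approx(f_oracle, rel=1e-6)
        assert f == pytest.approx(0.52, abs=0.01)

    def test_monotone_in_ligand(self):
        m = CoupledEquilibrium(1.6, 3.75)
        grid = np.geomspace(1e-3, 1e3, 40)
        f = m.bound_fraction_curve(0.1, grid)
        assert np.all(np.diff(f) >= -1e-12)

    def test_dimer_tetramer_monotone_in_protein(self):
        m = CoupledEquilibrium(1.6)
        p_grid = np.geomspace(1e-3, 1e3, 30)
        dimer = [m.dimer_fraction(p) for p in p_grid]
        tet = [m.solve_species(p).tetramer_fraction for p in p_grid]
        assert np.all(np.diff(dimer) <= 1e-12)
        assert np.all(np.diff(tet) >= -1e-12)


class TestEc50:
    def test_forward_simulation_near_measured_midpoint(self):
        ec50 = CoupledEquilibrium(1.6, 3.75).ec50(0.1)
        assert abs(ec50 - 2.5) / 2.5 < 0.15

    def test_no_tetramer_limit_closed_form(self):
        # with k_tet -> inf the bound fraction is (x + x^2)/(1 + x + x^2) in
        # x = L_free/K, giving EC50 = phi*K + (phi + 2 phi^2)/4 * P once the
        # exactly-solved ligand depletion is added back
        k, p = 1.0, 0.1
        expected = PHI * k + (PHI + 2 * PHI ** 2) / 4.0 * p
        assert CoupledEquilibrium(1e14, k).ec50(p) == pytest.approx(
            expected, rel=1e-6)

    def test_depletion_free_limit_is_golden_ratio(self):
        assert CoupledEquilibrium(1e14, 1.0).ec50(1e-8) == pytest.approx(
            PHI, rel=1e-6)

    @pytest.mark.parametrize("k_lig", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_round_trip_with_inversion(self, k_lig):
        ec50 = model_ec50(EquilibriumParams(1.6, k_lig), 0.1)
        assert klig_from_ec50(ec50, 1.6, 0.1) == pytest.approx(
            k_lig, rel=1e-6)

    def test_intrinsic_statistical_site_model(self):
        # statistical factors shift the macroscopic steps but the EC50 stays
        # within a factor ~2 and the inversion still round-trips
        ec50 = model_ec50(
            EquilibriumParams(1.6, 3.75, "intrinsic_statistical"), 0.1)
        k = klig_from_ec50(ec50, 1.6, 0.1, "intrinsic_statistical")
        assert k == pytest.approx(3.75, rel=1e-6)

    def test_inversion_matches_published_constant(self):
        k = klig_from_ec50(2.5, 1.6, 0.1)
        assert abs(k - 3.75) / 3.75 < 0.15

    def test_no_root_raises(self):
        with pytest.raises(SolverError):
            klig_from_ec50(1e9, 1.6, 0.1)


class TestErrorPropagation:
    def test_zero_input_sd_gives_zero_sd(self):
        out = propagate_klig_error(UncertainValue(2.5, 0.0),
                                   UncertainValue(1.6, 0.0), 0.1,
                                   n_draws=1000, seed=11)
        assert out.sd == 0.0
        assert out.value == pytest.approx(klig_from_ec50(2.5, 1.6, 0.1),
                                          rel=1e-9)

    def test_deterministic_given_seed(self):
        a = propagate_klig_error(UncertainValue(2.5, 0.4),
                                 UncertainValue(1.6, 0.0), 0.1,
                                 n_draws=1000, seed=5)
        b = propagate_klig_error(UncertainValue(2.5, 0.4),
                                 UncertainValue(1.6, 0.0), 0.1,
                                 n_draws=1000, seed=5)
        assert a.value == b.value and a.sd == b.sd

    def test_sd_tracks_finite_difference_sensitivity(self):
        # with only the EC50 uncertain, sd ~ |dK/dEC50| * sd_EC50
        h = 1e-4
        slope = (klig_from_ec50(2.5 + h, 1.6, 0.1)
                 - klig_from_ec50(2.5 - h, 1.6, 0.1)) / (2 * h)
        out = propagate_klig_error(UncertainValue(2.5, 0.2),
                                   UncertainValue(1.6, 0.0), 0.1,
                                   n_draws=1500, seed=3)
        assert out.sd == pytest.approx(abs(slope) * 0.2, rel=0.15)

    def test_combined_uncertainty_matches_published_scale(self):
        out = propagate_klig_error(UncertainValue(2.5, 0.8),
                                   UncertainValue(1.6, 0.32), 0.1,
                                   n_draws=1500, seed=2)
        # the printed +/- on K_lig is 1.22; Monte Carlo should land nearby
        assert 0.9 < out.sd < 1.6
        assert out.ci_low <= out.value <= out.ci_high

    def test_n_draws_floor(self):
        with pytest.raises(ValueError):
            propagate_klig_error(UncertainValue(2.5, 0.8),
                                 UncertainValue(1.6, 0.32), 0.1,
                                 n_draws=10, seed=1)
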