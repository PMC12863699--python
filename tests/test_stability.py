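import numpy as np
import pytest

import fearsis as fs
from fearsis.model import jacobian
from fearsis.stability import (
    char_poly_coeffs,
    classify,
    discriminant,
    global_cep_condition,
    global_pdpf_condition,
    global_pfp_condition,
    invasion_eigenvalue,
    routh_hurwitz_fractional,
    stability_of_equilibria,
)

from conftest import draw_params


class TestClassify:
    def test_all_negative_real_is_las(self):
        rep = classify([-0.5, -0.2, -0.5], alpha=0.95)
        assert rep.classification == "LAS"
        assert rep.margin < 0
        assert rep.alpha_star is None

    def test_cone_crossing_in_alpha(self):
        # complex pair with positive real part: stable below the critical
        # order, unstable above it
        eigs = [-1.0, 0.3 + 1.0j, 0.3 - 1.0j]
        a_star = 2 / np.pi * np.arctan(1.0 / 0.3)
        assert classify(eigs, alpha=a_star - 0.05).classification == "LAS"
        rep = classify(eigs, alpha=min(1.0, a_star + 0.05))
        assert rep.classification == "saddle"  # real eig outside, pair inside
        assert rep.alpha_star == pytest.approx(a_star, abs=1e-12)

    def test_mixed_real_signs_is_saddle(self):
        for alpha in (0.6, 0.95, 1.0):
            assert classify([-1.0, 0.5, -2.0], alpha).classification == "saddle"

    def test_zero_eigenvalue_is_marginal(self):
        assert classify([0.0, -1.0, -2.0], alpha=0.9).classification == "marginal"

    def test_all_inside_cone_is_unstable(self):
        assert classify([1.0, 0.5 + 0.1j, 0.5 - 0.1j], 0.95).classification == "unstable"

    def test_alpha_star_only_for_hopf_structure(self, rng):
        # reported iff spectrum = {negative real, complex pair with Re > 0}
        for _ in range(100):
            real_part = rng.normal()
            theta = rng.normal()
            omega = rng.normal() * rng.integers(0, 2)  # half the draws purely real
            eigs = np.array(
                [real_part, theta + 1j * omega, theta - 1j * omega], dtype=complex
            )
            rep = classify(eigs, alpha=0.9)
            is_hopf_structure = real_part < 0 and abs(omega) > 1e-10 and theta > 0
            assert (rep.alpha_star is not None) == is_hopf_structure


class TestCharPoly:
    def test_identity_matrix(self):
        assert char_poly_coeffs(np.eye(3)) == pytest.approx((-3.0, 3.0, -1.0))

    def test_zero_matrix(self):
        assert char_poly_coeffs(np.zeros((3, 3))) == pytest.approx((0.0, 0.0, 0.0))

    def test_roots_match_eigenvalues(self, rng):
        for _ in range(50):
            J = rng.normal(size=(3, 3))
            c1, c2, c3 = char_poly_coeffs(J)
            roots = np.roots([1.0, c1, c2, c3])
            eigs = np.linalg.eigvals(J)
            assert np.max(np.abs(np.sort_complex(roots) - np.sort_complex(eigs))) < 1e-8


class TestRouthHurwitz:
    def test_all_negative_real_roots_clause_i(self):
        # (lambda+1)(lambda+2)(lambda+3): c = (6, 11, 6)
        rep = routh_hurwitz_fractional(6.0, 11.0, 6.0, alpha=0.95)
        assert rep.condition_met == "i" and rep.stable is True

    def test_positive_real_root_never_stable(self, rng):
        # c3 < 0 implies a positive real root
        for _ in range(20):
            c1, c2 = rng.normal(size=2)
            rep = routh_hurwitz_fractional(c1, c2, -abs(rng.normal()) - 0.1, alpha=0.9)
            assert rep.stable is not True

    def test_discriminant_identity(self, rng):
        for _ in range(20):
            c1, c2, c3 = rng.normal(size=3)
            expected = (
                18 * c1 * c2 * c3 + (c1 * c2) ** 2 - 4 * c3 * c1**3 - 4 * c2**3 - 27 * c3**2
            )
            assert discriminant(c1, c2, c3) == pytest.approx(expected, rel=1e-12)

    def test_no_decisive_contradiction_with_matignon_at_cep(self, table_params):
        # at beta=0.06, alpha=0.95 the interior point is Matignon-stable;
        # the Routh-Hurwitz clauses must not decisively contradict that
        p = table_params.replace(beta=0.06)
        J = jacobian(fs.cep(p), p)
        rep = routh_hurwitz_fractional(*char_poly_coeffs(J), p.alpha)
        mat = classify(np.linalg.eigvals(J), p.alpha)
        assert mat.classification == "LAS"
        assert rep.stable is not False


class TestStabilityOfEquilibria:
    def test_disease_free_stable_below_r0_one(self, table_params):
        reports = stability_of_equilibria(table_params.replace(beta=0.04))
        assert set(reports) == {"pdpf"}
        assert reports["pdpf"]["matignon"].classification == "LAS"

    def test_forward_exchange_of_stability(self, table_params):
        reports = stability_of_equilibria(table_params.replace(beta=0.052))
        assert reports["pdpf"]["matignon"].classification == "saddle"
        assert reports["pfp"]["matignon"].classification == "LAS"

    def test_interior_point_unstable_past_hopf(self, table_params):
        reports = stability_of_equilibria(table_params.replace(beta=0.6))
        rep = reports["cep"]["matignon"]
        assert rep.classification in ("unstable", "saddle")
        assert rep.margin > 0  # complex pair inside the cone

    def test_invasion_eigenvalue_matches_compound_form(self, table_params, rng):
        # n*I2/(1+a*I2) - d equals n*xi2 - d with
        # xi2 = (R0-1)*Lambda / (delta*R0 + (R0-1)*Lambda*a)
        for beta in (0.052, 0.06, 0.3):
            p = table_params.replace(beta=beta)
            R0 = fs.basic_reproduction_number(p)
            xi2 = (R0 - 1) * p.Lambda / (p.delta * R0 + (R0 - 1) * p.Lambda * p.a)
            assert invasion_eigenvalue(p) == pytest.approx(p.n * xi2 - p.d, rel=1e-12)

    def test_invasion_eigenvalue_absent_without_pfp(self, table_params):
        assert invasion_eigenvalue(table_params.replace(beta=0.04)) is None


class TestGlobalConditions:
    def test_pdpf_condition_arithmetic(self, table_params):
        # with beta=0.04, k=0: R0=0.8 but the upper bound 1-omega/(beta*S~)
        # is 0.375, so the sufficient condition does not hold
        rep = global_pdpf_condition(table_params.replace(beta=0.04, k=0.0))
        assert rep.holds is False
        assert rep.details["upper"] == pytest.approx(0.375)
        assert rep.details["R0"] == pytest.approx(0.8)

    def test_pdpf_condition_satisfiable_at_low_recovery(self, table_params):
        # a small recovery rate opens the window between the bounds:
        # beta=0.02, omega=0.01 gives R0 = 0.784 and upper bound 0.975
        p = table_params.replace(beta=0.02, k=0.0, omega=0.01)
        rep = global_pdpf_condition(p)
        assert rep.holds is True
        assert rep.details["upper"] == pytest.approx(0.975)

    def test_pdpf_condition_fails_above_threshold(self, table_params, rng):
        for _ in range(20):
            p = draw_params(rng)
            if fs.basic_reproduction_number(p) >= 1.0:
                assert global_pdpf_condition(p).holds is False

    def test_pdpf_condition_fails_at_high_fear(self, table_params):
        p = table_params.replace(beta=0.02, omega=0.01, k=50.0)
        assert global_pdpf_condition(p).holds is False

    def test_pfp_condition_arithmetic(self, table_params):
        # beta=0.052, k=0: bound = (1/4)(4*0.76923 + 4) = 1.76923 > d = 0.5
        rep = global_pfp_condition(table_params.replace(beta=0.052, k=0.0))
        assert rep.applicable and rep.holds is False
        assert rep.details["bound"] == pytest.approx(1.76923, abs=1e-5)

    def test_pfp_condition_limit_small_conversion(self, table_params):
        p = table_params.replace(beta=0.052, k=0.0, n=1e-6)
        rep = global_pfp_condition(p)
        assert rep.holds is True

    def test_pfp_condition_monotone_in_fear(self, table_params):
        bounds = [
            global_pfp_condition(table_params.replace(beta=0.052, k=k)).details["bound"]
            for k in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(b1 < b2 for b1, b2 in zip(bounds, bounds[1:]))

    def test_pfp_condition_not_applicable_without_pfp(self, table_params):
        rep = global_pfp_condition(table_params.replace(beta=0.04))
        assert not rep.applicable

    def test_cep_condition_arithmetic(self, table_params):
        # default scenario, gamma = Lambda/theta = 20: gamma1 = 15.5 > 0
        rep = global_cep_condition(table_params, gamma=20.0)
        assert rep.applicable and rep.holds is False
        assert rep.details["gamma1"] == pytest.approx(15.5)
        # gamma3 = (2n + (1+a)kappa - 2ad)/(2a) > 0 here as well
        kappa = fs.cep(table_params)[2]
        assert rep.details["gamma3"] == pytest.approx((2 + 2 * kappa - 1) / 2)

    def test_cep_condition_monotone_in_gamma(self, table_params):
        g1 = global_cep_condition(table_params, gamma=20.0).details["gamma1"]
        g1_bigger = global_cep_condition(table_params, gamma=40.0).details["gamma1"]
        assert g1_bigger > g1

    def test_pdpf_global_condition_implies_convergence(self, table_params, rng):
        # when the sufficient condition holds, trajectories from random
        # admissible starting points must reach the disease-free point
        p = table_params.replace(beta=0.02, k=0.0, omega=0.01)
        assert global_pdpf_condition(p).holds
        target = fs.pdpf(p)
        cfg = fs.SolverConfig(h=0.05, t_end=500.0)
        for _ in range(10):
            # admissible starts inside the attracting region (predator ~ O(1))
            y0 = np.array(
                [rng.uniform(0.05, 20.0), rng.uniform(0.05, 10.0), rng.uniform(0.05, 2.0)]
            )
            traj = fs.simulate(p, y0, cfg)
            assert np.max(np.abs(traj.final_state - target)) < 0.1
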