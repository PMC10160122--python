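"""Local (Routh-Hurwitz vs eigenvalues) and global (Lyapunov) stability."""

import numpy as np
import pytest

from patchfishery import (
    charpoly_coefficients,
    charpoly_comparison,
    eigenvalue_verdict,
    jacobian_at,
    lyapunov_bounds,
    lyapunov_value,
    routh_hurwitz_verdict,
    sample_random_parameters,
    simulate_ode,
    solve_interior_equilibrium,
    stability_verdict,
    vdot_box_census,
    vdot_diagnostic,
)
from patchfishery.stability import CharPolyCoefficients


class TestJacobianAtEquilibrium:
    def test_linear_coupling_entries_exact(self, figset_params, figset_eq):
        J = jacobian_at(figset_params, figset_eq)
        assert J[0, 1] == figset_params.sigma2
        assert J[1, 0] == figset_params.sigma1

    def test_predator_self_interaction_is_minus_alpha(self, figset_params, figset_eq):
        # at z* = gamma1*x*: d(z')/dz = alpha1 - 2*alpha1 = -alpha1
        J = jacobian_at(figset_params, figset_eq)
        assert J[2, 2] == pytest.approx(-figset_params.alpha1, rel=1e-12)
        assert J[3, 3] == pytest.approx(-figset_params.alpha2, rel=1e-12)


class TestCharpolyCoefficients:
    def test_trace_and_determinant_identities(self, figset_params, figset_eq):
        c = charpoly_coefficients(figset_params, figset_eq)
        J = jacobian_at(figset_params, figset_eq)
        assert c.a11 == pytest.approx(-np.trace(J), rel=1e-10)
        assert c.a44 == pytest.approx(np.linalg.det(J), rel=1e-10)

    def test_a11_closed_form(self, figset_params, figset_eq):
        c = charpoly_coefficients(figset_params, figset_eq)
        assert c.a11 == pytest.approx(
            figset_params.alpha1 + figset_params.alpha2 + c.aux_a + c.aux_b,
            rel=1e-10,
        )

    def test_published_forms_agree_up_to_quadratic_coefficient(
        self, figset_params, figset_eq
    ):
        """The published a11, a22 reproduce the Jacobian values; the published
        a33, a44 do not (suspected typos), which the report quantifies."""
        rep = charpoly_comparison(figset_params, figset_eq)
        assert rep["a11"]["rel_difference"] < 1e-12
        assert rep["a22"]["rel_difference"] < 1e-12
        assert rep["a33"]["rel_difference"] > 1e-3
        assert rep["a44"]["rel_difference"] > 1e-3


class TestRouthHurwitz:
    def test_quartic_with_all_roots_at_minus_one_passes(self):
        c = CharPolyCoefficients(4.0, 6.0, 4.0, 1.0, 1.0, 1.0)
        assert routh_hurwitz_verdict(c)

    def test_quartic_with_real_positive_root_fails(self):
        c = CharPolyCoefficients(0.0, 0.0, 0.0, -1.0, 1.0, 1.0)  # lambda^4 = 1
        assert not routh_hurwitz_verdict(c)

    def test_eigenvalue_verdict_diagonal_examples(self):
        assert eigenvalue_verdict(np.diag([-1.0, -2.0, -3.0, -4.0])).eigen_pass
        assert not eigenvalue_verdict(np.diag([-1.0, -2.0, -3.0, 0.5])).eigen_pass

    def test_near_marginal_spectrum_is_flagged_indeterminate(self):
        v = eigenvalue_verdict(np.diag([-1.0, -2.0, -3.0, -1e-12]))
        assert v.indeterminate

    def test_verdicts_agree_over_sampled_parameter_sets(self):
        """Routh-Hurwitz and the eigenvalue oracle are equivalent statements
        about the quartic; any mismatch away from the margin is a bug."""
        for p in sample_random_parameters(5, 40):
            eq = solve_interior_equilibrium(p)
            v = stability_verdict(p, eq)
            if not v.indeterminate:
                assert v.agreement


class TestLyapunov:
    def test_bounds_positive_and_ordered_over_samples(self):
        for p in sample_random_parameters(13, 30):
            eq = solve_interior_equilibrium(p)
            lb = lyapunov_bounds(p, eq)
            assert 0 < lb.A < lb.B
            assert 0 < lb.C < lb.D

    def test_box_width_closed_form(self, figset_params, figset_eq):
        # B - A = (2/m1) * sqrt(4c + 4c^2), c = r/(m1*K*gamma1)
        lb = lyapunov_bounds(figset_params, figset_eq)
        c = figset_params.r / (figset_params.m1 * figset_params.K * figset_params.gamma1)
        assert lb.B - lb.A == pytest.approx(
            2.0 / figset_params.m1 * np.sqrt(4 * c + 4 * c**2), rel=1e-12
        )

    def test_weights_match_definitions(self, figset_params, figset_eq):
        lb = lyapunov_bounds(figset_params, figset_eq)
        assert lb.l1 == pytest.approx(
            figset_eq.y_star / figset_eq.x_star
            * figset_params.sigma2 / figset_params.sigma1, rel=1e-12
        )
        assert lb.l2 == 1.0 / figset_params.alpha1
        assert lb.l3 == 1.0 / figset_params.alpha2

    def test_V_zero_at_equilibrium_positive_elsewhere(self, figset_params, figset_eq):
        assert lyapunov_value(figset_eq.to_array(), figset_eq, figset_params) == 0.0
        assert vdot_diagnostic(figset_eq.to_array(), figset_eq, figset_params) == \
            pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(2)
        for _ in range(20):
            u = figset_eq.to_array() * rng.uniform(0.3, 3.0, 4)
            assert lyapunov_value(u, figset_eq, figset_params) > 0

    def test_vdot_negative_throughout_the_box(self, figset_params, figset_eq):
        census = vdot_box_census(figset_params, figset_eq, 2000, seed=1)
        assert census["frac_negative"] == 1.0
        assert census["max_vdot"] < 0

    def test_V_decreases_while_prey_inside_box(self, figset_params, figset_eq):
        """Trajectory-level check: V is non-increasing on every saved step
        whose prey biomasses lie in (A, B) x (C, D).  (V need not decrease
        outside the box — for this parameter set the box does not contain
        the equilibrium's patch-2 prey level.)"""
        lb = lyapunov_bounds(figset_params, figset_eq)
        init = [0.5 * (lb.A + lb.B), 0.5 * (lb.C + lb.D),
                figset_eq.z_star, figset_eq.w_star]
        traj = simulate_ode(figset_params, init, 40.0, 0.02)
        V = np.array([
            lyapunov_value(u, figset_eq, figset_params) for u in traj.states
        ])
        x, y = traj.states[:, 0], traj.states[:, 1]
        inside = (x > lb.A) & (x < lb.B) & (y > lb.C) & (y < lb.D)
        step_inside = inside[:-1] & inside[1:]
        assert step_inside.sum() > 10
        assert np.all(V[1:][step_inside] <= V[:-1][step_inside] + 1e-9)
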