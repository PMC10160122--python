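"""Additive-noise machinery: linearization, spectra, variances, simulation."""

import numpy as np
import pytest

from patchfishery import (
    LinearizedSystem,
    NoiseSpec,
    Trajectory,
    autocorrelation_from_spectrum,
    autocorrelation_from_trajectory,
    linearization_gap,
    linearize,
    noise_variance_scan,
    periodogram,
    simulate_linearized_sde,
    simulate_sde,
    spectral_density,
    transfer_matrix,
    variance_lyapunov,
)
from patchfishery.stochastic import _spectrum_values

# index pairs (i, j) whose adjugate entries are identically zero in the published closed forms
STRUCTURAL_ZEROS = [(0, 1), (0, 3), (1, 0), (1, 2), (2, 1), (2, 3), (3, 0), (3, 2)]


@pytest.fixture(scope="module")
def figset_lin(figset_params, figset_eq):
    return linearize(figset_params, figset_eq)


def ou_embedding(a: float) -> LinearizedSystem:
    """Scalar Ornstein-Uhlenbeck u' = -a*u + beta*xi in the first slot."""
    return LinearizedSystem(1, 1, 1, 1, 0, 0, 0, 0,
                            np.diag([-a, -1.0, -1.0, -1.0]))


class TestLinearize:
    def test_published_drift_entries(self, figset_params, figset_eq, figset_lin):
        A = figset_lin.drift
        S, T = figset_eq.x_star, figset_eq.z_star
        assert A[0, 2] == pytest.approx(-figset_params.m1 * S)
        assert A[0, 1] == 0.0  # migration coupling absent from the published system
        assert A[2, 0] == pytest.approx(figset_lin.N3 * T**2 / S**2)
        assert figset_lin.N1 == figset_params.r / figset_params.K
        assert figset_lin.N3 == figset_params.alpha1 / figset_params.gamma1

    def test_gap_to_full_jacobian_is_reported(self, figset_params, figset_eq):
        gap = linearization_gap(figset_params, figset_eq)
        # the published system drops sigma2 from entry (1,2) among others
        assert gap["max_abs_difference"] >= figset_params.sigma2

    def test_drift_is_stable_for_preset(self, figset_lin):
        assert figset_lin.stable


class TestTransferMatrix:
    @pytest.mark.parametrize("omega", [0.0, 1.0, 10.0])
    def test_inverse_contract(self, figset_lin, omega):
        tm = transfer_matrix(figset_lin, omega)
        np.testing.assert_allclose(tm.G @ tm.M, np.eye(4), atol=1e-10)

    def test_zero_frequency_is_negated_drift(self, figset_lin):
        tm = transfer_matrix(figset_lin, 0.0)
        assert np.all(tm.M.imag == 0)
        np.testing.assert_array_equal(tm.M.real, -figset_lin.drift)

    @pytest.mark.parametrize("omega", [0.3, 1.0, 5.0])
    def test_structural_zeros_of_adjugate(self, figset_lin, omega):
        G = transfer_matrix(figset_lin, omega).G
        for i, j in STRUCTURAL_ZEROS:
            assert abs(G[i, j]) < 1e-12


class TestSpectralDensity:
    def test_zero_noise_gives_zero_spectrum_and_variance(self, figset_lin):
        spec = spectral_density(figset_lin, NoiseSpec())
        assert np.all(spec.S == 0)
        np.testing.assert_array_equal(spec.variances, np.zeros(4))

    def test_spectrum_nonnegative_in_squared_mode(self, figset_lin):
        spec = spectral_density(figset_lin, NoiseSpec(1.5, 1.0, 1.5, 1.0))
        assert np.all(spec.S >= 0)

    def test_variance_scales_quadratically_in_amplitude(self, figset_lin):
        base = spectral_density(figset_lin, NoiseSpec(1.5, 1.0, 1.5, 1.0))
        double = spectral_density(figset_lin, NoiseSpec(3.0, 2.0, 3.0, 2.0))
        np.testing.assert_allclose(double.variances, 4.0 * base.variances,
                                   rtol=1e-12)

    def test_paper_literal_mode_scales_linearly(self, figset_lin):
        base = spectral_density(figset_lin, NoiseSpec(1.5, 1.0, 1.5, 1.0),
                                mode="paper_literal")
        double = spectral_density(figset_lin, NoiseSpec(3.0, 2.0, 3.0, 2.0),
                                  mode="paper_literal")
        np.testing.assert_allclose(double.variances, 2.0 * base.variances,
                                   rtol=1e-12)

    def test_quadrature_matches_lyapunov_equation(self, figset_lin):
        """The module's central oracle check: frequency-integrated spectra
        and the stationary-covariance route agree."""
        noise = NoiseSpec(1.5, 1.0, 1.5, 1.0)
        spec = spectral_density(figset_lin, noise)
        cov = variance_lyapunov(figset_lin, noise)
        np.testing.assert_allclose(spec.variances, cov.variances, rtol=0.01)


class TestVarianceLyapunov:
    def test_ou_closed_form_variance(self):
        a, beta = 0.7, 1.3
        cov = variance_lyapunov(ou_embedding(a), NoiseSpec(beta))
        assert cov.variances[0] == pytest.approx(beta**2 / (2 * a), abs=1e-12)

    def test_covariance_symmetric_positive_semidefinite(self, figset_lin):
        cov = variance_lyapunov(figset_lin, NoiseSpec(1.5, 1.0, 1.5, 1.0))
        P = cov.covariance
        np.testing.assert_allclose(P, P.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(P) >= -1e-12)

    def test_unstable_drift_raises(self):
        lin = LinearizedSystem(1, 1, 1, 1, 0, 0, 0, 0,
                               np.diag([0.1, -1.0, -1.0, -1.0]))
        with pytest.raises(np.linalg.LinAlgError):
            variance_lyapunov(lin, NoiseSpec(1.0))


class TestAutocorrelation:
    def test_ou_exponential_autocorrelation(self):
        a, beta = 0.7, 1.3
        omegas = np.concatenate([[0.0], np.geomspace(1e-4, 3000.0, 60_000)])
        S = beta**2 / (a**2 + omegas**2)
        taus = np.linspace(0.0, 3.0 / a, 16)
        _, P = autocorrelation_from_spectrum(omegas, S, taus)
        np.testing.assert_allclose(P[:, 0], np.exp(-a * taus), atol=1e-3)

    def test_normalization_at_zero_lag(self, figset_lin):
        noise = NoiseSpec(1.5, 1.0, 1.5, 1.0, seed=9)
        traj = simulate_linearized_sde(figset_lin, noise, t_end=200.0, dt=0.01)
        lags, C, P = autocorrelation_from_trajectory(traj, max_lag=100)
        np.testing.assert_array_equal(P[0], np.ones(4))
        np.testing.assert_allclose(C[0], traj.states.var(axis=0), rtol=1e-10)


class TestSimulateSDE:
    def test_zero_noise_equals_deterministic_euler(self, figset_params):
        init = np.array([7.0, 10.0, 12.0, 15.0])
        dt = 1e-3
        traj = simulate_sde(figset_params, NoiseSpec(seed=1), init, 0.5, dt)
        from patchfishery.stochastic import _drift_rhs_vec
        u = init[None, :].copy()
        for _ in range(500):
            u = u + _drift_rhs_vec(u, figset_params) * dt
        np.testing.assert_allclose(traj.final_state, u[0], rtol=1e-12)

    def test_seeded_determinism(self, figset_params):
        init = [7.0, 10.0, 12.0, 15.0]
        noise = NoiseSpec(1.5, 1.0, 1.5, 1.0, seed=77)
        a = simulate_sde(figset_params, noise, init, 2.0)
        b = simulate_sde(figset_params, noise, init, 2.0)
        np.testing.assert_array_equal(a.states, b.states)

    def test_larger_noise_larger_late_variance(self, table1_params, table1_eq):
        scan = noise_variance_scan(
            table1_params,
            [(1.5, 1.0, 1.5, 1.0), (10.0, 8.0, 10.0, 8.0)],
            table1_eq.to_array(),
            t_end=20.0, dt=1e-3, n_replicates=10, seed=4,
        )
        lo = np.array(scan["results"][0]["variance"])
        hi = np.array(scan["results"][1]["variance"])
        assert np.all(hi > lo)


class TestPeriodogram:
    def test_sinusoid_power_and_peak(self):
        dt, amp, f0 = 0.01, 2.0, 0.5
        t = np.arange(0.0, 200.0, dt)
        states = np.stack([amp * np.sin(2 * np.pi * f0 * t)] * 4, axis=1)
        spec = periodogram(Trajectory(t, states))
        total = np.trapezoid(spec.S[:, 0], spec.omegas) / np.pi
        assert total == pytest.approx(amp**2 / 2.0, rel=1e-6)
        peak = spec.omegas[np.argmax(spec.S[:, 0])]
        assert peak == pytest.approx(2 * np.pi * f0, rel=1e-6)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(8)
        dt = 0.05
        n = 80_000
        states = rng.standard_normal((n, 4))
        t = np.arange(n) * dt
        spec = periodogram(Trajectory(t, states), band_average=800)
        # discrete unit-variance white noise: flat over the Nyquist band
        # [0, pi/dt], so (1/pi)*S*(pi/dt) = 1 gives density S = dt
        expected = dt
        inner = spec.S[1:-1]
        assert np.all(np.abs(inner / expected - 1.0) < 0.2)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.4])
        with pytest.raises(ValueError, match="uniform"):
            periodogram(Trajectory(t, np.ones((4, 4))))

    def test_linearized_simulation_matches_analytic_spectra(self, figset_lin):
        """Band-averaged periodogram of a long linearized run tracks the
        analytic fluctuation spectra across the dominant band."""
        noise = NoiseSpec(1.5, 1.0, 1.5, 1.0, seed=42)
        traj = simulate_linearized_sde(figset_lin, noise, t_end=4000.0, dt=0.01)
        spec = periodogram(traj, band_average=400)
        mask = (spec.omegas > 0.05) & (spec.omegas < 3.0)
        analytic = _spectrum_values(figset_lin, noise, spec.omegas[mask], "squared")
        for i in range(4):
            dominant = analytic[:, i] >= 0.25 * analytic[:, i].max()
            ratio = spec.S[mask][dominant, i] / analytic[dominant, i]
            assert np.all((ratio > 0.8) & (ratio < 1.2))
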