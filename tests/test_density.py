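"""Linearization, Hurwitz check, stationary covariance by both routes, marginals."""

import numpy as np
import pytest

import sivs_ou as so
from sivs_ou.density import companion_matrix, is_positive_definite

from conftest import random_hurwitz_params


@pytest.fixture(scope="module")
def lin2(group2):
    return so.linearize(group2)


class TestLinearize:
    def test_group2_coefficients(self, lin2):
        got = (lin2.a11, lin2.a12, lin2.a13, lin2.a14,
               lin2.a21, lin2.a31, lin2.a33, lin2.a44)
        expected = (1.36, 0.25, 0.2, 0.448148, 0.66, 0.6, 0.3, 0.7)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_a12_is_eta_plus_epsilon(self, group2, lin2):
        assert lin2.a12 == pytest.approx(group2.eta + group2.epsilon, rel=1e-12)

    def test_infected_row_has_no_self_term(self, lin2):
        assert lin2.A_matrix[1, 1] == 0.0

    def test_drift_sign_pattern(self, lin2):
        A = lin2.A_matrix
        expected = np.array([
            [-lin2.a11, -lin2.a12, lin2.a13, -lin2.a14],
            [lin2.a21, 0.0, 0.0, lin2.a14],
            [lin2.a31, 0.0, -lin2.a33, 0.0],
            [0.0, 0.0, 0.0, -lin2.a44],
        ])
        np.testing.assert_array_equal(A, expected)

    def test_subcritical_parameters_rejected(self, group1):
        with pytest.raises(so.NoEndemicEquilibrium):
            so.linearize(group1)


class TestCharacteristicCoefficients:
    def test_group2_cubic_coefficients(self, lin2):
        c = so.characteristic_coefficients(lin2)
        assert (c.b1, c.b2, c.b3) == pytest.approx((1.66, 0.453, 0.0495), abs=1e-12)
        assert c.b1 * c.b2 - c.b3 == pytest.approx(0.70248, abs=1e-10)

    def test_group2_quartic_coefficients(self, lin2):
        c = so.characteristic_coefficients(lin2)
        assert (c.c1, c.c2, c.c3, c.c4) == pytest.approx(
            (2.36, 1.615, 0.3666, 0.03465), abs=1e-12)

    def test_hurwitz_flag_agrees_with_eigenvalues(self, lin2):
        c = so.characteristic_coefficients(lin2)
        eig_stable = bool(np.all(np.linalg.eigvals(lin2.A_matrix).real < 0))
        assert c.hurwitz == eig_stable is True

    def test_hurwitz_flag_agrees_with_eigenvalues_on_random_draws(self):
        for params in random_hurwitz_params(np.random.default_rng(42), 10):
            lin = so.linearize(params)
            c = so.characteristic_coefficients(lin)
            eig_stable = bool(np.all(np.linalg.eigvals(lin.A_matrix).real < 0))
            assert c.hurwitz == eig_stable


class TestLyapunovSolve:
    def test_defining_residual(self, lin2):
        res = so.solve_lyapunov(lin2)
        G2 = lin2.G_matrix @ lin2.G_matrix
        residual = G2 + lin2.A_matrix @ res.Sigma + res.Sigma @ lin2.A_matrix.T
        assert np.abs(residual).max() < 1e-10
        assert np.abs(res.Sigma - res.Sigma.T).max() < 1e-12

    def test_ou_corner_is_stationary_variance(self, lin2, group2):
        res = so.solve_lyapunov(lin2)
        assert res.Sigma[3, 3] == pytest.approx(group2.theta**2 / (2 * group2.k), rel=1e-10)
        assert res.Sigma[3, 3] == pytest.approx(0.0071429, abs=1e-7)

    def test_zero_volatility_gives_zero_covariance(self, group2):
        lin = so.linearize(group2.replace(theta=0.0))
        assert np.abs(so.solve_lyapunov(lin).Sigma).max() == 0.0

    def test_covariance_scales_with_theta_squared(self, group2):
        s1 = so.solve_lyapunov(so.linearize(group2)).Sigma
        s2 = so.solve_lyapunov(so.linearize(group2.replace(theta=0.2))).Sigma
        np.testing.assert_allclose(s2, 4.0 * s1, rtol=1e-9)

    def test_positive_definite(self, lin2):
        assert is_positive_definite(so.solve_lyapunov(lin2).Sigma)


class TestTransformChain:
    def test_companion_form(self, lin2):
        B = companion_matrix(lin2)
        c = so.characteristic_coefficients(lin2)
        np.testing.assert_allclose(B[0], [-c.c1, -c.c2, -c.c3, -c.c4], atol=1e-10)
        np.testing.assert_allclose(B[1:], np.eye(4)[:3], atol=1e-10)

    def test_positive_definiteness_determinant_condition(self, lin2):
        c = so.characteristic_coefficients(lin2)
        assert c.c1 * c.c2 * c.c3 - c.c3**2 - c.c1**2 * c.c4 > 0

    def test_both_a7_variants_match_lyapunov_for_group2(self, lin2):
        """The two printed a7 forms are the same quantity; both must agree with
        the direct solve entrywise to 1e-8."""
        report = so.validate_chain(lin2)
        assert report["theorem"] < 1e-8
        assert report["proof"] < 1e-8

    def test_chain_matches_lyapunov_on_random_hurwitz_draws(self):
        """Central correctness property of the closed-form algebra: the chain
        covariance equals the Lyapunov covariance on 20 random supercritical
        Hurwitz parameter sets."""
        for params in random_hurwitz_params(np.random.default_rng(2024), 20):
            lin = so.linearize(params)
            ref = so.solve_lyapunov(lin).Sigma
            chain = so.sigma_transform_chain(lin).Sigma
            scale = max(np.abs(ref).max(), 1e-30)
            assert np.abs(chain - ref).max() < 1e-8 * max(1.0, scale)

    def test_empirical_covariance_of_long_simulation(self, group2):
        """A long exact-OU run around P* at small volatility reproduces the
        Lyapunov diagonals within 25%."""
        params = group2.replace(theta=0.02)
        lin = so.linearize(params)
        Sigma = so.solve_lyapunov(lin).Sigma
        eq = lin.equilibria
        start = so.SivsState(eq.S_star, eq.I_star, eq.V_star, 0.0)
        config = so.SimConfig(dt=0.1, n_steps=500_000, seed=3,
                              scheme="exact_ou", record_stride=5)
        traj = so.simulate_path(start, params, config)
        mask = traj.times >= 5000.0
        dev = traj.states[mask] - np.array([eq.S_star, eq.I_star, eq.V_star, 0.0])
        emp = np.cov(dev, rowvar=False)
        rel = np.abs(np.diag(emp) - np.diag(Sigma)) / np.diag(Sigma)
        assert rel.max() < 0.25


class TestMarginals:
    # diagonal entries of the published ensemble covariance estimate, used as
    # plain inputs to the prefactor formula
    @pytest.mark.parametrize(
        "variance, prefactor",
        [(0.0706e-2, 15.01332), (0.2391e-2, 8.15787), (0.0870e-2, 13.52366)],
    )
    def test_prefactor_reproduces_worked_values(self, variance, prefactor):
        d = so.MarginalDensity(mean=0.0, variance=variance)
        assert d.prefactor == pytest.approx(prefactor, rel=5e-4)

    def test_prefactor_exp_coeff_identities(self):
        d = so.MarginalDensity(mean=0.7333, variance=0.2391e-2)
        assert d.prefactor * np.sqrt(2 * np.pi * d.variance) == pytest.approx(1.0, rel=1e-12)
        assert d.exp_coeff * 2.0 * d.variance == pytest.approx(1.0, rel=1e-12)

    def test_means_are_equilibrium_components(self, lin2, group2_equilibrium):
        cov = so.solve_lyapunov(lin2)
        mS, mI, mV = so.marginal_densities(cov)
        eq = group2_equilibrium
        assert (mS.mean, mI.mean, mV.mean) == (eq.S_star, eq.I_star, eq.V_star)
        for marg in (mS, mI, mV):
            assert marg.variance > 0


class TestDensityAt:
    def test_value_at_origin(self, lin2):
        cov = so.solve_lyapunov(lin2)
        expected = (2 * np.pi) ** -2 / np.sqrt(np.linalg.det(cov.Sigma))
        assert so.density_at(np.zeros(4), cov) == pytest.approx(expected, rel=1e-10)

    def test_central_symmetry(self, lin2):
        cov = so.solve_lyapunov(lin2)
        u = np.array([0.01, -0.02, 0.015, 0.005])
        assert so.density_at(u, cov) == pytest.approx(so.density_at(-u, cov), rel=1e-12)

    def test_log_density_is_quadratic_form(self, lin2):
        cov = so.solve_lyapunov(lin2)
        u = np.array([0.02, 0.01, -0.03, 0.004])
        diff = np.log(so.density_at(u, cov)) - np.log(so.density_at(np.zeros(4), cov))
        quad = -0.5 * u @ np.linalg.solve(cov.Sigma, u)
        assert diff == pytest.approx(quad, rel=1e-9)

    def test_singular_covariance_rejected(self, group2):
        lin = so.linearize(group2.replace(theta=0.0))
        cov = so.solve_lyapunov(lin)
        with pytest.raises(ValueError):
            so.density_at(np.zeros(4), cov)
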