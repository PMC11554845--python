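import numpy as np
import pytest

from pulmuq.pce import (
    DEFAULT_BOUNDS,
    ParameterPrior,
    design_matrix,
    fit_ols,
    generalized_sobol,
    moments,
    multi_indices,
    sample_prior,
    sobol_indices,
    validation_mse,
)

from oracles import pick_freeze_sobol


def uniform_prior(n, lo=-1.0, hi=1.0):
    return ParameterPrior(tuple(f"t{i}" for i in range(n)), ((lo, hi),) * n)


class TestPrior:
    def test_default_bounds(self):
        prior = ParameterPrior()
        assert prior.names == tuple(DEFAULT_BOUNDS)
        assert prior.bounds[prior.names.index("r_min")] == (1e-3, 1e-2)
        assert prior.bounds[prior.names.index("alpha")] == (0.80, 0.92)

    def test_canonical_roundtrip(self):
        prior = ParameterPrior()
        x, xi = sample_prior(prior, 50, 3)
        assert np.all(x >= prior.lo) and np.all(x <= prior.hi)
        assert np.allclose(prior.from_canonical(prior.to_canonical(x)), x)
        assert np.allclose(prior.to_canonical(x), xi)

    def test_seeded_resample_is_bitwise_identical(self):
        prior = ParameterPrior()
        a, _ = sample_prior(prior, 2000, 42)
        b, _ = sample_prior(prior, 2000, 42)
        assert np.array_equal(a, b)

    def test_lhs_design_within_bounds(self):
        prior = ParameterPrior()
        x, _ = sample_prior(prior, 64, 5, design="lhs")
        assert np.all(x >= prior.lo) and np.all(x <= prior.hi)


class TestBasis:
    @pytest.mark.parametrize("n,K,J", [(8, 4, 495), (2, 2, 6), (3, 9, 220)])
    def test_basis_count(self, n, K, J):
        assert multi_indices(n, K).shape[0] == J

    def test_orthonormality_by_quadrature(self):
        # Gauss-Legendre quadrature makes E[Psi_i Psi_j] exact
        nodes, weights = np.polynomial.legendre.leggauss(12)
        xi = np.array(np.meshgrid(nodes, nodes)).reshape(2, -1).T
        w = np.outer(weights, weights).ravel() / 4.0  # uniform density 1/2 per dim
        Psi = design_matrix(xi, multi_indices(2, 4))
        G = (Psi * w[:, None]).T @ Psi
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-12)


class TestFitAndMoments:
    def test_exact_polynomial_recovery(self):
        prior = uniform_prior(3)
        _, xi = sample_prior(prior, 400, 0)
        Z = xi[:, 0]  # affine model
        s = fit_ols(xi, Z, 3, prior=prior, canonical=True)
        deg1 = np.all(s.mi == [1, 0, 0], axis=1)
        assert s.coeffs[deg1, 0] == pytest.approx(1 / np.sqrt(3), abs=1e-10)
        assert np.abs(s.coeffs[~deg1, 0]).max() < 1e-10

    def test_moments_of_uniform_variable(self):
        prior = uniform_prior(2)
        _, xi = sample_prior(prior, 300, 1)
        s = fit_ols(xi, xi[:, 1], 2, prior=prior, canonical=True)
        mean, var = moments(s)
        assert mean[0] == pytest.approx(0.0, abs=1e-10)
        assert var[0] == pytest.approx(1.0 / 3.0, abs=1e-10)

    def test_variance_matches_monte_carlo(self):
        prior = uniform_prior(3)
        _, xi = sample_prior(prior, 500, 2)
        Z = 1 + xi[:, 0] + 0.5 * xi[:, 1] ** 2 + xi[:, 0] * xi[:, 2]
        s = fit_ols(xi, Z, 3, prior=prior, canonical=True)
        _, var = moments(s)
        rng = np.random.default_rng(9)
        x = rng.uniform(-1, 1, (100_000, 3))
        mc = np.var(1 + x[:, 0] + 0.5 * x[:, 1] ** 2 + x[:, 0] * x[:, 2])
        assert var[0] == pytest.approx(mc, rel=0.01)

    def test_parseval_against_prediction_variance(self):
        prior = uniform_prior(4)
        _, xi = sample_prior(prior, 600, 3)
        Z = np.sin(xi[:, 0]) + xi[:, 1] * xi[:, 2]
        s = fit_ols(xi, Z, 4, prior=prior, canonical=True)
        _, var = moments(s)
        rng = np.random.default_rng(11)
        pred = s.predict(rng.uniform(-1, 1, (100_000, 4)))
        assert var[0] == pytest.approx(np.var(pred), rel=0.01)

    def test_underdetermined_raises_and_small_n_warns(self):
        prior = uniform_prior(2)
        _, xi = sample_prior(prior, 20, 4)
        with pytest.raises(ValueError):
            fit_ols(xi[:4], xi[:4, 0], 2, prior=prior, canonical=True)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            fit_ols(xi[:8], xi[:8, 0], 2, prior=prior, canonical=True)


class TestSobol:
    def test_additive_model(self):
        prior = uniform_prior(2)
        _, xi = sample_prior(prior, 300, 5)
        rep = sobol_indices(fit_ols(xi, xi[:, 0] + xi[:, 1], 2, prior=prior, canonical=True))
        assert rep.S1[:, 0] == pytest.approx([0.5, 0.5], abs=1e-10)
        assert rep.S2[(0, 1)][0] == pytest.approx(0.0, abs=1e-10)

    def test_pure_interaction(self):
        prior = uniform_prior(2)
        _, xi = sample_prior(prior, 300, 6)
        rep = sobol_indices(fit_ols(xi, xi[:, 0] * xi[:, 1], 2, prior=prior, canonical=True))
        assert rep.S1[:, 0] == pytest.approx([0.0, 0.0], abs=1e-10)
        assert rep.S2[(0, 1)][0] == pytest.approx(1.0, abs=1e-10)
        assert rep.ST[:, 0] == pytest.approx([1.0, 1.0], abs=1e-10)

    def test_ishigami_closed_forms(self):
        a, b = 7.0, 0.1
        prior = uniform_prior(3, -np.pi, np.pi)
        x, xi = sample_prior(prior, 4000, 7)
        Z = np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2 + b * x[:, 2] ** 4 * np.sin(x[:, 0])
        rep = sobol_indices(fit_ols(x, Z, 9, prior=prior))
        # closed-form variance decomposition of the Ishigami function
        V1 = 0.5 * (1 + b * np.pi**4 / 5) ** 2
        V2 = a**2 / 8
        V13 = b**2 * np.pi**8 * (1 / 18 - 1 / 50)
        V = V1 + V2 + V13
        assert rep.S1[0, 0] == pytest.approx(V1 / V, abs=0.02)
        assert rep.S1[1, 0] == pytest.approx(V2 / V, abs=0.02)
        assert rep.S1[2, 0] == pytest.approx(0.0, abs=0.02)
        assert rep.ST[2, 0] == pytest.approx(V13 / V, abs=0.02)
        assert V1 / V == pytest.approx(0.3139, abs=1e-4)
        assert V2 / V == pytest.approx(0.4424, abs=1e-4)
        assert V13 / V == pytest.approx(0.2437, abs=1e-4)

    def test_matches_pick_freeze_oracle(self):
        def model(x):
            return x[:, 0] + 0.5 * x[:, 1] ** 2 + np.sin(x[:, 2]) * x[:, 0]

        prior = uniform_prior(3)
        _, xi = sample_prior(prior, 1500, 8)
        rep = sobol_indices(fit_ols(xi, model(xi), 6, prior=prior, canonical=True))
        S1_mc, ST_mc = pick_freeze_sobol(model, 3, 100_000, seed=13)
        assert np.abs(rep.S1[:, 0] - S1_mc).max() < 0.03
        assert np.abs(rep.ST[:, 0] - ST_mc).max() < 0.03

    def test_bounds_and_ordering_invariants(self):
        prior = uniform_prior(3)
        _, xi = sample_prior(prior, 800, 9)
        Z = xi[:, 0] * xi[:, 1] + 0.3 * xi[:, 2] + 0.1 * xi[:, 0] ** 2
        rep = sobol_indices(fit_ols(xi, Z, 4, prior=prior, canonical=True))
        tol = 0.02
        assert np.all(rep.S1 >= -tol) and np.all(rep.ST <= 1 + tol)
        assert np.all(rep.ST + tol >= rep.S1)
        assert rep.S1[:, 0].sum() <= 1 + tol


class TestGeneralizedSobol:
    def test_constant_index_passes_through(self):
        S = np.full(100, 0.37)
        V = np.linspace(1, 3, 100)
        assert generalized_sobol(S, V) == pytest.approx(0.37, rel=1e-12)

    def test_variance_concentration(self):
        V = np.zeros(100); V[50] = 1.0
        S = np.zeros(100); S[50] = 0.8
        assert generalized_sobol(S, V) == pytest.approx(0.8, rel=1e-6)

    def test_piecewise_hand_integral(self):
        S = np.concatenate([np.ones(500), np.zeros(500)])
        V = np.concatenate([np.ones(500), 3 * np.ones(500)])
        t = np.linspace(0, 1, 1000)
        assert generalized_sobol(S, V, t) == pytest.approx(0.25, abs=2e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            generalized_sobol(np.ones(10), np.zeros(10))


class TestValidation:
    def test_exact_truth_gives_null_mse(self):
        prior = uniform_prior(2)
        _, xi = sample_prior(prior, 200, 10)
        truth = lambda x: 1 + x[:, 0] + x[:, 0] * x[:, 1]
        s = fit_ols(xi, truth(xi), 2, prior=prior, canonical=True)
        _, xv = sample_prior(prior, 100, 11)
        err, mean = validation_mse(s, xv, truth(xv), canonical=True)
        assert mean < 1e-20

    def test_mse_improves_with_order(self):
        prior = uniform_prior(3)
        _, xi = sample_prior(prior, 2000, 12)
        f = lambda x: np.exp(0.5 * x[:, 0]) * np.cos(x[:, 1]) + 0.3 * x[:, 2]
        _, xv = sample_prior(prior, 100, 13)
        mses = []
        for K in (2, 3, 4):
            s = fit_ols(xi, f(xi), K, prior=prior, canonical=True)
            mses.append(validation_mse(s, xv, f(xv), canonical=True)[1])
        assert mses[1] <= mses[0] * 1.001
        assert mses[2] <= mses[1] * 1.001

    def test_size_mismatch_rejected(self):
        prior = uniform_prior(2)
        _, xi = sample_prior(prior, 100, 14)
        s = fit_ols(xi, xi[:, 0], 2, prior=prior, canonical=True)
        with pytest.raises(ValueError):
            validation_mse(s, xi[:10], np.zeros(9), canonical=True)
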