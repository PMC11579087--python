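"""The four objectives against conjugate-model closed forms.

The toy structural model predicts eta_1 at every observation time, so the
joint density is linear-Gaussian: posterior, evidence and marginal
likelihood all have closed forms that serve as oracles for MAP, FO, FOCE
and the ELBO.
"""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from neuralpk import autodiff as ad
from neuralpk.data import CovariateVector, SubjectBatch, SubjectRecord
from neuralpk.objectives import (
    OmegaDecomposition,
    PopulationParameters,
    ResidualModel,
    VariationalPosterior,
    elbo,
    elbo_t,
    fo_objective,
    foce_objective,
    log_joint,
    map_estimate,
    mse_objective,
    predict_with_eta_jacobian_t,
)

from conftest import (
    ConjugateToyModel,
    TruthCovariateModel,
    make_toy_subject,
    make_toy_population,
    toy_population_parameters,
)


def exact_minus2_marginal(subjects, omega11, sigma):
    """-2 log marginal likelihood of y_i ~ N(0, omega11 J + sigma^2 I)."""
    total = 0.0
    for s in subjects:
        T = s.n_obs
        V = omega11 * np.ones((T, T)) + sigma**2 * np.eye(T)
        total += -2.0 * multivariate_normal.logpdf(s.obs_values, np.zeros(T), V)
    return total


def exact_posterior(subject, omega11, sigma):
    """Posterior mean and variance of eta_1 given y."""
    T = subject.n_obs
    var = 1.0 / (1.0 / omega11 + T / sigma**2)
    mean = var * subject.obs_values.sum() / sigma**2
    return mean, var


class TestLogJoint:
    def test_no_observations_prior_only(self, toy_model):
        pop = toy_population_parameters(toy_model, omega=np.diag([0.5, 0.3]))
        s = make_toy_subject(0, np.empty(0), times=np.empty(0))
        eta = np.array([0.4, -0.2])
        expected = multivariate_normal.logpdf(eta, np.zeros(2), np.diag([0.5, 0.3]))
        assert log_joint(pop, s, eta) == pytest.approx(expected, abs=1e-12)

    def test_zero_residual_single_observation(self, toy_model):
        pop = toy_population_parameters(toy_model, sigma=2.0)
        s = make_toy_subject(0, [0.0])  # prediction at eta=0 equals obs
        expected = -0.5 * np.log(2 * np.pi * 4.0) + multivariate_normal.logpdf(
            np.zeros(2), np.zeros(2), np.eye(2)
        )
        assert log_joint(pop, s, np.zeros(2)) == pytest.approx(expected, abs=1e-12)

    def test_matches_hand_computed_bivariate_density(self, toy_model):
        pop = toy_population_parameters(toy_model)
        s = make_toy_subject(0, [1.7])
        eta = np.array([0.6, -0.9])
        expected = norm.logpdf(1.7, loc=0.6, scale=1.0) + multivariate_normal.logpdf(
            eta, np.zeros(2), np.eye(2)
        )
        assert log_joint(pop, s, eta) == pytest.approx(expected, abs=1e-12)

    def test_singular_omega_is_named(self, toy_model):
        pop = toy_population_parameters(toy_model)
        pop.omega = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="Omega"):
            log_joint(pop, make_toy_subject(0, [1.0]), np.zeros(2))


class TestMapEstimate:
    def test_no_observations_gives_prior_mode(self, toy_model):
        pop = toy_population_parameters(toy_model)
        s = make_toy_subject(0, np.empty(0), times=np.empty(0))
        np.testing.assert_array_equal(map_estimate(pop, s), np.zeros(2))

    def test_conjugate_ridge_shrinkage(self, toy_model):
        # y = 2 with sigma^2 = omega^2 = 1: posterior mode at y/2 = 1
        pop = toy_population_parameters(toy_model)
        eta = map_estimate(pop, make_toy_subject(0, [2.0]))
        assert eta[0] == pytest.approx(1.0, abs=1e-6)
        assert eta[1] == pytest.approx(0.0, abs=1e-8)

    def test_box_constraint_activates(self, toy_model):
        pop = toy_population_parameters(toy_model)
        eta = map_estimate(pop, make_toy_subject(0, [10.0]))
        assert eta[0] == pytest.approx(3.0)

    def test_map_on_pk_subject_improves_joint_density(self, truth_model, small_population):
        from neuralpk.simulate import TRUE_OMEGA

        pop = PopulationParameters(truth_model, {}, TRUE_OMEGA, ResidualModel("additive", 5.0))
        s = small_population[0]
        eta = map_estimate(pop, s)
        assert log_joint(pop, s, eta) >= log_joint(pop, s, np.zeros(2))
        assert np.all(np.abs(eta) <= 3.0)


class TestFoObjective:
    def test_equals_exact_marginal_for_linear_model(self, toy_model):
        subjects = make_toy_population(np.diag([0.25, 0.1]), 0.8, n=12, obs_per_subject=3, seed=0)
        pop = toy_population_parameters(toy_model, omega=np.diag([0.25, 0.1]), sigma=0.8)
        got = fo_objective(pop, subjects)
        assert got == pytest.approx(exact_minus2_marginal(subjects, 0.25, 0.8), abs=1e-8)

    def test_doubling_omega_tracks_closed_form(self, toy_model):
        subjects = make_toy_population(np.diag([0.25, 0.1]), 0.8, n=8, obs_per_subject=2, seed=1)
        for scale in (1.0, 2.0):
            pop = toy_population_parameters(
                toy_model, omega=np.diag([0.25 * scale, 0.1]), sigma=0.8
            )
            assert fo_objective(pop, subjects) == pytest.approx(
                exact_minus2_marginal(subjects, 0.25 * scale, 0.8), abs=1e-8
            )

    def test_omega_to_zero_reduces_to_weighted_least_squares(self, toy_model):
        subjects = make_toy_population(np.eye(2), 1.0, n=6, obs_per_subject=2, seed=2)
        sigma = 1.3
        pop = toy_population_parameters(toy_model, omega=np.eye(2) * 1e-14, sigma=sigma)
        n_obs = sum(s.n_obs for s in subjects)
        deviance = sum((s.obs_values**2).sum() for s in subjects) / sigma**2
        expected = deviance + n_obs * np.log(sigma**2) + n_obs * np.log(2 * np.pi)
        assert fo_objective(pop, subjects) == pytest.approx(expected, rel=1e-9)

    def test_non_pd_marginal_covariance_names_subject(self, toy_model):
        subjects = [make_toy_subject(0, [1.0])]
        pop = toy_population_parameters(toy_model)
        pop.omega = np.eye(2)
        # force a negative variance through a corrupted residual model
        object.__setattr__(pop.residual, "sigma_add", np.nan)
        with pytest.raises((np.linalg.LinAlgError, FloatingPointError)):
            fo_objective(pop, subjects)


class TestFoceObjective:
    def test_equals_fo_at_zero_mode_toy(self, toy_model):
        subjects = make_toy_population(np.diag([0.25, 0.1]), 0.8, n=10, obs_per_subject=3, seed=3)
        pop = toy_population_parameters(toy_model, omega=np.diag([0.25, 0.1]), sigma=0.8)
        eta0 = np.zeros((10, 2))
        assert foce_objective(pop, subjects, eta0) == pytest.approx(
            fo_objective(pop, subjects), abs=1e-10
        )

    def test_equals_fo_at_zero_mode_pk(self, truth_model, small_population):
        from neuralpk.simulate import TRUE_OMEGA

        pop = PopulationParameters(truth_model, {}, TRUE_OMEGA, ResidualModel("additive", 5.0))
        subjects = small_population[:15]
        eta0 = np.zeros((15, 2))
        assert foce_objective(pop, subjects, eta0) == pytest.approx(
            fo_objective(pop, subjects), rel=1e-12
        )

    def test_linearization_exact_for_linear_model_any_mode(self, toy_model):
        subjects = make_toy_population(np.diag([0.25, 0.1]), 0.8, n=9, obs_per_subject=2, seed=4)
        pop = toy_population_parameters(toy_model, omega=np.diag([0.25, 0.1]), sigma=0.8)
        rng = np.random.default_rng(5)
        eta_hat = rng.normal(0, 0.5, size=(9, 2))
        assert foce_objective(pop, subjects, eta_hat) == pytest.approx(
            exact_minus2_marginal(subjects, 0.25, 0.8), abs=1e-8
        )

    def test_true_scale_preferred_over_inflated(self, toy_model):
        wins = 0
        for seed in range(7):
            subjects = make_toy_population(np.eye(2) * 0.25, 0.5, n=40, obs_per_subject=2, seed=seed)
            eta_hat = np.stack(
                [map_estimate(toy_population_parameters(toy_model, np.eye(2) * 0.25, 0.5), s) for s in subjects]
            )
            at_truth = foce_objective(
                toy_population_parameters(toy_model, np.eye(2) * 0.25, 0.5), subjects, eta_hat
            )
            inflated = foce_objective(
                toy_population_parameters(toy_model, np.eye(2), 1.0), subjects, eta_hat
            )
            wins += at_truth < inflated
        assert wins >= 5  # majority of seeds

    def test_unknown_formulation_rejected(self, toy_model):
        pop = toy_population_parameters(toy_model)
        with pytest.raises(ValueError):
            foce_objective(pop, [make_toy_subject(0, [1.0])], np.zeros((1, 2)), "bogus")


class TestElbo:
    OMEGA = np.diag([0.5**2, 0.3**2])
    SIGMA = 0.7

    def exact_q(self, subjects):
        n = len(subjects)
        mu = np.zeros((n, 2))
        L = np.zeros((n, 2, 2))
        for i, s in enumerate(subjects):
            mean, var = exact_posterior(s, self.OMEGA[0, 0], self.SIGMA)
            mu[i] = (mean, 0.0)
            L[i] = np.diag([np.sqrt(var), 0.3])
        return VariationalPosterior(mu, L)

    def test_zero_variance_at_exact_posterior(self, toy_model):
        subjects = make_toy_population(self.OMEGA, self.SIGMA, n=6, obs_per_subject=2, seed=6)
        pop = toy_population_parameters(toy_model, self.OMEGA, self.SIGMA)
        q = self.exact_q(subjects)
        evidence = -0.5 * exact_minus2_marginal(subjects, self.OMEGA[0, 0], self.SIGMA)
        values = [elbo(pop, q, subjects, n_mc=3, rng=seed) for seed in range(5)]
        np.testing.assert_allclose(values, evidence, rtol=1e-10)

    def test_estimators_agree_in_value(self, toy_model):
        subjects = make_toy_population(self.OMEGA, self.SIGMA, n=5, obs_per_subject=2, seed=7)
        pop = toy_population_parameters(toy_model, self.OMEGA, self.SIGMA)
        n = len(subjects)
        q = VariationalPosterior(
            np.full((n, 2), 0.1), np.tile(np.array([[0.2, 0.0], [0.05, 0.15]]), (n, 1, 1))
        )
        a = elbo(pop, q, subjects, estimator="standard", rng=11)
        b = elbo(pop, q, subjects, estimator="path_derivative", rng=11)
        assert a == pytest.approx(b, rel=1e-12)

    def test_no_observations_elbo_zero_at_prior(self, toy_model):
        subjects = [make_toy_subject(i, np.empty(0), times=np.empty(0)) for i in range(4)]
        pop = toy_population_parameters(toy_model, self.OMEGA, self.SIGMA)
        L = np.tile(np.diag([0.5, 0.3]), (4, 1, 1))
        q = VariationalPosterior(np.zeros((4, 2)), L)
        assert elbo(pop, q, subjects, rng=0) == pytest.approx(0.0, abs=1e-12)

    def test_elbo_below_evidence_away_from_posterior(self, toy_model):
        subjects = make_toy_population(self.OMEGA, self.SIGMA, n=6, obs_per_subject=2, seed=8)
        pop = toy_population_parameters(toy_model, self.OMEGA, self.SIGMA)
        n = len(subjects)
        q = VariationalPosterior(np.zeros((n, 2)), np.tile(np.diag([0.4, 0.3]), (n, 1, 1)))
        evidence = -0.5 * exact_minus2_marginal(subjects, self.OMEGA[0, 0], self.SIGMA)
        rng = np.random.default_rng(9)
        est = np.mean([elbo(pop, q, subjects, n_mc=50, rng=int(s)) for s in rng.integers(1e6, size=20)])
        assert est < evidence

    def test_unbiased_in_n_mc(self, toy_model):
        subjects = make_toy_population(self.OMEGA, self.SIGMA, n=4, obs_per_subject=1, seed=10)
        pop = toy_population_parameters(toy_model, self.OMEGA, self.SIGMA)
        q = VariationalPosterior(
            np.full((4, 2), 0.05), np.tile(np.diag([0.3, 0.25]), (4, 1, 1))
        )
        rng = np.random.default_rng(12)
        small = np.array([elbo(pop, q, subjects, n_mc=1, rng=int(s)) for s in rng.integers(1e6, size=400)])
        large = np.array([elbo(pop, q, subjects, n_mc=16, rng=int(s)) for s in rng.integers(1e6, size=50)])
        se = np.sqrt(small.var() / small.size + large.var() / large.size)
        assert abs(small.mean() - large.mean()) < 4 * se

    def _grad_norm(self, toy_model, estimator):
        subjects = make_toy_population(self.OMEGA, self.SIGMA, n=6, obs_per_subject=2, seed=6)
        batch = SubjectBatch.from_subjects(subjects)
        q = self.exact_q(subjects)
        mu_t = ad.parameter(q.mu)
        l11 = ad.parameter(q.L[:, 0, 0])
        l21 = ad.parameter(q.L[:, 1, 0])
        l22 = ad.parameter(q.L[:, 1, 1])
        eps = np.random.default_rng(13).standard_normal((3, 6, 2))
        value = elbo_t(
            toy_model, {}, self.OMEGA, self.SIGMA, 0.0, "additive", batch,
            mu_t, l11, l21, l22, eps, estimator,
        )
        value.backward()
        return max(
            float(np.max(np.abs(t.grad))) if t.grad is not None else 0.0
            for t in (mu_t, l11, l21, l22)
        )

    def test_path_derivative_gradient_vanishes_at_posterior(self, toy_model):
        assert self._grad_norm(toy_model, "path_derivative") < 1e-6

    def test_standard_gradient_is_noisy_at_posterior(self, toy_model):
        assert self._grad_norm(toy_model, "standard") > 1e-3

    def test_invalid_n_mc_rejected(self, toy_model):
        pop = toy_population_parameters(toy_model)
        q = VariationalPosterior(np.zeros((1, 2)), np.eye(2)[None])
        with pytest.raises(ValueError):
            elbo(pop, q, [make_toy_subject(0, [1.0])], n_mc=0)


class TestMseObjective:
    def test_perfect_predictions_zero(self, toy_model):
        pop = toy_population_parameters(toy_model)
        assert mse_objective(pop, [make_toy_subject(0, [0.0, 0.0])]) == pytest.approx(0.0)

    def test_single_residual_squared(self, toy_model):
        pop = toy_population_parameters(toy_model)
        assert mse_objective(pop, [make_toy_subject(0, [2.0])]) == pytest.approx(4.0)

    def test_affine_relation_to_fo_residual_term(self, toy_model):
        # with Omega -> 0 the FO deviance is N*mse/sigma^2 + constants
        subjects = make_toy_population(np.eye(2), 1.0, n=5, obs_per_subject=2, seed=14)
        sigma = 1.7
        pop = toy_population_parameters(toy_model, omega=np.eye(2) * 1e-14, sigma=sigma)
        n_obs = sum(s.n_obs for s in subjects)
        fo = fo_objective(pop, subjects)
        mse = mse_objective(pop, subjects)
        expected = n_obs * mse / sigma**2 + n_obs * (np.log(sigma**2) + np.log(2 * np.pi))
        assert fo == pytest.approx(expected, rel=1e-9)


class TestOmegaDecomposition:
    def test_roundtrip(self):
        omega = np.array([[0.037, 0.0113], [0.0113, 0.017]])
        dec = OmegaDecomposition.from_matrix(omega)
        np.testing.assert_allclose(dec.matrix, omega, rtol=1e-12)
        np.testing.assert_allclose(dec.S, np.sqrt(np.diag(omega)))

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            OmegaDecomposition(np.array([0.1, 0.2]), np.array([[1.0, 1.2], [1.2, 1.0]]))


def test_pk_eta_jacobian_matches_finite_differences(truth_model, small_population):
    """The forward-mode Jacobian behind FO/FOCE against central differences."""
    batch = SubjectBatch.from_subjects(small_population[:4])
    eta_hat = np.random.default_rng(15).normal(0, 0.2, size=(4, 2))
    pred, G = predict_with_eta_jacobian_t(truth_model, {}, batch, eta_hat)
    h = 1e-6
    for j in range(2):
        shift = np.zeros((4, 2))
        shift[:, j] = h
        from neuralpk.objectives import predict_t

        hi = predict_t(truth_model, {}, batch, (eta_hat + shift)[:, 0], (eta_hat + shift)[:, 1])
        lo = predict_t(truth_model, {}, batch, (eta_hat - shift)[:, 0], (eta_hat - shift)[:, 1])
        np.testing.assert_allclose(G[:, :, j], (hi - lo) / (2 * h), atol=1e-5)
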