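"""Shared fixtures: toy analytically-tractable models and small populations."""

from __future__ import annotations

import numpy as np
import pytest

from neuralpk import autodiff as ad
from neuralpk.covariates import true_typical_values
from neuralpk.data import CovariateVector, SubjectRecord
from neuralpk.objectives import PopulationParameters, ResidualModel
from neuralpk.pk import DoseEvent
from neuralpk.simulate import SimulationDesign, simulate_population


class TruthCovariateModel:
    """The data-generating covariate map with no free parameters."""

    def init_params(self, rng):
        return {}

    def forward(self, theta, cov):
        cl, v1, _, _ = true_typical_values(
            np.asarray(cov["weight"], dtype=float), np.asarray(cov["vwf"], dtype=float)
        )
        return cl, v1, 0.15, 0.75


class ConjugateToyModel:
    """Linear-Gaussian toy: the prediction is eta_1 at every observation time.

    Bypasses the compartment engine via the predict_batch hooks, so every
    objective has a closed-form oracle (posterior, evidence, marginal
    likelihood) to compare against.
    """

    def init_params(self, rng):
        return {}

    def predict_batch(self, theta, batch, eta1=None, eta2=None):
        T = batch.y.shape[1]
        if eta1 is None:
            return np.zeros_like(batch.y)
        if isinstance(eta1, ad.Tensor):
            return eta1.reshape((*eta1.shape, 1)) * np.ones(T)
        eta1 = np.asarray(eta1, dtype=float)
        return np.broadcast_to(eta1[..., None], (*eta1.shape, T)).copy()

    def predict_batch_jacobian(self, theta, batch, eta_hat=None):
        n, T = batch.y.shape
        eta1 = np.zeros(n) if eta_hat is None else np.asarray(eta_hat)[:, 0]
        pred = np.broadcast_to(eta1[:, None], (n, T)).copy()
        G = np.zeros((n, T, 2))
        G[:, :, 0] = 1.0
        return pred, G


def make_toy_subject(sid, y_values, times=None) -> SubjectRecord:
    y_values = np.atleast_1d(np.asarray(y_values, dtype=float))
    times = np.arange(1.0, y_values.size + 1.0) if times is None else np.asarray(times)
    return SubjectRecord(
        id=sid,
        covariates=CovariateVector(weight=70.0, vwf=100.0),
        doses=[DoseEvent(0.0, 1.0)],
        obs_times=times,
        obs_values=y_values,
    )


def make_toy_population(pop_omega, sigma, n, obs_per_subject, seed) -> list[SubjectRecord]:
    """Simulate y = eta_1 + eps under the conjugate toy model."""
    rng = np.random.default_rng(seed)
    eta1 = rng.multivariate_normal(np.zeros(2), pop_omega, size=n)[:, 0]
    return [
        make_toy_subject(i, eta1[i] + sigma * rng.standard_normal(obs_per_subject))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def toy_model():
    return ConjugateToyModel()


@pytest.fixture(scope="session")
def truth_model():
    return TruthCovariateModel()


def toy_population_parameters(toy_model, omega=None, sigma=1.0) -> PopulationParameters:
    omega = np.eye(2) if omega is None else np.asarray(omega, dtype=float)
    return PopulationParameters(toy_model, {}, omega, ResidualModel("additive", sigma))


@pytest.fixture(scope="session")
def small_population():
    """Simulated study population, small enough for fast unit tests."""
    return simulate_population(SimulationDesign(n_subjects=40, seed=5))


@pytest.fixture(scope="session")
def study_population():
    """Full-size simulated population (expensive fixture, shared)."""
    return simulate_population(SimulationDesign(n_subjects=500, seed=11))
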