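"""Scikit-learn style estimator facade over the training harness.

``NeuralMixedEffectsModel`` is a BaseEstimator whose ``fit`` takes a list of
:class:`~neuralpk.data.SubjectRecord` and whose ``predict`` returns typical
(population-level) concentration predictions; ``predict_individual`` applies
per-subject MAP random effects for individualized predictions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .covariates import DEFAULT_BRANCHES, MultiBranchNetwork
from .data import SubjectBatch, SubjectRecord
from .metrics import rmse_typical
from .objectives import map_estimate, predict_t
from .train import TrainingConfig, fit


class NeuralMixedEffectsModel(BaseEstimator):
    """Mixed-effects deep compartment model with a selectable objective.

    Parameters
    ----------
    objective : {"vi", "fo", "foce", "mse"}
        Training objective. ``vi`` maximizes a reparameterized ELBO; ``fo``
        and ``foce`` minimize first-order approximate deviances; ``mse``
        fits fixed effects only.
    branches : tuple of BranchSpec
        Wiring of covariates to PK parameters.
    learning_rate, epochs, checkpoint_every, trailing_window
        ADAM step size and the checkpoint/averaging schedule.
    n_mc : int
        Monte-Carlo samples per ELBO evaluation (``vi`` only).
    elbo_estimator : {"path_derivative", "standard"}
        Which gradient paths of log q are recorded (``vi`` only).
    foce_formulation : {"interaction", "no_interaction"}
        Residual-variance linearization point for FOCE.
    residual_kind : {"additive", "combined"}
    random_state : int
        Seed for initialization and Monte-Carlo draws.

    Attributes
    ----------
    population_ : PopulationParameters
        Constrained parameters from the trailing-window average.
    omega_ : ndarray (2, 2); sigma_ : ResidualModel
    posterior_ : VariationalPosterior or None
    status_ : str; checkpoints_ : dict; result_ : FitResult
    """

    def __init__(
        self,
        objective: str = "vi",
        branches=DEFAULT_BRANCHES,
        learning_rate: float = 0.1,
        epochs: int = 2000,
        checkpoint_every: int = 25,
        trailing_window: int = 500,
        n_mc: int = 3,
        elbo_estimator: str = "path_derivative",
        foce_formulation: str = "interaction",
        residual_kind: str = "additive",
        random_state: int = 0,
    ):
        self.objective = objective
        self.branches = branches
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.checkpoint_every = checkpoint_every
        self.trailing_window = trailing_window
        self.n_mc = n_mc
        self.elbo_estimator = elbo_estimator
        self.foce_formulation = foce_formulation
        self.residual_kind = residual_kind
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            objective=self.objective,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            checkpoint_every=self.checkpoint_every,
            trailing_window=self.trailing_window,
            seed=self.random_state,
            n_mc=self.n_mc,
            elbo_estimator=self.elbo_estimator,
            foce_formulation=self.foce_formulation,
            residual_kind=self.residual_kind,
        )

    def fit(self, X: list[SubjectRecord], y=None):
        if not isinstance(X, (list, tuple)) or not all(
            isinstance(s, SubjectRecord) for s in X
        ):
            raise TypeError("X must be a list of SubjectRecord")
        network = MultiBranchNetwork(self.branches)
        result = fit(self._config(), list(X), network)
        self.result_ = result
        self.network_ = network
        self.checkpoints_ = result.checkpoints
        self.status_ = result.status
        self.population_ = result.population
        self.posterior_ = result.posterior
        if result.population is not None:
            self.omega_ = result.population.omega
            self.sigma_ = result.population.residual
        self.n_features_in_ = len(X)
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted")
        if self.population_ is None:
            raise RuntimeError(f"fit did not produce usable parameters: {self.status_}")

    def predict(self, X: list[SubjectRecord]) -> np.ndarray:
        """Typical (eta = 0) predictions, concatenated over subjects."""
        self._check_fitted()
        batch = SubjectBatch.from_subjects(list(X))
        pred = np.asarray(
            predict_t(self.population_.cov_model, self.population_.theta, batch)
        )
        return pred[batch.mask.astype(bool)]

    def predict_individual(self, X: list[SubjectRecord]) -> np.ndarray:
        """Predictions at each subject's MAP random-effect estimate."""
        self._check_fitted()
        out = []
        for s in X:
            eta = map_estimate(self.population_, s)
            batch = SubjectBatch.from_subjects([s])
            pred = np.asarray(
                predict_t(
                    self.population_.cov_model,
                    self.population_.theta,
                    batch,
                    np.full(1, eta[0]),
                    np.full(1, eta[1]),
                )
            )
            out.append(pred.reshape(-1)[: s.n_obs])
        return np.concatenate(out) if out else np.empty(0)

    def score(self, X: list[SubjectRecord], y=None) -> float:
        """Negative RMSE of typical predictions (higher is better)."""
        self._check_fitted()
        return -rmse_typical(self.population_, list(X))
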