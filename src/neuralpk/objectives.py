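"""Training objectives for the mixed-effects deep compartment model.

Four objectives over the population model (structural PK model +
covariate map + log-normal random effects on CL and V1):

* ``mse`` — mean squared error of typical (eta = 0) predictions; no
  population parameters are estimated.
* ``fo`` — first-order approximation of -2 log marginal likelihood:
  linearization of the model in eta at the population mean (zero).
* ``foce`` — first-order conditional estimation (extended least squares):
  linearization at each subject's MAP estimate eta_hat, with the
  NONMEM-style shifted residual r = y - yhat(eta_hat) + G eta_hat.  The
  ``interaction`` formulation evaluates the residual variance at the
  conditional prediction, ``no_interaction`` at the typical prediction.
* ``vi`` — negative ELBO, estimated by Monte Carlo with the
  reparameterization trick over a per-subject full-rank Gaussian q.  The
  ``standard`` estimator differentiates log q through its parameters; the
  ``path_derivative`` estimator stops those gradients, which drives the
  gradient variance to zero as q approaches the true posterior.

All *_t functions build reverse-mode graphs (inputs may be Tensors); the
plain-named wrappers take constrained numpy parameters and return floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import autodiff as ad
from .autodiff import Tensor, logdet, inv, stack, stop_gradient
from .data import SubjectBatch, SubjectRecord
from .pk import concentration_profile, concentration_with_eta_jacobian

LOG_2PI = float(np.log(2.0 * np.pi))

#: MAP estimates of eta are box-constrained to improve training stability.
ETA_BOUND = 3.0


@dataclass(frozen=True)
class ResidualModel:
    """Residual error: additive (variance sigma_add^2) or combined
    (sigma_add^2 + (sigma_prop * prediction)^2)."""

    kind: str = "additive"
    sigma_add: float = 5.0
    sigma_prop: float = 0.0

    def __post_init__(self):
        if self.kind not in ("additive", "combined"):
            raise ValueError(f"unknown residual model {self.kind!r}")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.sigma_add == 0 and self.sigma_prop == 0:
            raise ValueError("at least one residual component must be positive")


@dataclass(frozen=True)
class OmegaDecomposition:
    """Omega = S C S' with marginal SDs S and correlation matrix C."""

    S: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        S = np.atleast_1d(np.asarray(self.S, dtype=float))
        C = np.asarray(self.C, dtype=float)
        if np.any(S <= 0):
            raise ValueError("marginal SDs must be positive")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("C must be symmetric with unit diagonal")
        if np.any(np.linalg.eigvalsh(C) <= 0):
            raise ValueError("C must be positive definite")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "C", C)

    @property
    def matrix(self) -> np.ndarray:
        return np.diag(self.S) @ self.C @ np.diag(self.S)

    @classmethod
    def from_matrix(cls, omega: np.ndarray) -> "OmegaDecomposition":
        omega = np.asarray(omega, dtype=float)
        s = np.sqrt(np.diag(omega))
        return cls(s, omega / np.outer(s, s))


@dataclass
class PopulationParameters:
    """Everything shared across subjects: the covariate model and its
    parameters theta, the random-effect covariance Omega, and the residual
    model Sigma."""

    cov_model: object
    theta: dict
    omega: np.ndarray
    residual: ResidualModel

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(np.linalg.eigvalsh(self.omega) <= 0):
            raise np.linalg.LinAlgError("Omega is not positive definite")


@dataclass
class VariationalPosterior:
    """Per-subject full-rank Gaussian q(eta) = N(mu, L L')."""

    mu: np.ndarray  # (n, k)
    L: np.ndarray  # (n, k, k) lower-triangular, positive diagonal

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.L = np.asarray(self.L, dtype=float)
        if np.any(np.diagonal(self.L, axis1=-2, axis2=-1) <= 0):
            raise ValueError("L must have positive diagonal")

    @property
    def covariance(self) -> np.ndarray:
        return self.L @ np.swapaxes(self.L, -1, -2)


# ---------------------------------------------------------------------------
# structural predictions
# ---------------------------------------------------------------------------


def typical_values_t(cov_model, theta, batch: SubjectBatch):
    """(CL, V1, Q, V2) from the covariate model; CL, V1 shaped (n,)."""
    return cov_model.forward(theta, batch.covariates)


def predict_t(cov_model, theta, batch: SubjectBatch, eta1=None, eta2=None):
    """Concentration predictions, shape (n, T) or (m, n, T) with MC samples.

    eta1/eta2 (if given) have shape (n,) or (m, n) and act multiplicatively
    on CL and V1 through exp().  A covariate model may bypass the
    two-compartment engine entirely by providing ``predict_batch`` (used by
    analytically tractable toy models in validation).
    """
    if hasattr(cov_model, "predict_batch"):
        return cov_model.predict_batch(theta, batch, eta1, eta2)
    cl, v1, q, v2 = typical_values_t(cov_model, theta, batch)
    if eta1 is not None:
        cl = cl * ad.exp(eta1)
        v1 = v1 * ad.exp(eta2)
    extra = () if _ndim(cl) == 1 else (_shape(cl)[0],)
    cl = _reshape(cl, (*extra, batch.n_subjects, 1))
    v1 = _reshape(v1, (*extra, batch.n_subjects, 1))
    q, v2 = _per_subject_column(q, batch), _per_subject_column(v2, batch)
    return concentration_profile(
        cl, v1, q, v2, batch.times, batch.dose_times, batch.dose_amounts, batch.dose_durations
    )


def predict_with_eta_jacobian_t(cov_model, theta, batch: SubjectBatch, eta_hat=None):
    """Prediction and Jacobian d pred / d eta, both (n, T) / (n, T, 2),
    evaluated at constant eta_hat (default zero)."""
    if hasattr(cov_model, "predict_batch_jacobian"):
        return cov_model.predict_batch_jacobian(theta, batch, eta_hat)
    cl, v1, q, v2 = typical_values_t(cov_model, theta, batch)
    if eta_hat is not None:
        eta_hat = np.asarray(eta_hat, dtype=float)
        cl = cl * np.exp(eta_hat[:, 0])
        v1 = v1 * np.exp(eta_hat[:, 1])
    cl = _reshape(cl, (batch.n_subjects, 1))
    v1 = _reshape(v1, (batch.n_subjects, 1))
    q, v2 = _per_subject_column(q, batch), _per_subject_column(v2, batch)
    pred, g1, g2 = concentration_with_eta_jacobian(
        cl, v1, q, v2, batch.times, batch.dose_times, batch.dose_amounts, batch.dose_durations
    )
    G = stack([g1, g2], axis=-1) if isinstance(pred, Tensor) or isinstance(g1, Tensor) else np.stack([g1, g2], axis=-1)
    return pred, G


def _per_subject_column(x, batch):
    """Reshape per-subject (n,) global parameters to (n, 1); scalars pass."""
    if _ndim(x) == 1 and _shape(x)[0] == batch.n_subjects:
        return _reshape(x, (batch.n_subjects, 1))
    return x


def _ndim(x):
    return x.data.ndim if isinstance(x, Tensor) else np.ndim(x)


def _shape(x):
    return x.data.shape if isinstance(x, Tensor) else np.shape(x)


def _reshape(x, shape):
    return x.reshape(shape) if isinstance(x, Tensor) else np.reshape(x, shape)


def _value(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def residual_variance_t(pred, sigma_add, sigma_prop, kind: str):
    if kind == "additive":
        v = sigma_add * sigma_add
        return v + 0.0 * pred  # broadcast to prediction shape
    return sigma_add * sigma_add + (sigma_prop * pred) * (sigma_prop * pred)


# ---------------------------------------------------------------------------
# the extended-least-squares core shared by FO and FOCE
# ---------------------------------------------------------------------------


def gaussian_m2ll_t(r, G, omega, var, mask):
    """-2 log N(r; 0, G Omega G' + diag(var)) summed over subjects.

    r: (n, T) residuals; G: (n, T, k) eta-Jacobians; omega: (k, k);
    var: (n, T) residual variances; mask: (n, T) with 1 for real
    observations.  Padded entries contribute exactly zero (their rows of G
    and r are zeroed and their variance is set to one).
    """
    n, T = mask.shape
    r = r * mask
    G = G * mask[..., None]
    var = var * mask + (1.0 - mask)
    V = G @ omega @ _mT(G) + _reshape(var, (n, T, 1)) * np.eye(T)
    V_data = _value(V)
    finite = np.all(np.isfinite(V_data), axis=(-1, -2))
    signs = np.where(finite, np.linalg.slogdet(np.where(np.isfinite(V_data), V_data, 0.0))[0], -1.0)
    if not np.all(signs > 0):
        bad = np.flatnonzero(~(signs > 0)).tolist()
        raise np.linalg.LinAlgError(
            f"marginal covariance V_i not positive definite for subjects {bad}"
        )
    ld = logdet(V).sum() if isinstance(V, Tensor) else np.linalg.slogdet(V)[1].sum()
    Vinv = inv(V) if isinstance(V, Tensor) else np.linalg.inv(V)
    r_col = _reshape(r, (n, T, 1))
    quad = (r_col * (Vinv @ r_col)).sum()
    return ld + quad + float(mask.sum()) * LOG_2PI


def _mT(G):
    if isinstance(G, Tensor):
        return G.mT
    return np.swapaxes(G, -1, -2)


def fo_objective_t(cov_model, theta, omega, sigma_add, sigma_prop, kind, batch):
    """FO approximation of -2 log marginal likelihood (Tensor-aware)."""
    pred, G = predict_with_eta_jacobian_t(cov_model, theta, batch)
    r = batch.y - pred
    var = residual_variance_t(pred, sigma_add, sigma_prop, kind)
    return gaussian_m2ll_t(r, G, omega, var, batch.mask)


def foce_objective_t(
    cov_model, theta, omega, sigma_add, sigma_prop, kind, batch, eta_hat, formulation="interaction"
):
    """FOCE extended least squares at the MAP estimates (Tensor-aware)."""
    eta_hat = np.asarray(eta_hat, dtype=float)
    pred_h, G = predict_with_eta_jacobian_t(cov_model, theta, batch, eta_hat)
    shift = (G @ eta_hat[:, :, None]) if isinstance(G, Tensor) else G @ eta_hat[:, :, None]
    shift = _reshape(shift, batch.y.shape)
    r = batch.y - pred_h + shift
    if formulation == "interaction":
        var = residual_variance_t(pred_h, sigma_add, sigma_prop, kind)
    elif formulation == "no_interaction":
        typical = predict_t(cov_model, theta, batch)
        var = residual_variance_t(typical, sigma_add, sigma_prop, kind)
    else:
        raise ValueError(f"unknown FOCE formulation {formulation!r}")
    return gaussian_m2ll_t(r, G, omega, var, batch.mask)


def mse_objective_t(cov_model, theta, batch):
    pred = predict_t(cov_model, theta, batch)
    r = (batch.y - pred) * batch.mask
    return (r * r).sum() * (1.0 / batch.n_obs)


# ---------------------------------------------------------------------------
# ELBO with reparameterized Monte Carlo
# ---------------------------------------------------------------------------


def gaussian_prior_logpdf_t(eta1, eta2, omega):
    """log N(eta; 0, Omega) for a 2x2 Omega, elementwise over samples."""
    o11, o12, o22 = omega[0][0], omega[0][1], omega[1][1]
    det = o11 * o22 - o12 * o12
    quad = (o22 * eta1 * eta1 - 2.0 * o12 * eta1 * eta2 + o11 * eta2 * eta2) / det
    return -LOG_2PI - 0.5 * ad.log(det) - 0.5 * quad


def elbo_t(
    cov_model,
    theta,
    omega,
    sigma_add,
    sigma_prop,
    kind,
    batch,
    q_mu,
    q_l11,
    q_l21,
    q_l22,
    eps,
    estimator="path_derivative",
):
    """Monte-Carlo ELBO (to be maximized), Tensor-aware.

    q_mu: (n, 2); q_l11/q_l21/q_l22: (n,) Cholesky entries of the
    per-subject covariance; eps: (m, n, 2) standard-normal draws.  The two
    estimators produce the identical value for the same draws; they differ
    only in which gradient paths are recorded.
    """
    mu1, mu2 = q_mu[:, 0], q_mu[:, 1]
    e1, e2 = eps[..., 0], eps[..., 1]  # (m, n) constants
    eta1 = mu1 + q_l11 * e1
    eta2 = mu2 + q_l21 * e1 + q_l22 * e2

    pred = predict_t(cov_model, theta, batch, eta1, eta2)  # (m, n, T)
    var = residual_variance_t(pred, sigma_add, sigma_prop, kind)
    r = (batch.y - pred) * batch.mask
    loglik = (-0.5 * ((ad.log(var) + LOG_2PI) * batch.mask + r * r / var)).sum(axis=-1)
    logprior = gaussian_prior_logpdf_t(eta1, eta2, omega)

    if estimator == "path_derivative":
        m1, m2 = stop_gradient(mu1), stop_gradient(mu2)
        l11, l21, l22 = stop_gradient(q_l11), stop_gradient(q_l21), stop_gradient(q_l22)
    elif estimator == "standard":
        m1, m2, l11, l21, l22 = mu1, mu2, q_l11, q_l21, q_l22
    else:
        raise ValueError(f"unknown ELBO estimator {estimator!r}")
    u1 = (eta1 - m1) / l11
    u2 = (eta2 - m2 - l21 * u1) / l22
    logq = -LOG_2PI - ad.log(l11) - ad.log(l22) - 0.5 * (u1 * u1 + u2 * u2)

    total = (loglik + logprior - logq).sum()
    m = eps.shape[0]
    return total * (1.0 / m)


# ---------------------------------------------------------------------------
# per-subject joint density, MAP estimation
# ---------------------------------------------------------------------------


def _subject_batch(subject: SubjectRecord) -> SubjectBatch:
    return SubjectBatch.from_subjects([subject])


def log_joint(pop: PopulationParameters, subject: SubjectRecord, eta) -> float:
    """log p(y | eta) + log N(eta; 0, Omega) for one subject."""
    eta = np.asarray(eta, dtype=float)
    omega = pop.omega
    sign, ld = np.linalg.slogdet(omega)
    if sign <= 0:
        raise np.linalg.LinAlgError("Omega is not positive definite")
    prior = -0.5 * (2 * LOG_2PI + ld + eta @ np.linalg.solve(omega, eta))
    if subject.n_obs == 0:
        return float(prior)
    batch = _subject_batch(subject)
    pred = np.asarray(
        predict_t(pop.cov_model, pop.theta, batch, np.full(1, eta[0]), np.full(1, eta[1]))
    ).reshape(-1)
    res = pop.residual
    var = res.sigma_add**2 + (res.sigma_prop * pred) ** 2
    r = subject.obs_values - pred
    loglik = -0.5 * np.sum(np.log(2 * np.pi * var) + r * r / var)
    return float(loglik + prior)


def _neg_log_joint_and_grad(pop, subject, batch, eta):
    """Value and gradient of -log p(y, eta); gradient via the forward-mode
    tangents of the analytic PK solution."""
    omega_inv = np.linalg.inv(pop.omega)
    prior_grad = -omega_inv @ eta
    sign, ld = np.linalg.slogdet(pop.omega)
    prior = -0.5 * (2 * LOG_2PI + ld + eta @ omega_inv @ eta)
    if subject.n_obs == 0:
        return -prior, -prior_grad
    pred, G = predict_with_eta_jacobian_t(pop.cov_model, pop.theta, batch, eta[None, :])
    pred = np.asarray(_value(pred)).reshape(-1)
    G = np.asarray(_value(G)).reshape(-1, 2)
    res = pop.residual
    var = res.sigma_add**2 + (res.sigma_prop * pred) ** 2
    r = subject.obs_values - pred
    loglik = -0.5 * np.sum(np.log(2 * np.pi * var) + r * r / var)
    dll_dc = r / var
    if res.sigma_prop > 0:
        dll_dc = dll_dc + res.sigma_prop**2 * pred * (r * r / var**2 - 1.0 / var)
    grad = G.T @ dll_dc + prior_grad
    return -(loglik + prior), -grad


def map_estimate(
    pop: PopulationParameters, subject: SubjectRecord, x0=None, bound: float = ETA_BOUND
) -> np.ndarray:
    """Posterior mode of eta within the box [-bound, bound]^2 (L-BFGS-B)."""
    if subject.n_obs == 0:
        return np.zeros(2)
    batch = _subject_batch(subject)
    x0 = np.zeros(2) if x0 is None else np.asarray(x0, dtype=float)

    def fun(eta):
        return _neg_log_joint_and_grad(pop, subject, batch, eta)

    result = minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=[(-bound, bound)] * 2,
        options={"maxiter": 100},
    )
    return np.clip(result.x, -bound, bound)


def map_estimates(pop: PopulationParameters, subjects, x0s=None) -> np.ndarray:
    """MAP estimates for every subject, optionally warm-started."""
    out = np.zeros((len(subjects), 2))
    for i, s in enumerate(subjects):
        out[i] = map_estimate(pop, s, None if x0s is None else x0s[i])
    return out


# ---------------------------------------------------------------------------
# float-returning wrappers over constrained numpy parameters
# ---------------------------------------------------------------------------


def _res_args(pop):
    return pop.residual.sigma_add, pop.residual.sigma_prop, pop.residual.kind


def mse_objective(pop: PopulationParameters, subjects) -> float:
    batch = SubjectBatch.from_subjects(list(subjects))
    return float(_value(mse_objective_t(pop.cov_model, pop.theta, batch)))


def fo_objective(pop: PopulationParameters, subjects) -> float:
    batch = SubjectBatch.from_subjects(list(subjects))
    return float(
        _value(fo_objective_t(pop.cov_model, pop.theta, pop.omega, *_res_args(pop), batch))
    )


def foce_objective(pop: PopulationParameters, subjects, eta_hats, formulation="interaction") -> float:
    batch = SubjectBatch.from_subjects(list(subjects))
    return float(
        _value(
            foce_objective_t(
                pop.cov_model, pop.theta, pop.omega, *_res_args(pop), batch,
                eta_hats, formulation,
            )
        )
    )


def elbo(
    pop: PopulationParameters,
    q: VariationalPosterior,
    subjects,
    n_mc: int = 3,
    estimator: str = "path_derivative",
    rng=None,
) -> float:
    """Monte-Carlo ELBO estimate over a subject list (higher is better)."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(rng)
    batch = SubjectBatch.from_subjects(list(subjects))
    eps = rng.standard_normal((n_mc, batch.n_subjects, 2))
    value = elbo_t(
        pop.cov_model, pop.theta, pop.omega, *_res_args(pop), batch,
        q.mu, q.L[:, 0, 0], q.L[:, 1, 0], q.L[:, 1, 1], eps, estimator,
    )
    out = float(_value(value))
    if not np.isfinite(out):
        raise FloatingPointError("non-finite ELBO sample (check rng seed and parameters)")
    return out
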