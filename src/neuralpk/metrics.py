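"""Comparison metrics: RMSE of typical predictions, Gaussian KL of Omega,
MAE of variance components, CV conversion, replicate aggregation and
training-trajectory summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SubjectBatch
from .objectives import PopulationParameters, predict_t


@dataclass
class MetricReport:
    """Per-fit metrics plus median +/- SD aggregates over replicates."""

    rmse: float = np.nan
    kl_omega: float = np.nan
    mae_omega_1: float = np.nan
    mae_omega_2: float = np.nan
    mae_sigma: float = np.nan

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "kl_omega": self.kl_omega,
            "mae_omega_1": self.mae_omega_1,
            "mae_omega_2": self.mae_omega_2,
            "mae_sigma": self.mae_sigma,
        }


def rmse_typical(pop: PopulationParameters, subjects) -> float:
    """Root mean squared error of eta = 0 predictions over all observations."""
    subjects = list(subjects)
    if not subjects or all(s.n_obs == 0 for s in subjects):
        raise ValueError("no observations to evaluate")
    batch = SubjectBatch.from_subjects(subjects)
    pred = np.asarray(predict_t(pop.cov_model, pop.theta, batch))
    sq = ((batch.y - pred) * batch.mask) ** 2
    return float(np.sqrt(sq.sum() / batch.mask.sum()))


def eta_information(pop: PopulationParameters, subjects) -> np.ndarray:
    """Mean per-subject Fisher information about the random effects.

    Evaluated at eta = 0 under the Gaussian observation model:
    mean over subjects of G_i' diag(1/var) G_i, with G_i the prediction
    Jacobian in eta.  Comparing its diagonal against the prior precision
    diag(Omega^-1) shows how much each random-effect coordinate is
    informed by the sampling design; values far below the prior precision
    mean the corresponding variance component is weakly identified.
    """
    from .objectives import predict_with_eta_jacobian_t, residual_variance_t

    batch = SubjectBatch.from_subjects(list(subjects))
    pred, G = predict_with_eta_jacobian_t(pop.cov_model, pop.theta, batch)
    pred, G = np.asarray(pred), np.asarray(G)
    res = pop.residual
    var = np.asarray(residual_variance_t(pred, res.sigma_add, res.sigma_prop, res.kind))
    w = batch.mask / var
    info = np.einsum("ntk,nt,ntl->kl", G, w, G)
    return info / batch.n_subjects


def kl_omega(omega_est: np.ndarray, omega_true: np.ndarray) -> float:
    """KL( N(0, Omega_est) || N(0, Omega_true) ) in nats.

    The direction penalizes collapsed variance estimates severely, which is
    the observed FOCE failure mode (variances shrinking during training).
    """
    est = np.atleast_2d(np.asarray(omega_est, dtype=float))
    true = np.atleast_2d(np.asarray(omega_true, dtype=float))
    for name, m in (("omega_est", est), ("omega_true", true)):
        if np.any(np.linalg.eigvalsh(m) <= 0):
            raise np.linalg.LinAlgError(f"{name} is not positive definite")
    k = est.shape[0]
    solve = np.linalg.solve(true, est)
    _, ld_true = np.linalg.slogdet(true)
    _, ld_est = np.linalg.slogdet(est)
    return float(0.5 * (np.trace(solve) - k + ld_true - ld_est))


def cv_percent(omega_marginal_sd: float) -> float:
    """Log-normal coefficient of variation: sqrt(exp(omega^2) - 1) * 100%."""
    if omega_marginal_sd < 0:
        raise ValueError("marginal SD must be non-negative")
    return float(np.sqrt(np.expm1(omega_marginal_sd**2)) * 100.0)


def aggregate_replicates(values) -> dict:
    """Median and SD over non-failed replicates; NaNs are counted as
    failures, never silently propagated."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate")
    ok = values[np.isfinite(values)]
    n_failed = int(values.size - ok.size)
    if ok.size == 0:
        return {"median": np.nan, "sd": np.nan, "n": 0, "n_failed": n_failed,
                "status": "all replicates failed"}
    return {
        "median": float(np.median(ok)),
        "sd": float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0,
        "n": int(ok.size),
        "n_failed": n_failed,
        "status": "ok",
    }


def trailing_window_mean(checkpoints: dict, epochs: int, window: int, cadence: int) -> dict:
    """Mean of checkpointed raw parameters over the final training window.

    Averaging happens on the unconstrained scale (pre-softplus /
    pre-correlation transform), so the averaged parameters stay inside the
    feasible region after transformation.  ``checkpoints`` maps epoch ->
    dict of raw parameter arrays.
    """
    if not checkpoints:
        raise ValueError("no checkpoints in the trailing window")
    if window > epochs:
        import warnings

        warnings.warn("window longer than training; using all checkpoints")
    start = epochs - window
    selected = [e for e in sorted(checkpoints) if e > start] or sorted(checkpoints)
    keys = checkpoints[selected[0]].keys()
    return {
        k: np.mean([checkpoints[e][k] for e in selected], axis=0) for k in keys
    }


def training_trajectory_summary(checkpoints: dict, series: dict | None = None) -> dict:
    """Long-format per-checkpoint series for convergence plots.

    Returns {"epoch": [...], <metric>: [...]} merging any recorded scalar
    series (objective value, KL of Omega, residual SD) by epoch.
    """
    epochs = sorted(checkpoints)
    out = {"epoch": list(epochs)}
    if series:
        for name, values in series.items():
            out[name] = [values.get(e, np.nan) for e in epochs]
    return out
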