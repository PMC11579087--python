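"""Closed-form two-compartment kinetics with bolus and infusion dosing.

The structural model is the linear two-compartment system

    dA1/dt = u(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - k21 A2

with micro-constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2.  Because the
system is linear, the concentration in the central compartment is a
superposition over dose events of the biexponential unit impulse response

    h(u) = [(alpha - k21) e^{-alpha u} + (k21 - beta) e^{-beta u}]
           / (V1 (alpha - beta)),

where alpha, beta are the eigen-rates (roots of s^2 - (k10+k12+k21) s +
k10 k21).  Constant-rate infusions use the running integral H of h.
Amounts are IU, volumes L, times hours; concentrations are reported in
IU/dL (1 IU/L = 0.1 IU/dL), which puts factor VIII levels on the clinical
0-100 scale.

All kinetics functions are written against the dispatching math in
:mod:`neuralpk.autodiff`, so the PK parameters may be floats, numpy arrays,
reverse-mode :class:`~neuralpk.autodiff.Tensor` values, or forward-mode
:class:`~neuralpk.autodiff.Dual` numbers; observation and dose times are
always plain constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Dual, dual_exp, dual_sqrt

IU_PER_L_TO_IU_PER_DL = 0.1

# relative jitter guarding the (measure-zero) coincident-eigenvalue case
_EIGEN_JITTER = 1e-12


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: bolus if ``duration == 0``, else an infusion
    of ``amount / duration`` IU/h over ``[time, time + duration]``."""

    time: float
    amount: float
    duration: float = 0.0

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.duration < 0:
            raise ValueError(f"dose duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment parameters: clearance CL (L/h), central volume V1 (L),
    inter-compartmental clearance Q (L/h), peripheral volume V2 (L)."""

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self):
        for name in ("CL", "V1", "Q", "V2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.CL, self.V1, self.Q, self.V2])


@dataclass(frozen=True)
class ConcentrationSeries:
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("concentrations must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def _eigen_rates(cl, v1, q, v2):
    """Hybrid rate constants (alpha, beta) and k21 of the 2-compartment system."""
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    # smooth guard: adds O(1e-24) relative perturbation to the discriminant
    disc = dual_sqrt(s * s - 4.0 * k10 * k21 + (_EIGEN_JITTER * s) * (_EIGEN_JITTER * s))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta, k21


def unit_impulse_response(cl, v1, q, v2, u):
    """Central concentration (per IU dosed, in IU/L) at elapsed time u >= 0."""
    alpha, beta, k21 = _eigen_rates(cl, v1, q, v2)
    denom = v1 * (alpha - beta)
    coef_a = (alpha - k21) / denom
    coef_b = (k21 - beta) / denom
    return coef_a * dual_exp(-1.0 * alpha * u) + coef_b * dual_exp(-1.0 * beta * u)


def unit_infusion_integral(cl, v1, q, v2, u):
    """Integral of the unit impulse response over [0, u]; 0 at u = 0."""
    alpha, beta, k21 = _eigen_rates(cl, v1, q, v2)
    denom = v1 * (alpha - beta)
    coef_a = (alpha - k21) / denom
    coef_b = (k21 - beta) / denom
    term_a = (coef_a / alpha) * (1.0 - dual_exp(-1.0 * alpha * u))
    term_b = (coef_b / beta) * (1.0 - dual_exp(-1.0 * beta * u))
    return term_a + term_b


def concentration_profile(
    cl,
    v1,
    q,
    v2,
    times: np.ndarray,
    dose_times: np.ndarray,
    dose_amounts: np.ndarray,
    dose_durations: np.ndarray,
):
    """Central concentration in IU/dL by superposition over dose events.

    ``times`` has shape (..., T); dose arrays have shape (..., K) or (K,)
    and are constants (never differentiated).  PK parameters broadcast
    against the leading axes of ``times``.
    """
    times = np.asarray(times, dtype=float)
    dose_times = np.atleast_1d(np.asarray(dose_times, dtype=float))
    dose_amounts = np.atleast_1d(np.asarray(dose_amounts, dtype=float))
    dose_durations = np.atleast_1d(np.asarray(dose_durations, dtype=float))
    total = 0.0
    n_slots = dose_times.shape[-1]
    for k in range(n_slots):
        t0 = dose_times[..., k : k + 1]
        amt = dose_amounts[..., k : k + 1]
        dur = dose_durations[..., k : k + 1]
        if np.all(amt == 0.0):
            continue
        is_bolus = dur == 0.0
        u = np.maximum(times - t0, 0.0)
        if np.any(is_bolus):
            active = (times >= t0) & is_bolus
            bolus = (amt * active) * unit_impulse_response(cl, v1, q, v2, u)
            total = bolus + total
        if not np.all(is_bolus):
            safe_dur = np.where(is_bolus, 1.0, dur)
            rate = np.where(is_bolus, 0.0, amt / safe_dur)
            u_stop = np.maximum(times - t0 - dur, 0.0)
            running = unit_infusion_integral(cl, v1, q, v2, u)
            stopped = unit_infusion_integral(cl, v1, q, v2, u_stop)
            total = rate * (running - stopped) + total
    if isinstance(total, float):  # no (non-zero) doses at all
        return np.zeros(times.shape)
    return total * IU_PER_L_TO_IU_PER_DL


def predict_concentrations(
    params: PKParameters, doses: list[DoseEvent], times
) -> ConcentrationSeries:
    """Noise-free central-compartment concentrations (IU/dL) at ``times``."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("observation times must be >= 0")
    if not doses:
        return ConcentrationSeries(times, np.zeros_like(times))
    values = concentration_profile(
        params.CL,
        params.V1,
        params.Q,
        params.V2,
        times,
        np.array([d.time for d in doses]),
        np.array([d.amount for d in doses]),
        np.array([d.duration for d in doses]),
    )
    return ConcentrationSeries(times, np.asarray(values))


def concentration_with_eta_jacobian(
    cl, v1, q, v2, times, dose_times, dose_amounts, dose_durations
):
    """Prediction and its Jacobian w.r.t. the log-scale random effects.

    The random effects act multiplicatively, CL = zeta_CL e^{eta1} and
    V1 = zeta_V1 e^{eta2}, so d pred / d eta1 = CL * d pred / d CL and
    d pred / d eta2 = V1 * d pred / d V1.  Parameter derivatives come from
    one forward-mode pass with two tangent slots; the results remain on the
    reverse-mode tape when the inputs are Tensors.

    Returns (pred, dpred_deta1, dpred_deta2).
    """
    out = concentration_profile(
        Dual(cl, 1.0, 0.0),
        Dual(v1, 0.0, 1.0),
        q,
        v2,
        times,
        dose_times,
        dose_amounts,
        dose_durations,
    )
    return out.val, cl * out.d1, v1 * out.d2
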