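"""Covariate-to-parameter maps: the simulation ground truth, a free-coefficient
version of the same functional family, and the trainable multi-branch network.

The fixed-effects map f(x; theta) produces the typical two-compartment
parameters zeta = (CL, V1, Q, V2) from covariates; per-subject random effects
eta ~ N(0, Omega) then act multiplicatively, z = g(zeta, eta) with
CL_i = zeta_CL e^{eta_1} and V1_i = zeta_V1 e^{eta_2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import softplus, swish
from .pk import PKParameters

#: Normalization constants applied to covariates before they enter a branch.
DEFAULT_NORMALIZATION = {"weight": 70.0, "vwf": 100.0, "age": 50.0, "height": 175.0}


def leaky_softplus(x, alpha: float = 1.0 / 20.0, beta: float = 1.0 / 10.0):
    """alpha*x + (1-alpha)*log(exp(beta*x) + 1)/beta.

    A softplus with a non-zero left slope: derivative lies in (alpha, 1),
    strictly increasing and C-infinity.  Overflow-safe for large |x|.
    """
    return alpha * x + (1.0 - alpha) * softplus(beta * x) / beta


def _inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


def true_typical_values(weight, vwf):
    """Typical (eta = 0) parameters of the simulation's data-generating model.

    CL (L/h) rises with body weight (allometric exponent 0.75) and with
    VWF:Ag through a saturating leaky-softplus term; V1 (L) scales linearly
    with weight; Q = 0.15 L/h and V2 = 0.75 L are constants.
    """
    weight = np.asarray(weight, dtype=float)
    vwf = np.asarray(vwf, dtype=float)
    cl = 0.1 * (weight / 70.0) ** 0.75 * (leaky_softplus(vwf + 100.0) / 55.0 + 0.9)
    v1 = 2.0 * (weight / 70.0)
    q = np.full_like(cl, 0.15)
    v2 = np.full_like(cl, 0.75)
    return cl, v1, q, v2


def true_pk_parameters(cov, eta=(0.0, 0.0)) -> PKParameters:
    """Individual parameters of the data-generating model for one subject."""
    cl, v1, q, v2 = true_typical_values(cov.weight, cov.vwf)
    eta = np.asarray(eta, dtype=float)
    return PKParameters(
        CL=float(cl * np.exp(eta[0])),
        V1=float(v1 * np.exp(eta[1])),
        Q=float(q),
        V2=float(v2),
    )


def apply_random_effects(zeta: PKParameters, eta) -> PKParameters:
    """g(zeta, eta): multiplicative log-normal effects on CL and V1."""
    eta = np.asarray(eta, dtype=float)
    return PKParameters(
        CL=zeta.CL * float(np.exp(eta[0])),
        V1=zeta.V1 * float(np.exp(eta[1])),
        Q=zeta.Q,
        V2=zeta.V2,
    )


@dataclass(frozen=True)
class BranchSpec:
    """One branch of the multi-branch network: a small fully-connected net
    from a subset of (normalized) covariates to one PK parameter."""

    input_covariates: tuple
    target_parameter: str  # "CL" or "V1"
    hidden_sizes: tuple = (16,)

    def __post_init__(self):
        if self.target_parameter not in ("CL", "V1"):
            raise ValueError("branch target must be CL or V1")
        if not self.input_covariates:
            raise ValueError("branch needs at least one input covariate")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")

    @property
    def name(self) -> str:
        return f"{self.target_parameter}_{'_'.join(self.input_covariates)}"


#: Wiring used throughout the simulation study: weight -> CL and V1,
#: VWF:Ag -> CL; Q and V2 are global scalars.
DEFAULT_BRANCHES = (
    BranchSpec(("weight",), "CL"),
    BranchSpec(("vwf",), "CL"),
    BranchSpec(("weight",), "V1"),
)


class MultiBranchNetwork:
    """Trainable fixed-effects map built from per-covariate branches.

    Each branch is a one-hidden-layer network (swish activation, linear
    output).  Branch outputs targeting the same parameter are summed with a
    parameter-level bias and passed through softplus, guaranteeing positive
    CL and V1.  Q and V2 are softplus-transformed global scalars.
    """

    def __init__(self, branches=DEFAULT_BRANCHES, normalization=None):
        self.branches = tuple(branches)
        self.normalization = dict(normalization or DEFAULT_NORMALIZATION)
        targets = {b.target_parameter for b in self.branches}
        for t in ("CL", "V1"):
            if t not in targets:
                raise ValueError(f"no branch targets {t}")

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Random initial parameters: hidden weights ~ N(0, 1/fan_in); output
        biases start the softplus outputs near plausible typical values."""
        params: dict[str, np.ndarray] = {}
        for b in self.branches:
            fan_in = len(b.input_covariates)
            sizes = (fan_in, *b.hidden_sizes, 1)
            for li in range(len(sizes) - 1):
                n_in, n_out = sizes[li], sizes[li + 1]
                scale = 1.0 / np.sqrt(n_in)
                if li == len(sizes) - 2:
                    scale *= 0.1  # small output layer: start near the bias
                params[f"{b.name}/W{li}"] = rng.normal(0.0, scale, size=(n_in, n_out))
                params[f"{b.name}/b{li}"] = np.zeros(n_out)
        params["CL/bias"] = np.array(_inv_softplus(0.1) + rng.normal(0.0, 0.1))
        params["V1/bias"] = np.array(_inv_softplus(2.0) + rng.normal(0.0, 0.1))
        params["Q/raw"] = np.array(_inv_softplus(0.1) + rng.normal(0.0, 0.1))
        params["V2/raw"] = np.array(_inv_softplus(1.0) + rng.normal(0.0, 0.1))
        return params

    def _branch_output(self, params, spec: BranchSpec, cov: dict):
        x = np.column_stack(
            [
                np.asarray(cov[name], dtype=float) / self.normalization.get(name, 1.0)
                for name in spec.input_covariates
            ]
        )
        h = x
        n_layers = len(spec.hidden_sizes) + 1
        for li in range(n_layers):
            w = params[f"{spec.name}/W{li}"]
            b = params[f"{spec.name}/b{li}"]
            h = h @ w + b
            if li < n_layers - 1:
                h = swish(h)
        for key in (f"{spec.name}/W0",):  # fail fast on NaN weights
            data = params[key].data if isinstance(params[key], ad.Tensor) else params[key]
            if not np.all(np.isfinite(data)):
                raise FloatingPointError(f"non-finite weights in branch {spec.name}")
        return h.reshape(-1) if isinstance(h, ad.Tensor) else np.reshape(h, -1)

    def forward(self, params, cov: dict):
        """Typical parameters for a batch of subjects.

        ``params`` values may be ndarrays or Tensors; ``cov`` maps covariate
        names to (n,) arrays.  Returns (CL, V1, Q, V2) with CL, V1 of shape
        (n,) and Q, V2 scalars.
        """
        sums = {"CL": params["CL/bias"], "V1": params["V1/bias"]}
        for spec in self.branches:
            sums[spec.target_parameter] = (
                sums[spec.target_parameter] + self._branch_output(params, spec, cov)
            )
        n = len(np.asarray(next(iter(cov.values()))))
        cl = softplus(sums["CL"])
        v1 = softplus(sums["V1"])
        if not isinstance(cl, ad.Tensor) and np.ndim(cl) == 0:
            cl = np.full(n, float(cl))
            v1 = np.full(n, float(v1))
        return cl, v1, softplus(params["Q/raw"]), softplus(params["V2/raw"])


class ParametricCovariateModel:
    """The data-generating functional family with free coefficients.

    CL = cl_base * (weight/70)^{cl_exp} * (leaky_softplus(VWF+100)/55 + 0.9),
    V1 = v1_base * (weight/70); Q, V2 global softplus scalars.  Used for
    parameter-recovery checks where the estimator is given the correct model
    family and has only to find its coefficients.
    """

    truth = {"cl_base": 0.1, "cl_exp": 0.75, "v1_base": 2.0}

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        return {
            "log_cl_base": np.array(np.log(0.15) + rng.normal(0.0, 0.1)),
            "cl_exp": np.array(0.5 + rng.normal(0.0, 0.1)),
            "log_v1_base": np.array(np.log(1.5) + rng.normal(0.0, 0.1)),
            "Q/raw": np.array(_inv_softplus(0.1) + rng.normal(0.0, 0.1)),
            "V2/raw": np.array(_inv_softplus(1.0) + rng.normal(0.0, 0.1)),
        }

    def forward(self, params, cov: dict):
        w = np.asarray(cov["weight"], dtype=float) / 70.0
        vwf = np.asarray(cov["vwf"], dtype=float)
        vwf_term = leaky_softplus(vwf + 100.0) / 55.0 + 0.9
        cl = ad.exp(params["log_cl_base"] + params["cl_exp"] * np.log(w)) * vwf_term
        v1 = ad.exp(params["log_v1_base"]) * w
        return cl, v1, softplus(params["Q/raw"]), softplus(params["V2/raw"])


def visualize_covariate_effects(
    model: MultiBranchNetwork,
    theta_samples: list[dict],
    covariate_grid: dict[str, np.ndarray],
    reference: dict | None = None,
):
    """Learned covariate-effect curves across fitted replicates.

    For each branch, its input covariate sweeps the grid while the other
    covariates sit at reference values; the branch's target parameter is
    evaluated for every replicate's parameters.  Returns, per branch, the
    grid, the pointwise median and a 95% band over replicates.
    """
    if not theta_samples:
        raise ValueError("need at least one fitted replicate")
    reference = dict(DEFAULT_NORMALIZATION if reference is None else reference)
    out = {}
    for spec in getattr(model, "branches", ()):
        cov_name = spec.input_covariates[0]
        grid = np.asarray(covariate_grid[cov_name], dtype=float)
        curves = []
        for params in theta_samples:
            cov = {name: np.full(grid.size, reference.get(name, 0.0)) for name in reference}
            cov[cov_name] = grid
            cl, v1, _, _ = model.forward(params, cov)
            values = cl if spec.target_parameter == "CL" else v1
            curves.append(np.asarray(values.data if isinstance(values, ad.Tensor) else values))
        curves = np.stack(curves)
        out[spec.name] = {
            "covariate": cov_name,
            "grid": grid,
            "median": np.median(curves, axis=0),
            "lo": np.percentile(curves, 2.5, axis=0),
            "hi": np.percentile(curves, 97.5, axis=0),
        }
    return out
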