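"""Reference posteriors by ensemble MCMC, for validating variational fits.

Two scenarios mirror the simulation study's posterior-accuracy check:

1. all population parameters fixed at their true values — the posterior
   factorizes over subjects into 2-D densities p(eta_i | y_i), each sampled
   exactly with an affine-invariant ensemble sampler (emcee);
2. population covariance and residual error sampled jointly with the
   random effects, under weakly-informative priors on the S-C-S'
   decomposition: half-Normal(0.5) marginal SDs, LKJ(2) correlation,
   half-Normal(5 IU/dL) additive error.

Variational and MCMC posteriors are compared with the exact 2-Wasserstein
distance between Gaussians, after moment-matching the MCMC cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import sqrtm
from scipy.stats import chi2

from .data import SubjectRecord
from .objectives import PopulationParameters, VariationalPosterior

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class McmcConfig:
    scenario: int = 1
    n_samples: int = 10000  # scenario 2 default: 5000
    n_warmup: int = 1000
    seed: int = 0
    n_walkers: int = 16

    def __post_init__(self):
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class PosteriorSamples:
    """Draws from the hierarchical posterior; scenario 2 adds population
    parameter draws."""

    eta: np.ndarray  # (draws, n_subjects, 2)
    s: np.ndarray | None = None  # (draws, 2) marginal SDs
    rho: np.ndarray | None = None  # (draws,)
    sigma_add: np.ndarray | None = None  # (draws,)
    acceptance: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.eta.shape[0]

    def subject_moments(self):
        """Per-subject posterior mean (n, 2) and covariance (n, 2, 2)."""
        mean = self.eta.mean(axis=0)
        centered = self.eta - mean
        cov = np.einsum("dnk,dnl->nkl", centered, centered) / (self.n_draws - 1)
        return mean, cov


def _subject_loglik_factory(pop: PopulationParameters, subject: SubjectRecord):
    """Vectorized log p(y_i | eta) over an (m, 2) array of eta values."""
    from .data import SubjectBatch
    from .objectives import predict_t

    batch = SubjectBatch.from_subjects([subject])
    y = subject.obs_values

    def loglik(eta, sigma_add, sigma_prop=0.0):
        eta = np.atleast_2d(eta)
        pred = np.asarray(
            predict_t(pop.cov_model, pop.theta, batch, eta[:, 0:1], eta[:, 1:2])
        ).reshape(eta.shape[0], -1)
        sa = np.asarray(sigma_add, dtype=float)
        sp = np.asarray(sigma_prop, dtype=float)
        if sa.ndim == 1:
            sa = sa[:, None]
        if sp.ndim == 1:
            sp = sp[:, None]
        var = sa**2 + (sp * pred) ** 2
        r = y[None, :] - pred
        return -0.5 * np.sum(np.log(2 * np.pi * var) + r * r / var, axis=1)

    return loglik


def _prior_eta(eta, omega_inv, ld_omega):
    quad = np.einsum("mk,kl,ml->m", eta, omega_inv, eta)
    return -0.5 * (2 * LOG_2PI + ld_omega + quad)


def sample_reference(
    pop_truth: PopulationParameters, subjects: list[SubjectRecord], cfg: McmcConfig
) -> PosteriorSamples:
    """Draws from the reference posterior under the chosen scenario."""
    import emcee

    rng = np.random.default_rng(cfg.seed)
    if cfg.scenario == 1:
        return _sample_scenario1(pop_truth, subjects, cfg, rng, emcee)
    return _sample_scenario2(pop_truth, subjects, cfg, rng, emcee)


def _sample_scenario1(pop, subjects, cfg, rng, emcee):
    n = len(subjects)
    omega_inv = np.linalg.inv(pop.omega)
    _, ld = np.linalg.slogdet(pop.omega)
    res = pop.residual
    nw = cfg.n_walkers
    steps = int(np.ceil(cfg.n_samples / nw))
    burn = max(1, int(np.ceil(cfg.n_warmup / nw)))
    eta_all = np.empty((steps * nw, n, 2))
    acc = np.empty(n)
    for i, subject in enumerate(subjects):
        loglik = _subject_loglik_factory(pop, subject)

        def logprob(eta):
            lp = _prior_eta(eta, omega_inv, ld)
            if subject.n_obs:
                lp = lp + loglik(eta, res.sigma_add, res.sigma_prop)
            return lp

        sampler = emcee.EnsembleSampler(nw, 2, logprob, vectorize=True)
        p0 = rng.normal(0.0, 0.1, size=(nw, 2))
        state = sampler.run_mcmc(p0, burn, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, steps, progress=False)
        eta_all[:, i, :] = sampler.get_chain(flat=True)
        acc[i] = sampler.acceptance_fraction.mean()
    out = PosteriorSamples(eta_all[: cfg.n_samples], acceptance=acc)
    if np.any(acc < 0.1):
        out.warnings.append("low acceptance fraction for some subjects")
    return out


def _sample_scenario2(pop, subjects, cfg, rng, emcee):
    """Joint posterior over (eta_1..n, S, rho, sigma_add)."""
    n = len(subjects)
    dim = 2 * n + 4
    res_kind = pop.residual.kind
    logliks = [_subject_loglik_factory(pop, s) for s in subjects]

    def logprob(x):
        x = np.atleast_2d(x)  # (m, dim)
        m = x.shape[0]
        eta = x[:, : 2 * n].reshape(m, n, 2)
        s = x[:, 2 * n : 2 * n + 2]
        rho = x[:, 2 * n + 2]
        sig = x[:, 2 * n + 3]
        lp = np.zeros(m)
        bad = (s <= 0).any(axis=1) | (np.abs(rho) >= 1) | (sig <= 0)
        lp[bad] = -np.inf
        ok = ~bad
        if not ok.any():
            return lp
        # priors: half-Normal(0.5) on S, LKJ(2) on C, half-Normal(5) on sigma
        lp[ok] += -0.5 * np.sum((s[ok] / 0.5) ** 2, axis=1)
        lp[ok] += np.log1p(-rho[ok] ** 2)
        lp[ok] += -0.5 * (sig[ok] / 5.0) ** 2
        det = (s[ok, 0] * s[ok, 1]) ** 2 * (1 - rho[ok] ** 2)
        e1, e2 = eta[ok, :, 0], eta[ok, :, 1]
        s0 = s[ok, 0:1]
        s1 = s[ok, 1:2]
        r_ = rho[ok][:, None]
        quad = (
            (e1 / s0) ** 2 - 2 * r_ * (e1 / s0) * (e2 / s1) + (e2 / s1) ** 2
        ) / (1 - r_**2)
        lp[ok] += np.sum(-0.5 * quad - LOG_2PI, axis=1) - 0.5 * n * np.log(det)
        for i, ll in enumerate(logliks):
            lp[ok] += ll(eta[ok][:, i, :], sig[ok], 0.0 if res_kind == "additive" else pop.residual.sigma_prop)
        return lp

    nw = max(cfg.n_walkers, 2 * dim + 2)
    steps = int(np.ceil(cfg.n_samples / nw))
    burn = max(1, int(np.ceil(cfg.n_warmup / nw)))
    p0 = np.concatenate(
        [
            rng.normal(0.0, 0.1, size=(nw, 2 * n)),
            np.abs(rng.normal(0.2, 0.05, size=(nw, 2))),
            rng.uniform(-0.3, 0.3, size=(nw, 1)),
            np.abs(rng.normal(4.0, 0.5, size=(nw, 1))),
        ],
        axis=1,
    )
    sampler = emcee.EnsembleSampler(nw, dim, logprob, vectorize=True)
    state = sampler.run_mcmc(p0, burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, steps, progress=False)
    flat = sampler.get_chain(flat=True)[: cfg.n_samples]
    out = PosteriorSamples(
        eta=flat[:, : 2 * n].reshape(-1, n, 2),
        s=flat[:, 2 * n : 2 * n + 2],
        rho=flat[:, 2 * n + 2],
        sigma_add=flat[:, 2 * n + 3],
        acceptance=np.array([sampler.acceptance_fraction.mean()]),
    )
    if out.acceptance[0] < 0.05:
        out.warnings.append("low joint acceptance fraction; increase walkers/steps")
    return out


def gaussian_w2(mu1, cov1, mu2, cov2) -> float:
    """Exact 2-Wasserstein distance between two Gaussians."""
    mu1, mu2 = np.atleast_1d(mu1), np.atleast_1d(mu2)
    cov1, cov2 = np.atleast_2d(cov1), np.atleast_2d(cov2)
    root2 = np.real(sqrtm(cov2))
    cross = np.real(sqrtm(root2 @ cov1 @ root2))
    d2 = float(np.sum((mu1 - mu2) ** 2) + np.trace(cov1 + cov2 - 2 * cross))
    return float(np.sqrt(max(d2, 0.0)))


def _ellipse(mean, cov, level=0.95):
    vals, vecs = np.linalg.eigh(cov)
    radius = np.sqrt(chi2.ppf(level, df=2) * vals)
    angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
    return {"center": mean, "radii": radius[::-1], "angle_deg": angle}


def compare_posteriors(vi_q: VariationalPosterior, mcmc: PosteriorSamples) -> dict:
    """Per-subject 2-Wasserstein distances between the Gaussian q and a
    Gaussian moment-match of the MCMC draws, plus 95% ellipse overlays."""
    if mcmc.n_draws < 100:
        raise ValueError("need at least 100 MCMC draws for stable moments")
    mean, cov = mcmc.subject_moments()
    n = mean.shape[0]
    if vi_q.mu.shape[0] != n:
        raise ValueError("subject mismatch between VI and MCMC posteriors")
    vi_cov = vi_q.covariance
    distances = np.array(
        [gaussian_w2(vi_q.mu[i], vi_cov[i], mean[i], cov[i]) for i in range(n)]
    )
    ellipses = [
        {"vi": _ellipse(vi_q.mu[i], vi_cov[i]), "mcmc": _ellipse(mean[i], cov[i])}
        for i in range(n)
    ]
    return {
        "wasserstein": distances,
        "median_wasserstein": float(np.median(distances)),
        "ellipses": ellipses,
    }
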