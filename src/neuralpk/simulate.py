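"""Synthetic haemophilia-A population generator and the fold/replicate design.

Covariates come from a small causal DAG (age -> height -> weight; blood
group and age -> VWF:Ag) that stands in for the external generative model
the study design assumes; its marginal ranges echo the covariate table of
the real cohorts (weight ~50-135 kg, VWF:Ag ~60-250%, blood-group O lower
VWF).  Factor VIII levels are then simulated from the two-compartment model
with the ground-truth covariate map, log-normal random effects with

    Omega = [[0.037, 0.0113], [0.0113, 0.017]],

a single bolus of 25 IU/kg rounded to the nearest 250 IU, samples at 4, 24
and 48 h, and additive Gaussian residual error (default SD 5 IU/dL — an
assumption surfaced in :class:`SimulationDesign`, as the generating value
is not published).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariates import true_typical_values
from .data import CovariateVector, SubjectRecord
from .objectives import ResidualModel
from .pk import DoseEvent, concentration_profile

TRUE_OMEGA = np.array([[0.037, 0.0113], [0.0113, 0.017]])

BLOOD_GROUPS = ("O", "A", "B", "AB")
BLOOD_GROUP_PROBS = (0.45, 0.40, 0.11, 0.04)


@dataclass(frozen=True)
class SimulationDesign:
    n_subjects: int = 500
    dose_per_kg: float = 25.0
    dose_rounding: float = 250.0
    obs_times: tuple = (4.0, 24.0, 48.0)
    omega: np.ndarray = field(default_factory=lambda: TRUE_OMEGA.copy())
    residual: ResidualModel = field(default_factory=lambda: ResidualModel("additive", 5.0))
    seed: int = 0

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=float)
        if np.any(np.linalg.eigvalsh(omega) <= 0):
            raise ValueError("omega must be positive definite")
        if any(t <= 0 for t in self.obs_times):
            raise ValueError("observation times must be positive")
        object.__setattr__(self, "omega", omega)


@dataclass(frozen=True)
class FoldPlan:
    n_folds: int = 20
    train_size: int = 60
    with_replacement: bool = True
    replicates_per_fold: int = 5
    seed: int = 0


def sample_covariates(n: int, seed=None) -> list[CovariateVector]:
    """Draw covariate vectors from the substitute DAG.

    age ~ TruncNormal(45, 15) on [12, 77]; height plateaus in adulthood;
    weight is log-normal around a height-derived mean (clipped to
    [40, 140] kg); VWF:Ag is log-normal with a downward shift for blood
    group O and a mild upward age trend, clipped to [40, 250]%.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(45.0, 15.0, size=n), 12.0, 77.0)
    adult_height = 175.0 + rng.normal(0.0, 7.0, size=n)
    growth = np.minimum(age, 18.0) / 18.0  # linear ramp to the adult plateau
    height = np.clip(adult_height * (0.55 + 0.45 * growth), 120.0, 205.0)
    bmi_mean = 24.0
    weight = bmi_mean * (height / 100.0) ** 2 * np.exp(rng.normal(0.0, 0.16, size=n))
    weight = np.clip(weight, 40.0, 140.0)
    group = rng.choice(BLOOD_GROUPS, size=n, p=BLOOD_GROUP_PROBS)
    group_shift = np.where(group == "O", np.log(0.75), 0.0)  # known O-group deficit
    age_trend = 0.004 * (age - 45.0)  # VWF rises mildly with age
    vwf = np.exp(np.log(120.0) + group_shift + age_trend + rng.normal(0.0, 0.28, size=n))
    vwf = np.clip(vwf, 40.0, 250.0)
    return [
        CovariateVector(
            weight=float(weight[i]),
            vwf=float(vwf[i]),
            age=float(age[i]),
            height=float(height[i]),
            blood_group=str(group[i]),
        )
        for i in range(n)
    ]


def compute_dose(weight: float, dose_per_kg: float = 25.0, rounding: float = 250.0) -> float:
    """Weight-based dose rounded to the nearest vial multiple (ties away
    from zero): 250 * round(25 * weight / 250)."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    raw = dose_per_kg * weight
    return float(np.floor(raw / rounding + 0.5) * rounding)


def simulate_population(design: SimulationDesign, seed=None) -> list[SubjectRecord]:
    """Covariates -> typical parameters -> random effects -> noisy levels."""
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    covs = sample_covariates(design.n_subjects, rng.integers(2**31))
    eta = rng.multivariate_normal(np.zeros(2), design.omega, size=design.n_subjects)
    times = np.asarray(design.obs_times, dtype=float)
    subjects = []
    for i, cov in enumerate(covs):
        cl, v1, q, v2 = true_typical_values(cov.weight, cov.vwf)
        dose = compute_dose(cov.weight, design.dose_per_kg, design.dose_rounding)
        conc = concentration_profile(
            float(cl) * np.exp(eta[i, 0]),
            float(v1) * np.exp(eta[i, 1]),
            float(q),
            float(v2),
            times,
            np.array([0.0]),
            np.array([dose]),
            np.array([0.0]),
        )
        res = design.residual
        noise_sd = np.sqrt(res.sigma_add**2 + (res.sigma_prop * conc) ** 2)
        y = np.maximum(conc + rng.standard_normal(times.size) * noise_sd, 0.0)
        subjects.append(
            SubjectRecord(
                id=i,
                covariates=cov,
                doses=[DoseEvent(0.0, dose)],
                obs_times=times.copy(),
                obs_values=y,
                true_eta=eta[i].copy(),
            )
        )
    return subjects


@dataclass(frozen=True)
class Fold:
    index: int
    train_indices: np.ndarray  # multiset of indices (with replacement)
    test_indices: np.ndarray  # subjects never drawn into training
    replicate_seeds: tuple


def make_folds(population: list[SubjectRecord], plan: FoldPlan) -> list[Fold]:
    """Random train subsets drawn with replacement; the test set is every
    subject the fold never drew."""
    n = len(population)
    if n < plan.train_size:
        raise ValueError("population smaller than the training size")
    if not plan.with_replacement and plan.train_size >= n:
        raise ValueError("without replacement the test set would be empty")
    rng = np.random.default_rng(plan.seed)
    folds = []
    for f in range(plan.n_folds):
        train = rng.choice(n, size=plan.train_size, replace=plan.with_replacement)
        test = np.setdiff1d(np.arange(n), train)
        if test.size == 0:
            raise ValueError(f"fold {f} has an empty test set")
        seeds = tuple(int(s) for s in rng.integers(2**31, size=plan.replicates_per_fold))
        folds.append(Fold(f, train, test, seeds))
    return folds


def expected_distinct_train(n_population: int, n_draws: int) -> float:
    """Expected number of distinct subjects among n_draws with replacement."""
    return n_population * (1.0 - (1.0 - 1.0 / n_population) ** n_draws)
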