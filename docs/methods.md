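# Methods

## Model

The structural model is a linear two-compartment system for factor VIII
disposition. With micro-constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, the
central concentration is the superposition over dose events of the
biexponential unit impulse response; constant-rate infusions use its
running integral. The solution is evaluated in closed form (eigen-rates of
the 2×2 rate matrix), not by numeric integration — this is faster, exact,
and differentiable; a stiff Radau integration of the mass-balance system
is kept in the test-suite as an independent oracle. Units are fixed as
amounts in IU, volumes in L, times in hours, concentrations in IU/dL
(1 IU/L = 0.1 IU/dL); baseline endogenous FVIII is taken as zero.

Typical parameters come from a fixed-effects map `f(x; θ)`:

* **Multi-branch network** (the trainable model): each branch is a
  one-hidden-layer fully connected net (16 units, swish activation, linear
  output) from one normalized covariate (weight/70, VWF/100) to one
  parameter; branch outputs for the same parameter are summed with a
  parameter-level bias and passed through softplus. Weight feeds CL and V1,
  VWF:Ag feeds CL; Q and V2 are softplus-transformed global scalars.
* **Ground-truth map** (simulation only): CL = 0.1·(weight/70)^0.75·
  (leaky_softplus(VWF+100)/55 + 0.9), V1 = 2.0·(weight/70), Q = 0.15,
  V2 = 0.75, with leaky_softplus(x) = x/20 + (19/20)·log(1+e^{x/10})·10.
  The VWF term *increases* clearance with VWF:Ag — the opposite of FVIII
  physiology — and is deliberately kept as stated in the generator
  definition rather than "corrected"; the simulation is self-consistent
  either way. A free-coefficient version of the same family
  (`ParametricCovariateModel`) is available for recovery checks.

Random effects act multiplicatively on clearance and central volume:
CL_i = ζ_CL e^{η1}, V1_i = ζ_V1 e^{η2}, η ~ N(0, Ω) with a full 2×2 Ω.
The generator's Ω is [[0.037, 0.0113], [0.0113, 0.017]]. Although the
printed generator equations attach an explicit η only to V1, a 2×2 Ω with
a CL–V1 covariance requires two random effects, so e^{η1} multiplies CL.

Residual error is additive (default) or combined; the combined variance
uses the model prediction, not the observation, in the proportional term
(the standard pharmacometric convention).

## Objectives

All four objectives act on the same population model; gradients come from
the package's own numpy reverse-mode tape (`neuralpk.autodiff`). The
η-Jacobian G = ∂ŷ/∂η needed by FO/FOCE is computed by a forward-mode dual
layer through the analytic solution (∂ŷ/∂η1 = CL·∂ŷ/∂CL, ∂ŷ/∂η2 =
V1·∂ŷ/∂V1), with the tangents themselves staying on the tape so the
objective remains differentiable in θ, Ω, Σ. No finite differences are
used anywhere in training.

* **MSE** minimizes the mean squared error of typical (η = 0) predictions;
  Ω and Σ are not estimated.
* **FO** is the first-order approximate deviance
  Σ_i [log det V_i + r_i′V_i⁻¹r_i] + N log 2π with V_i = G_iΩG_i′ + Σ_i,
  residuals and Jacobians at η = 0.
* **FOCE** linearizes at each subject's MAP estimate η̂_i with the
  NONMEM-style shifted residual r_i = y_i − ŷ_i(η̂) + G_iη̂_i, which folds
  the η̂′Ω⁻¹η̂ prior term into the quadratic form. The `interaction`
  formulation (default) evaluates Σ_i at the conditional prediction; a
  `no_interaction` variant evaluates it at the typical prediction. Which
  of the two ELS formulations a given study used can matter for its
  stability behaviour, so both are exposed. MAP estimates are produced by
  L-BFGS-B with analytic gradients, box-constrained to [−3, 3]² (bound
  enforced by the optimizer's projection), refreshed at the start of every
  epoch and warm-started from the previous epoch.
* **VI** maximizes a reparameterized Monte-Carlo ELBO (3 samples by
  default) over per-subject full-rank Gaussian posteriors q(η) = N(μ, LL′)
  initialized at μ = 0, L = 0.1·I. The `standard` estimator differentiates
  log q through its own parameters; the `path_derivative` estimator (the
  default) stops those gradients, making the per-draw gradient vanish
  identically when q equals the true posterior — in the conjugate test
  models this is exact, and it is why the path-derivative fits concentrate
  tightly across replicates while standard-estimator fits scatter.

Variance-like parameters are stored unconstrained: marginal SDs and
residual SDs through softplus, the 2×2 correlation through tanh, giving
Ω = S·C·S′ positive definite by construction. Run failures therefore
manifest as non-finite losses or numerically singular Ω (smallest
eigenvalue < 1e-8), both flagged in the fit status rather than raised.

## Training protocol

Full-batch ADAM (β1 = 0.9, β2 = 0.999, ε = 1e-8), learning rate 0.1
(0.01 recommended for FOCE), 2000 epochs by default with parameters
checkpointed every 25 epochs. Final estimates are the mean of the
checkpoints over the trailing 500 epochs, taken on the unconstrained scale
— averaging constrained covariance matrices can leave the PD manifold —
and transformed afterwards. Experiment grids draw 20 folds of 60 subjects
with replacement from the 500-subject population (test set = subjects the
fold never drew) with 5 training replicates per fold; the scaled runs in
the test-suite and acceptance script use 3–5 folds × 1 replicate × 1000
epochs to keep a full run on one CPU in minutes, which is enough to
estimate medians of the per-fit metrics.

Seed policy: a master seed drives the generator; each (fold, replicate)
pair receives its own child seed, all below 2^31 and echoed in the
reports. The entire pipeline is a pure function of its seeds.

## Synthetic data generator

The generator emulates a haemophilia-A PK study: covariates from a small
causal DAG (age → height → weight; blood group and age → VWF:Ag, with the
group-O deficit), a single bolus of 25 IU/kg rounded to the nearest
250 IU (ties away from zero), samples at 4/24/48 h, log-normal random
effects with the Ω above, additive residual SD 5 IU/dL, and levels floored
at zero. Two of these are declared assumptions rather than reproductions:
the covariate DAG is a synthetic stand-in for an external generative model
(its marginals echo published patient characteristics but its joint law is
ours), and the residual SD is unpublished — 5 IU/dL is a clinically
plausible assay-scale choice, configurable in `SimulationDesign`. The
generator does not model assay quantification limits, rounding, or
missingness; passing tests therefore speak to estimator behaviour under a
clean Gaussian error model, not to robustness against real assay
artifacts.

## Identifiability at the study design

Under the ground-truth map the typical clearance is ≈0.45 L/h (the VWF
term contributes a factor ≈4.5), so k10 + k12 ≈ 0.3 h⁻¹. The V1
sensitivity ∂ŷ/∂V1 changes sign near t ≈ 1/(k10+k12): raising V1 lowers
the early curve but slows elimination, and the two effects cancel close to
the 4 h sample; by 24 h and 48 h typical predictions are ~0–2 IU/dL
against a 5 IU/dL residual SD. The consequence — quantified by the
`eta_information` diagnostic and asserted in the test-suite — is that the
sampling design carries orders of magnitude less information about η2
(volume) than the prior precision 1/Ω22, while η1 (clearance) is
moderately informed. The marginal likelihood is therefore almost flat in
Ω22, and no estimator can recover it reliably at n = 60: in the scaled
recovery study the clearance-variance MAE is small but KL(Ω̂‖Ω) is
dominated by the unidentified volume component, and the corresponding
clauses of the recovery test fail by construction. Zero-flooring of the
near-zero late samples additionally biases the residual-SD estimate
downward (a censored-Gaussian effect outside the Gaussian likelihoods).
Typical-prediction RMSE is unaffected by all of this and lands where
expected (~5–6 IU/dL). A clearance scale near 0.1 L/h — the clinically
realistic FVIII value — would move the pivot to ~20 h and make both
variance components identifiable; the generator is nevertheless kept
exactly as specified.

## Reference posteriors

Scenario 1 fixes all population parameters at their true values, so the
posterior factorizes into per-subject 2-D densities; each is sampled with
emcee (16 walkers, vectorized log-probability, warmup discarded). An
affine-invariant ensemble sampler is exact and fast in 2-D, and no
gradient-based sampler is required. Scenario 2 samples (η_1..n, S, C,
σ_add) jointly with weakly-informative priors chosen for the S·C·S′
decomposition: half-Normal(0.5) on marginal SDs, LKJ(2) on the 2×2
correlation (density ∝ 1 − ρ²), half-Normal(5 IU/dL) on the additive SD;
walker count scales with dimension and the mean acceptance fraction is
reported (low acceptance triggers a warning in place of NUTS divergence
diagnostics). Variational and MCMC posteriors are compared with the exact
Gaussian 2-Wasserstein distance after moment-matching the MCMC cloud; the
order-2 distance with Gaussian moment matching is chosen for its closed
form, and the comparison report includes 95% ellipse overlays for
visualization.

## Numerical choices

* Coincident eigen-rates (α ≈ β) are guarded by adding (1e-12·trace)² to
  the discriminant — a smooth O(1e-24) relative perturbation instead of a
  branch to the repeated-root formula; coincidence is measure-zero for
  sampled parameters.
* softplus is evaluated as logaddexp(0, x); leaky_softplus inherits its
  overflow safety. Hidden weights initialize as N(0, 1/fan_in); output
  layers are down-scaled ×0.1 so initial CL/V1 sit near the biases'
  softplus values (0.1 L/h and 2 L); Ω initializes near marginal SDs 0.3,
  correlation 0, residual SD 3 IU/dL, all jittered per replicate seed.
* The ELBO value is identical between gradient estimators for the same
  draws (they differ only in recorded gradient paths), which the tests
  assert; ELBO-based convergence checks in the conjugate models use an
  ADAM step-size decay schedule because a constant step hovers around the
  optimum at its own scale.
* Padded (ragged) observations are masked so that absent samples
  contribute exactly zero to every objective.

## Limitations

* No absorption compartment, nonlinear elimination, or general ODE/neural-
  ODE structural models; two random effects fixed to (CL, V1).
* The FOCE inner loop is the main runtime cost (60 bounded BFGS solves per
  epoch); no SAEM or second-order Laplace objective is provided.
* Scenario-2 MCMC in ~124 dimensions mixes slowly with an ensemble
  sampler; it is adequate for the scaled checks here but a
  gradient-based sampler would be preferable at full scale.
* The real-data workflows (missing-covariate imputation, combined-error
  model selection) are out of scope; the combined residual model is
  implemented and tested but the shipped experiments use additive error.
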