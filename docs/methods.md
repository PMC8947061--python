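# Methods

## Model

Events on a window [0, T) arrive with conditional intensity
Λ(t | H_t) = λ σ(ϕ(t)), where σ is the logistic function, λ > 0 is the
intensity bound, and the linear intensity

ϕ(t) = s(t) + Σ_{t_n < t} g(t − t_n) e^{−α(t − t_n)}

adds a background rate s and a self-effect g that may be positive
(excitation) or negative (inhibition) at different lags.  s and g carry
independent zero-mean GP priors with RBF kernels
K(t, t') = a·exp(−(t−t')²/σ²); note the exponent has **no** factor 2 — the
conventional form is available via `half_exponent=True` on
`KernelParams`.  λ has a Gamma(α₀, β₀) prior.  Time is in seconds
throughout; the window is half-open; events are real-valued times, never
discretised.

Because ϕ is a sum of GPs, it is a GP conditioned on the history, with
kernel

K̃(t, t') = K_s(t, t') + Σ_{t_i<t} Σ_{t_j<t'} K_g(t−t_i, t'−t_j)
            e^{−α[(t−t_i)+(t'−t_j)]}.

The decay factor e^{−α(l+l')} is the unique form consistent with the
covariance of the decayed self-effect g̃(τ) = g(τ)e^{−ατ}; the
decomposition identity test (below) pins this reading down.  g is defined
on non-negative lags only (causality).  In the R-dimensional model,
ϕ_r(t) sums one influence function g_{r,m} (with its own amplitude,
lengthscale and decay) per source dimension; given the observations the
dimensions are independent and fitted one at a time.

## Augmentation

Sigmoid likelihood terms are removed by two standard devices: the
Pólya–Gamma identity σ(ϕ) = ∫ e^{f(w,ϕ)} PG(w; 1, 0) dw with
f(w, ϕ) = −ϕ²w/2 + ϕ/2 − ln 2, and a Campbell/marked-Poisson
representation of the survival integral, which introduces a latent thinned
process with PG marks.  All conditionals of the augmented posterior are
then Gaussian (ϕ), Gamma (λ), PG (marks) or Poisson-process (latent
points).

The tilt of every tilted PG factor is c = √(⟨ϕ⟩² + var ϕ), i.e. the root
of the posterior second moment — the convention under which
E[w] = tanh(c/2)/(2c) applies directly.  The latent-process marginal rate
used throughout is

Λ₁(t) = exp⟨ln λ⟩ · e^{−⟨ϕ(t)⟩/2} / (2 cosh(c(t)/2)),

which reduces to λ·σ(−⟨ϕ⟩) when var ϕ = 0 (the identity
e^{−x/2}/(2cosh(x/2)) = σ(−x) is unit-tested to machine precision).

## Variational inference

The mean-field family is q(λ)·q(ϕ)·q({w_n})·q(latent process) with a
sparse-GP parameterisation of q(ϕ): a Gaussian N(μ_c, Σ_c) on L inducing
points, with ϕ elsewhere following the prior conditional.  One sweep
updates, in closed form and in this order: the tilts and latent rate
(q₂), the inducing-point Gaussian (Σ_c from the PG-weighted quadratic
form, μ_c from the ±1/2 linear terms), and the Gamma factor
(α₀ + N + latent mass, β₀ + T).  Each step is an exact coordinate-ascent
maximiser, so the ELBO is non-decreasing; the implementation treats a
decrease beyond 1e−8 relative as an error when tuning is off.

Numerical choices:

- **Quadrature**: Gauss–Legendre on [0, T], 100 nodes per second by
  default, used for the latent-rate integrals, the ELBO and likelihood
  integrals.
- **Inducing points**: uniform grid on [0, T], default L = 50.  The
  aggregated kernel between an inducing location u and any t uses the full
  observed history before u and before t, which is what makes the
  posterior mean decompose exactly (below).
- **Initialisation**: μ_c = 0, Σ_c = K_c, λ-posterior = prior, tilts from
  the prior moments.
- **Convergence**: relative ELBO change < 1e−4, at most 200 iterations;
  the fixture converges in ~10.
- **Jitter**: 1e−6·amplitude on square Grams, escalated ×10 to at most
  1e−2 before a numerical error is raised.
- **Hyperparameters** {a_s, σ_s, a_g, σ_g, α} can be tuned by one
  log-space gradient-ascent step per iteration (default step 1e−2; the
  α₀, β₀ prior is not tuned).  The gradient is a central finite difference
  of the assembled ELBO with the variational moments frozen; its step-size
  robustness is unit-tested by step-halving.  Tuning rebuilds all Gram
  caches, so it is the expensive path.

`compute_elbo` assembles: event terms Σ_n [⟨ln λ⟩ + ⟨ϕ_n⟩/2 − ln 2 −
ln cosh(c_n/2)] (with the PG-moment correction retained so the bound is
valid mid-sweep), the latent-process term ∫Λ₁(bracket)dt − ⟨λ⟩T, minus the
Gamma KL, the Gaussian KL on the inducing values, and the tilted-PG KLs.

## Gibbs baseline

One sweep resamples (i) the latent points jointly by fresh thinning —
candidates from Poisson(λT), ϕ at the proposals from the GP conditional
given ϕ at the events, keep with probability σ(−ϕ); (ii) w ~ PG(1, |ϕ|)
at every event and latent point via an exact Devroye-type sampler
(implemented in `nhgps.pg`; a truncated sum-of-Gammas route serves as an
independent cross-check); (iii) ϕ at all active points from the Gaussian
with precision K̃⁻¹ + diag(w) and linear term +1/2 at events, −1/2 at
latent points; (iv) λ ~ Gamma(α₀+N+M, β₀+T).  Hyperparameters stay fixed.

By default the candidate locations of step (i) live on a uniform lattice
of 250 points per window, so all aggregated-kernel blocks are precomputed
once and a sweep costs milliseconds; duplicated lattice proposals share
one ϕ value and their PG draws/linear terms accumulate, which is the exact
conditional of the discretised proposal measure.  The lattice spacing
(T/250) is far below the background lengthscale, and `latent_grid=None`
switches to exact continuous-location proposals (a fresh Gram per sweep) —
this exact mode is what the correctness tests use.  Correctness is checked
two ways: the frozen-block λ conditional against its exact Gamma law, and
a Geweke-style successive-conditional run (regenerate the data from the
current state with an exact sequential simulator, then sweep) whose λ
marginal must match the prior.

Defaults: 5×10³ sweeps, 10³ burn-in, thinning 10–20; the λ chain's
autocorrelation decays over hundreds to thousands of sweeps, so thinned
post-burn-in samples (a few hundred) are stored together with ϕ at the
active points for post-processing.

## Decomposition

With μ̃ = K_c⁻¹μ_c and B = K_c⁻¹ − K_c⁻¹Σ_cK_c⁻¹:

- ⟨s(t)⟩ = k_s(t, u)ᵀμ̃ and ⟨g̃(τ)⟩ = Σ_l [Σ_{t_j<u_l} K̃_g(τ, u_l−t_j)] μ̃_l,
  which sum *exactly* to ⟨ϕ(t)⟩ (unit-tested at 1e−10; this identity also
  arbitrates the decay-form reading above);
- cov s = K_s − k_sᵀBk_s and cov g̃ = K̃_g − GᵀBG with G the g-feature
  matrix; diagonals are clipped at zero before taking square roots.

The same representer formulas post-process Gibbs samples (active points as
representers, μ̃ = K̃_act⁻¹ϕ_act).  g̃ (decayed) is the reported object;
the raw g = g̃·e^{+ατ} is exposed with an explicit warning that the
re-inflation also amplifies posterior noise at large lags — for the same
reason the plug-in generative model used in the realism check simulates
directly on the decayed scale.  Cross-covariances between s and g̃ are
available for joint sampling but are a convenience, not a core output.

## Evaluation

Log-likelihood: Σ ln Λ(t_n) − ∫Λ (Gauss–Legendre).  Held-out performance
is the Monte-Carlo posterior average of the per-event log-likelihood,
with posterior functions drawn by sampling ϕ_c (or a stored Gibbs sample)
and projecting to (s, g̃) on dense grids.  Goodness of fit: the
time-rescaling transform z_k = 1 − exp(−∫_{t_{k−1}}^{t_k} Λ) followed by a
one-sample KS test against Uniform(0, 1) (exact null below n = 35,
asymptotic otherwise; 95% band half-width 1.36/√n).  Rescaling a fitted
model uses the plug-in posterior-mean intensity by default; a sampled
variant is available.

## Synthetic study conditions

The generator is first-class, tested code and defines the study
conditions:

- **Univariate standard scenario**: T = 1 s, λ = 180/s, a_s = a_g = 1,
  σ_s = 0.3 s, σ_g = 0.2 s, α = 10/s, prior α₀ = 2, β₀ = 0.02.  These
  values were chosen once so that a typical draw yields on the order of 90
  events per window (the default seed yields exactly 90); σ(ϕ) then
  traverses its informative range and the memory spans a few inter-event
  gaps.  Event counts across truth draws are strongly bimodal — the
  self-effect feedback pushes windows hot or quiet — which is a property
  of the model itself.
- **Mis-specified truth**: s(t) = β₁cos(θ₁t), g(t) = β₂cos(θ₂t) for
  testing inference on data not drawn from the GP model.
- **Two-dimensional scenario**: T = 3 s, λ_r = 60/s, GP backgrounds, one
  constant excitatory coupling g_{1,0} = 2 and all other influence
  functions zero.  The longer window is what makes the directed coupling
  separable from the backgrounds; at T = 1 s the four component functions
  are confounded and null pairs false-alarm.
- **Transient simulation**: no events before t = 0, so early times feel no
  self-effects; the thinning acceptance uses accepted candidates only.
  g is tabulated to lag_max = min(T, 10/α) and clamped to zero beyond.

What the generator does *not* emulate: stationary-regime data with
pre-window history, measurement jitter, refractory hard constraints, or
model mismatch beyond the cosine truth.  Passing tests therefore show
that the machinery recovers what it models, not that real recordings
satisfy the model.

## Known limitations

- λ and ϕ are only jointly identified through λσ(ϕ); the λ posterior
  typically sits below a simulation's bound while the intensity matches.
  The variational Gamma factor is also visibly narrower than the Gibbs λ
  posterior (a standard mean-field effect, asserted in the tests).
- Posterior shrinkage in near-silent stretches raises σ(ϕ̂) above truth
  there; a free-running plug-in resimulation of a fixed-hyperparameter fit
  can overshoot the training count by ~30% through the excitation loop.
  With hyperparameter tuning enabled (the full procedure) the overshoot on
  the standard scenario drops to ~11%.
- In the multivariate model, confounded designs (short windows, dense
  couplings) leak influence into self-effect estimates; the package
  reports per-pair posterior bands so such leakage is visible, but the
  design of the recording matters.
- Finite-difference hyperparameter gradients cost ~10 ELBO/Gram rebuilds
  per step; tuning is off by default.
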