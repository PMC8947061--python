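# nhgps — nonlinear Hawkes processes with Gaussian-process self-effects

Event sequences in neuroscience, criminology, seismology and social systems
are shaped by their own history: a spike, a burglary or an aftershock can
raise *or lower* the probability of the next event for a while.  Classical
Hawkes processes capture only excitation with a rigidly parameterised
memory kernel.  `nhgps` implements a Bayesian point-process model in which
both the background rate and the self-effect function are nonparametric GP
draws, so excitation and inhibition of arbitrary shape can be learned even
from a single short recording.

## Model

The conditional intensity of the univariate process is

```
Λ(t | H_t) = λ σ(ϕ(t)),       σ(x) = 1 / (1 + e^{-x}),
ϕ(t) = s(t) + Σ_{t_n < t} g(t − t_n) e^{−α (t − t_n)},
```

with independent zero-mean GP priors `s ~ GP(0, K_s)`, `g ~ GP(0, K_g)`
(RBF kernels `K(t, t') = a exp(−(t−t')²/σ²)`), a Gamma(α₀, β₀) prior on the
intensity bound λ, and an explicit exponential forgetting factor with rate
α.  Because ϕ is a sum of GPs it is itself a GP whose kernel aggregates
`K_s` with decayed `K_g` terms over the event history, and inference is
performed directly on ϕ.  In the R-dimensional extension each pair (r, m)
carries its own influence function `g_{r,m}`, and, given the observations,
the dimensions decouple and are fitted separately.

Inference uses Pólya–Gamma augmentation of the sigmoid plus a latent marked
Poisson process for the survival term, which makes every conditional
conjugate.  Two routes are provided:

- **mean-field variational inference** — closed-form coordinate-ascent
  updates for a Gamma factor on λ, a sparse-GP (inducing-point) factor on
  ϕ, tilted-PG factors at the events and a latent-process factor, with an
  ELBO trace and optional hyperparameter tuning by gradient steps;
- **blocked Gibbs sampling** — the exact-conditional MCMC baseline (latent
  points by fresh thinning, PG draws, a joint Gaussian for ϕ, conjugate λ).

After fitting, the posterior over ϕ is decomposed exactly into the
background `⟨s(t)⟩` and the decayed self-effect `⟨g̃(τ)⟩ = ⟨g(τ) e^{−ατ}⟩`
with marginal covariances, and goodness of fit is assessed by the
time-rescaling theorem with a Kolmogorov–Smirnov uniformity test.

## Worked example

```python
import numpy as np
from nhgps import VIConfig, fit_vi
from nhgps.simulate import standard_fixture
from nhgps.decompose import decompose

truth, events = standard_fixture()        # GP truth, 90 events in [0, 1) s
state = fit_vi(events, VIConfig(params=truth.params))
mean, var = state.posterior_phi(events.times)

true_phi = np.array([truth.phi(t, events.before(t)) for t in events.times])
dec = decompose(state)
```

which prints, with the quantities computed above:

```
simulated 90 events in [0, 1) s  (bound lambda = 180/s)
converged in 9 iterations, final ELBO 340.42
posterior mean intensity bound <lambda> = 150.2/s
corr(posterior mean phi, true phi) at events = 0.900
corr(<s>, true s) = 0.984
corr(<g~>, true g~) = 0.837
```

The linear intensity is recovered almost exactly at the observed events,
and the decomposition separates the slowly varying background from the
event-locked self-effect; λ itself is only weakly identified (many (λ, ϕ)
pairs give the same intensity), so its posterior mean sits below the
simulation bound while the intensity λσ(ϕ) matches.

The same workflow is available from the shell:

```
nhgps simulate --lam 180 --seed 1 --out events.csv
nhgps fit-vi --events events.csv --out state.npz
nhgps fit-gibbs --events events.csv --sweeps 5000 --burnin 1000 --out chain.npz
nhgps decompose --state state.npz --out decomposition.csv
nhgps evaluate --state state.npz --events test.csv --out report.json
```

## Layout

| module | contents |
| --- | --- |
| `nhgps.kernels` | RBF/decayed/aggregated covariances, Gram builders |
| `nhgps.simulate` | GP and cosine ground truths, thinning simulators |
| `nhgps.pg` | Pólya–Gamma integrand, tilted moments, exact sampler |
| `nhgps.vi` | mean-field updates, ELBO, hyperparameter steps, `fit_vi` |
| `nhgps.gibbs` | blocked Gibbs sampler and chain diagnostics |
| `nhgps.decompose` | posterior s/g̃ means, covariances, influence matrix |
| `nhgps.evaluate` | log-likelihoods, time rescaling, KS test |
| `nhgps.io` / `nhgps.cli` | CSV/JSON/NPZ I/O, pipeline, `nhgps` CLI |

See `docs/methods.md` for the modelling and numerical choices.
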