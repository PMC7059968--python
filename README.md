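# growthpop

Population modeling of experimental tumor growth curves and backward
prediction of the age of a tumor.

## The problem

Longitudinal tumor-size measurements in animal cohorts (caliper volumes or
fluorescence signals after injecting a known quantity of cells) carry two
kinds of structure at once: a growth law shared by the group, and
animal-to-animal variability around it. `growthpop` fits that structure as
a nonlinear mixed-effects (NLME) model and then uses it to answer a
*backward* question: given only the last three measurements of one animal,
how long ago did its tumor start?  In experimental cohorts the injection
time is known, so predictions can be scored against the truth — accuracy
(relative error of the predicted age), precision (width of the 95%
prediction interval) and coverage are evaluated by leave-one-out
cross-validation.  The backward problem is a proxy for estimating the age
of a clinical tumor at diagnosis, which informs the plausible extent of
invisible metastasis.

## Models

Each animal's size V(t) follows one of four laws, anchored at the injected
size V_inj at t = 0, with α defined as the specific growth rate
(1/V·dV/dt) at that size:

- exponential: dV/dt = α V
- logistic: dV/dt = ρ (1 − V/K) V
- Gompertz: dV/dt = (α − β log(V/V_inj)) V, carrying capacity
  K = V_inj·e^{α/β}
- **reduced Gompertz**: the Gompertz law with α = k·β, where k is a single
  population-level constant and β the only individual parameter.  The
  reduction is justified empirically: individual (α, β) estimates are
  almost perfectly proportional (random-effect correlation ≈ 0.98,
  per-animal R² > 0.9), implying an approximately common carrying capacity
  V_inj·e^k within a cohort.

Statistical layer: individual parameters are lognormal around the typical
values, log θᵢ = log μ + ηᵢ with ηᵢ ~ N(0, ω), and measurements follow the
combined error model yᵢⱼ = f(tᵢⱼ; θᵢ) + (σ₁ + σ₂ f)·εᵢⱼ.  Population
parameters φ = (μ, ω, σ) are estimated by SAEM (stochastic-approximation
EM with a Metropolis E-step); models are ranked by importance-sampled
−2 log L with AIC/BIC.

Tumor age is the closed-form inversion of the growth curve from the first
of the three retained points back to V_inj (for the Gompertz family,
â = (1/β)[log(α/β) − log(α/β − log(V_I/V_inj))]), estimated either by
three-point likelihood maximization with Fisher-information prediction
intervals, or by Bayesian inference using the population fit as prior
(adaptive Metropolis, 4 chains, 2000 retained draws of (θ, V_I)).

## Worked example

```python
from growthpop import PopulationModel, bayes_posterior_sample, tasks_from_cohort
from growthpop.simulate import design_preset, generate_cohort, population_preset

pop = population_preset("breast-volume", "gompertz")   # published typical values
cohort = generate_cohort(pop, design_preset("breast-volume"), seed=42)
fit = PopulationModel(cohort, "gompertz").fit(seed=1)
fit.loglik(M=2000, seed=2)
print(fit.summary())
```

```
Population fit: gompertz model, combined error, N = 66 animals, 572 observations
Par.            Estimate  omega (SD)   R.S.E.(%)
alpha             0.5758       0.189        2.62
beta             0.07134       0.274        3.85
sigma1             22.32           -        15.2
sigma2             0.108           -        8.05
random-effect correlation: 0.984
-2LL = 7103.0  AIC = 7117.0  BIC = 7132.3  (P = 7)
```

The cohort was generated with α = 0.58 d⁻¹, β = 0.072 d⁻¹ and
random-effect correlation 0.981; SAEM recovers them within a few percent,
with relative standard errors of the same order as the design permits.
Backward prediction from one animal's last three points:

```python
red = population_preset("breast-volume", "reduced_gompertz")
rcoh = generate_cohort(red, design_preset("breast-volume"), seed=7)
rfit = PopulationModel(rcoh, "reduced_gompertz").fit(seed=1, compute_rse=False)
task = tasks_from_cohort(rcoh, rfit.sigma)[0]
est = bayes_posterior_sample(task, rfit.params, seed=3)
print(f"true age {task.a_true:.0f} d, predicted {est.a_hat:.1f} d, "
      f"95% PI [{est.pi[0]:.1f}, {est.pi[1]:.1f}]")
```

```
true age 32 d, predicted 23.4 d, 95% PI [17.6, 30.5]
```

A command-line interface mirrors the library:
`growthpop simulate | fit-pop | diagnose | predict-age | crossval`
(see `growthpop --help`); every run writes a manifest with its seeds and
configuration hash.

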