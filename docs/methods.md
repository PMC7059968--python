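# Methods

This note documents the statistical model, the estimation machinery, the
synthetic-data generator and the numerical choices behind `growthpop`, in
enough detail to judge what its tests do and do not demonstrate.

## Structural and statistical model

Growth laws are solved in closed form from an arbitrary initial condition
(t_I, V_I); population analysis anchors every animal at (0, V_inj), the
size equivalent of the injected cells, and defines α as the specific
growth rate at that anchor.  The general Gompertz solution used throughout
is

    V(t) = V_inj · exp( α/β + (log(V_I/V_inj) − α/β) · e^{−β (t − t_I)} ),

which evaluates exactly both forward and backward in time; the reduced
model substitutes α = kβ.  Closed forms — never numerical ODE integration
— are used in all fitting loops; adaptive Runge–Kutta integration serves
only as a test oracle (agreement < 1e−6 relative).

The hierarchy is lognormal: log θᵢ = log μ + ηᵢ, ηᵢ ~ N(0, ω), which keeps
parameters positive without constraints.  Random-effect structure follows
the estimation conventions frozen into the parameter-counting rule:
Gompertz and the λ-variant carry a full 2×2 ω (including the α–β
correlation), logistic a diagonal ω, reduced Gompertz a scalar ω on β with
k a pure fixed effect.  With a combined error model this yields
P = 7/5/6/4 estimated scalars for Gompertz / reduced / logistic /
exponential, the convention that reproduces the published AIC/BIC rows
exactly (AIC = −2LL + 2P, BIC = −2LL + P·ln N with N the number of
animals).

**Observation model and positivity.**  Measurements are
y = f + (σ₁ + σ₂ f)·ε with ε standard normal.  Because sizes are positive,
the generator re-samples non-positive draws, i.e. it simulates the
zero-truncated version of this distribution.  The fitting likelihood uses
the matching truncated density by default (an extra −log Φ(f/g) per
observation, g = σ₁ + σ₂ f).  Wherever the signal dominates the additive
noise (Φ ≈ 1, the Gompertz-family regime) the correction is negligible;
it matters for the exponential model, whose large additive error
component (σ₁ = 272 mm³) would otherwise make the likelihood inconsistent
with the simulated data.  `positivity="plain"` restores the untruncated
form.  The three-point backward likelihood keeps the plain Gaussian form:
its measurements are late and large.

## SAEM estimation

Each iteration: (1) E-step — vectorized random-walk Metropolis updates of
all animals' log-parameters simultaneously (two full-covariance sweeps
using the Cholesky factor of the current ω, one component-wise sweep),
proposal scales adapted by Robbins–Monro towards 30–50% acceptance;
(2) stochastic approximation of the sufficient statistics Σφᵢ and Σφᵢφᵢᵀ
with step 1 during 300 exploratory iterations and 1/(it − 300) during 100
smoothing iterations; (3) exact M-step for (μ, ω) from the smoothed
statistics, with ω projected to its declared structure and floored at
1e−10; (4) the error parameters σ (and the reduced-model k) updated by
conditional-likelihood optimization given the current imputed parameters,
then smoothed with the same step sequence.  During exploration the
variance parameters are annealed — not allowed to shrink by more than 5%
per iteration — so the chains explore before the random effects collapse.
All iteration counts are configurable; the test suite trims them to
150/60 where the cohorts are small.

Initialization is deterministic: μ from a coarse pooled log-scale fit
(grid search over β or (ρ, K), late-time slope for the exponential), per-
animal starting values from individual log-scale least squares, σ from the
residuals against those individual fits, ω = 0.1·I.  Residuals against
individual fits (rather than the pooled curve) keep inter-animal
variability out of the initial σ, which otherwise traps the algorithm on
low-noise/high-variability cohorts.

**Likelihood, criteria, EBEs.**  −2 log L is estimated per animal by
importance sampling with a Student-t (df 5) proposal centered at the
conditional mode with Laplace covariance (default M = 10,000 draws; an
effective-sample-size fraction below 5% is flagged).  With ω = 0 the
integral degenerates and the exact conditional likelihood is returned.
Empirical Bayes estimates are conditional modes found by Nelder–Mead from
both the population value and the final MCMC state.  Relative standard
errors come from Fisher's identity: the per-animal marginal score equals
the conditional expectation of the complete-data score, estimated with a
post-fit Metropolis pass at the final estimate; the information matrix is
the sum of outer products of these expected scores.  This estimator is
consistent at the MLE and adds a fraction of a second per fit.

**Diagnostics.**  The visual predictive check simulates replicate cohorts
from the estimate on the observed design, bins time by quantiles (bins
with fewer than 3 observations are merged, with a warning) and compares
empirical 10/50/90th percentiles with the simulated percentiles' 90%
band.  IWRES = (y − f(θ̂ᵢ))/(σ̂₁ + σ̂₂ f(θ̂ᵢ)) uses the EBE plug-in; its
SD is deflated by fit shrinkage, roughly √(1 − p/nᵢ) ≈ 0.88 at 8–9 points
and 2 parameters, so a band of (0.8, 1.05) is the calibrated expectation
for a correctly specified model (residuals standardized under the
*generating* parameters have SD 1).

## Backward age prediction

A prediction task holds one animal's last three measurements with the
clock re-anchored at the first of them (t = 0, V_I = y₀); the true age is
the time from injection to that point.  Predicted age is the closed-form
inversion back to V_inj; draws whose V_I is at or above their carrying
capacity are infeasible, discarded and counted (over 50% discarded flags
the interval unreliable).

*Likelihood maximization.*  Nelder–Mead on γ = log θ (5 starts jittered
±50% around the population typical values, ties broken by the smallest
‖γ‖, plus restart polishing — the 3-point Gompertz surface is extremely
flat along the α–β ridge).  Error parameters come from the population fit
and are not re-estimated.  s² = Σ(weighted residuals)²/(3 − p);
the covariance of θ̂ is ∇g·(s²·I⁻¹)·∇g with ∇g = diag(θ̂) and I the
expected information of the heteroscedastic Gaussian,
I_lm = Σⱼ ∂f_l ∂f_m (1 + 2σ₂²)/gⱼ² (the variance term enters through
Σ = diag(g²); this form equals the negative expected Hessian of the
log-likelihood, verified against a finite-difference oracle).  A condition
number above 1e12 flags the information singular — common for the
two-parameter Gompertz on three points — and suppresses the interval;
otherwise the 95% PI maps 1000 Gaussian parameter draws through the age
formula.  With noise-free data and a purely additive error the estimate
interpolates exactly; with σ₂ > 0 the MLE legitimately trades a small
residual against a smaller predicted variance.

*Bayesian inference.*  The population fit on a training set provides the
lognormal prior (only β for the reduced model, k fixed at its population
value); V_I is a random variable N(y₀, σ₁ + σ₂y₀), re-drawn with every
posterior realization by sampling it jointly with θ.  The sampler is
component-wise adaptive random-walk Metropolis in whitened coordinates
z = L⁻¹(φ − μ) (essential when the prior correlation approaches 1), with
4 chains × 500 retained draws (thinning 4, 500 warmup iterations with
batch adaptation towards 44% acceptance).  Convergence is declared at
split-R̂ < 1.01 and bulk ESS > 400 (computed with arviz); the predicted
age is the posterior median and the PI the 2.5–97.5 percentiles.

*Evaluation.*  Leave-one-out cross-validation refits the prior on the
other N − 1 animals for every animal (`mode="faithful"`); `mode="fast"`
fits it once on all animals, a documented approximation that changes mean
accuracy by well under 2 percentage points on cohorts of a few dozen
animals.  Accuracy is the mean |relative error| in percent, precision the
mean 95%-PI width in days, coverage the fraction of animals whose true
age falls inside their interval; standard errors are SD/√N.  Animals with
singular LM information contribute to the error statistics but not the
interval statistics.  Paired method comparisons use the two-sided
Wilcoxon signed-rank test on absolute errors and Levene's test on
dispersion at α = 0.05 (identical vectors are degenerate and reported as
not significant).

## Synthetic cohorts

The generator is the package's definition of the study conditions, not a
tuning knob.  Three presets emulate the experimental designs: breast
cells measured by caliper volume (66 animals, V_inj = 1 mm³, follow-up
capped at 2000 mm³), lung cells by volume (20 animals, cap 1500 mm³) and
breast cells by fluorescence (8 animals, V_inj = 1.22·10⁷ photons/s,
proportional error — σ₁ fixed to 0).  Population-parameter presets carry
the published breast-volume values for all four growth laws (e.g.
Gompertz α = 0.58 d⁻¹, β = 0.072 d⁻¹, random-effect SDs 0.19/0.26,
correlation 0.981, σ = [20.5, 0.11]); the lung and fluorescence values
are plausible settings chosen once for that tumor type (faster LLC
growth, k = 9.42 matching a ~12,300 mm³ capacity; near-unity correlation
0.998 for fluorescence).

Measurement schedules are twice weekly (thrice for the fast-growing lung
line) from the day tumors reach palpable size — day 11 for the breast
design, day 8 for lung — to the day the typical animal approaches the
follow-up cap.  Starting at palpable size rather than at injection
reflects caliper practice and keeps the additive noise from dominating
the early signal; the nominal totals reproduce the experimental ones
(~580 observations/66 animals, ~190/20, 64/8).  Follow-up stops at the
first measurement exceeding the cap, which is kept (the measurement that
triggers sacrifice is recorded).  One master seed; per-animal streams are
spawned from it, so cohorts are reproducible and order-independent.
Two documented quirks: the printed fluorescence inoculum (1.22·10⁷
photons/s) is used as-is although 80,000 cells at the printed
1.52·10⁹ photons/(s·mm³) calibration ratio would imply a larger value;
and the generator does not emulate caliper geometry (π/6·w²·L) or imaging
physics — noise enters only through the combined error model.

What passing tests show — and don't.  Recovery, coverage and
discrimination results hold under a correctly specified generator whose
noise is exactly the fitted error model.  Real cohorts add schedule
irregularity, pooled experiments, measurement-geometry error and possible
growth-law misspecification; the diagnostics (VPC, IWRES,
observations-vs-predictions) are the tools for judging those, not the
synthetic benchmarks.

## Numerical choices and limitations

- Exponents are capped at 700 before `exp` so optimizer excursions return
  finite (huge) sizes instead of overflowing.
- ω updates are symmetrized, eigenvalue-floored at 1e−10 and projected to
  the declared structure; the error SD g is floored at 1e−12.
- The α–β regression defaults to a through-origin fit (the intercept is
  empirically small); `fit_intercept=True` estimates it.  R² is computed
  against the centered total sum of squares in both cases.
- On self-consistent synthetic cohorts the per-animal contrast between
  reduced and full-Gompertz Bayesian interval widths is often a near-tie
  (the correlated Gompertz prior is nearly as informative as the reduced
  one); the mean-width ordering — reduced narrower — is the robust
  pattern, and the one asserted.
- Backward prediction is implemented for the Gompertz family only; the
  exponential and logistic laws are population-analysis comparators.
- Forward prediction of future tumor size, treatment-perturbed growth,
  the generalized-logistic law and clinical translation (single-cell
  V_c = 10⁻⁶ mm³) are out of scope.
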