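"""Backward prediction of the age of a tumor from its last three measurements.

The age of a tumor is the time elapsed between initiation (the injection,
size ``V_inj``) and the first of the three retained measurements.  The
curve is re-anchored at that first point: times are re-indexed so t = 0 at
t_{n-2} and the initial size V_I is that measurement.  Two estimation
routes are provided:

* likelihood maximization (LM): Nelder-Mead maximization of the
  three-point Gaussian log-likelihood over log-parameters, with
  delta-method prediction intervals from the Fisher information matrix
  (often singular for the two-parameter Gompertz, which is flagged);
* Bayesian inference: the population fit on a training set provides a
  lognormal prior; the posterior over (parameters, V_I) is sampled by
  adaptive random-walk Metropolis (4 chains, 500 retained draws each by
  default), V_I being a random variable around the first measurement to
  account for its own measurement error.

Both return the predicted age and a 95% prediction interval; ages of
infeasible draws (initial size at or above the drawn carrying capacity)
are discarded and their fraction reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .models import InjectionSpec, age_from_theta, curve_from_VI
from .params import PopulationParams

__all__ = [
    "PredictionTask",
    "LMEstimate",
    "BayesEstimate",
    "AgePredictionResult",
    "tasks_from_cohort",
    "loglik_last3",
    "lm_fit_last3",
    "fisher_information",
    "lm_prediction_interval",
    "bayes_posterior_sample",
    "predict_age",
]

_LOG2PI = math.log(2.0 * math.pi)
_SINGULAR_COND = 1e12

# fall-back reference values for LM multi-starts when no prior is given
_DEFAULT_THETA_REF = {"gompertz": np.array([0.58, 0.072]),
                      "reduced_gompertz": np.array([0.075])}


@dataclass(frozen=True)
class PredictionTask:
    """Three last measurements of one animal, re-anchored at the first."""

    animal_id: object
    times: np.ndarray  # shape (3,), times[0] == 0
    y: np.ndarray      # shape (3,), positive
    a_true: float      # actual age: days from injection to times[0]
    inj: InjectionSpec
    sigma: np.ndarray  # error parameters from the population fit

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.times.shape != (3,) or self.y.shape != (3,):
            raise ValueError("a prediction task holds exactly 3 observations")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.times[0]) > 1e-9:
            raise ValueError("times must be re-indexed so the first is 0")
        if np.any(self.y <= 0):
            raise ValueError("measurements must be positive")

    @property
    def V_I(self) -> float:
        return float(self.y[0])


def tasks_from_cohort(cohort, sigma, min_obs: int = 3):
    """Build one task per animal with at least three observations."""
    tasks = []
    for animal, t, y in cohort.per_animal():
        if len(t) < min_obs:
            continue
        t3, y3 = t[-3:], y[-3:]
        tasks.append(PredictionTask(
            animal_id=animal, times=t3 - t3[0], y=y3, a_true=float(t3[0]),
            inj=cohort.inj, sigma=np.asarray(sigma, dtype=float)))
    return tasks


def _fixed_for(model_name, k_pop):
    if model_name == "reduced_gompertz":
        if k_pop is None:
            raise ValueError("reduced_gompertz needs the population k")
        return {"k": float(k_pop)}
    return None


def _f3(model_name, theta, task, V_I=None, k_pop=None):
    V_I = task.V_I if V_I is None else V_I
    return curve_from_VI(model_name, theta, task.times, V_I,
                         task.inj.V_inj, _fixed_for(model_name, k_pop))


def loglik_last3(theta, task, model_name, V_I=None, k_pop=None):
    """Three-point Gaussian log-likelihood of the combined error model."""
    f = _f3(model_name, np.asarray(theta, dtype=float), task, V_I, k_pop)
    g = np.maximum(task.sigma[0] + task.sigma[1] * f, 1e-12)
    z = (task.y - f) / g
    return float(np.sum(-np.log(g) - 0.5 * z * z - 0.5 * _LOG2PI))


@dataclass
class LMEstimate:
    model_name: str
    theta_hat: np.ndarray
    gamma_hat: np.ndarray
    cov: np.ndarray | None
    s2: float
    a_hat: float | None
    pi: tuple | None
    singular: bool
    infeasible_fraction: float = 0.0
    unreliable_pi: bool = False
    k_pop: float | None = None


def lm_fit_last3(task: PredictionTask, model_name: str = "reduced_gompertz",
                 k_pop: float | None = None, theta_ref=None, n_starts: int = 5,
                 seed: int = 0, n_draws: int = 1000) -> LMEstimate:
    """Maximum-likelihood age estimate from the three last points.

    The optimization runs on gamma = log(theta) (positivity by
    construction) with Nelder-Mead from ``n_starts`` starting points
    jittered +-50% around ``theta_ref`` (population typical values); ties
    are broken by the smallest ||gamma||.  The error parameters are taken
    from the population fit and not re-estimated.
    """
    p = 2 if model_name == "gompertz" else 1
    if theta_ref is None:
        theta_ref = _DEFAULT_THETA_REF[model_name]
    theta_ref = np.asarray(theta_ref, dtype=float)
    rng = np.random.default_rng(seed)

    def neg_ll(gamma):
        return -loglik_last3(np.exp(gamma), task, model_name, k_pop=k_pop)

    gamma0 = np.log(theta_ref)
    starts = [gamma0]
    starts += [gamma0 + np.log(rng.uniform(0.5, 1.5, size=p))
               for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = minimize(neg_ll, x0, method="Nelder-Mead",
                       options={"maxiter": 800, "xatol": 1e-8, "fatol": 1e-10})
        key = (round(res.fun, 6), float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    # restart from the incumbent: the 3-point surface is extremely flat
    # along the alpha-beta ridge and a fresh simplex sharpens the optimum
    for _ in range(3):
        res2 = minimize(neg_ll, res.x, method="Nelder-Mead",
                        options={"maxiter": 800, "xatol": 1e-12, "fatol": 1e-14})
        if res2.fun >= res.fun - 1e-14:
            res = res2 if res2.fun < res.fun else res
            break
        res = res2
    gamma_hat = res.x
    theta_hat = np.exp(gamma_hat)
    f = _f3(model_name, theta_hat, task, k_pop=k_pop)
    g = np.maximum(task.sigma[0] + task.sigma[1] * f, 1e-12)
    s2 = float(np.sum(((task.y - f) / g) ** 2)) / (3 - p)

    fim = fisher_information(gamma_hat, task, model_name, k_pop=k_pop)
    cond = np.linalg.cond(fim)
    singular = (not np.all(np.isfinite(fim))) or cond > _SINGULAR_COND
    cov = None
    if not singular:
        grad_g = np.diag(theta_hat)  # gradient of theta = e^gamma
        cov = grad_g @ (s2 * np.linalg.inv(fim)) @ grad_g
    age = age_from_theta(model_name, theta_hat, task.V_I, task.inj.V_inj,
                         _fixed_for(model_name, k_pop))
    a_hat = float(age) if np.isfinite(age) else None
    est = LMEstimate(model_name=model_name, theta_hat=theta_hat,
                     gamma_hat=gamma_hat, cov=cov, s2=s2, a_hat=a_hat,
                     pi=None, singular=singular, k_pop=k_pop)
    if not singular:
        lm_prediction_interval(est, task, n_draws=n_draws, seed=seed + 1)
    return est


def fisher_information(gamma, task: PredictionTask, model_name: str,
                       k_pop: float | None = None, step: float = 1e-6):
    """Expected information of the three-point likelihood at gamma.

    For the heteroscedastic Gaussian y_j ~ N(f_j, (s1 + s2 f_j)^2),

        I_lm = sum_j df_j/dgamma_l df_j/dgamma_m (1 + 2 s2^2) / g_j^2,

    the mean term plus the variance term of the Gaussian information
    identity (the variance depends on gamma only through f).  Derivatives
    of f are central finite differences on the log scale.
    """
    gamma = np.asarray(gamma, dtype=float)
    p = gamma.size
    derivs = np.empty((p, 3))
    for l in range(p):
        e = np.zeros(p)
        e[l] = step
        fp = _f3(model_name, np.exp(gamma + e), task, k_pop=k_pop)
        fm = _f3(model_name, np.exp(gamma - e), task, k_pop=k_pop)
        derivs[l] = (fp - fm) / (2 * step)
    f = _f3(model_name, np.exp(gamma), task, k_pop=k_pop)
    g = np.maximum(task.sigma[0] + task.sigma[1] * f, 1e-12)
    w = (1.0 + 2.0 * task.sigma[1] ** 2) / g**2
    fim = (derivs * w) @ derivs.T
    if not np.all(np.isfinite(fim)):
        raise FloatingPointError("non-finite Fisher information entries")
    return fim


def lm_prediction_interval(est: LMEstimate, task: PredictionTask,
                           n_draws: int = 1000, seed: int = 0,
                           level: float = 95.0):
    """Delta-method 95% PI: parameter draws from N(theta_hat, cov) mapped
    through the age formula; infeasible draws discarded and counted."""
    if est.cov is None:
        raise ValueError("no covariance available (singular information)")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(est.theta_hat, est.cov, size=n_draws,
                                    method="svd")
    valid = np.all(draws > 0, axis=1)
    ages = np.full(n_draws, np.nan)
    if valid.any():
        ages[valid] = age_from_theta(est.model_name, draws[valid], task.V_I,
                                     task.inj.V_inj,
                                     _fixed_for(est.model_name, est.k_pop))
    ok = np.isfinite(ages)
    est.infeasible_fraction = 1.0 - ok.sum() / n_draws
    est.unreliable_pi = est.infeasible_fraction > 0.5
    if ok.sum() >= 2:
        lo, hi = np.percentile(ages[ok], [(100 - level) / 2,
                                          100 - (100 - level) / 2])
        est.pi = (float(lo), float(hi))
    else:
        est.pi = None
        est.unreliable_pi = True
    return est.pi


# ---------------------------------------------------------------------------
# Bayesian route
# ---------------------------------------------------------------------------

@dataclass
class BayesEstimate:
    model_name: str
    draws_theta: np.ndarray  # (n, d) natural scale
    draws_VI: np.ndarray
    ages: np.ndarray         # feasible age draws
    a_hat: float
    pi: tuple
    infeasible_fraction: float
    rhat: float
    ess: float
    converged: bool
    k_pop: float | None = None


class AllInfeasibleError(RuntimeError):
    pass


def _adaptive_metropolis(logpost, x0, n_keep, warmup, thin, rng, scale0):
    """Component-wise adaptive random-walk Metropolis, vectorized over chains.

    ``logpost`` maps an (C, d) state matrix to a length-C vector; ``x0`` is
    (C, d).  Per-component proposal scales are adapted per chain during
    warmup towards the 0.44 scalar-update target.  Returns (C, n_keep, d).
    """
    C, d = x0.shape
    x = x0.copy()
    lp = logpost(x)
    log_s = np.tile(np.log(np.asarray(scale0, dtype=float)), (C, 1))
    kept = np.empty((C, n_keep, d))
    n_iter = warmup + n_keep * thin
    acc = np.zeros((C, d))
    batch = 0
    for it in range(n_iter):
        for j in range(d):
            prop = x.copy()
            prop[:, j] += np.exp(log_s[:, j]) * rng.standard_normal(C)
            lp_prop = logpost(prop)
            accept = np.log(rng.uniform(size=C)) < lp_prop - lp
            x[accept] = prop[accept]
            lp = np.where(accept, lp_prop, lp)
            acc[:, j] += accept
        if it < warmup and (it + 1) % 25 == 0:
            batch += 1
            delta = min(0.1, 1.0 / math.sqrt(batch))
            log_s += np.where(acc / 25.0 > 0.44, delta, -delta)
            acc[:] = 0.0
        if it >= warmup and (it - warmup) % thin == thin - 1:
            kept[:, (it - warmup) // thin] = x
    return kept


def bayes_posterior_sample(task: PredictionTask, prior: PopulationParams,
                           n_draws: int = 2000, chains: int = 4,
                           warmup: int = 500, thin: int = 4,
                           seed: int = 0) -> BayesEstimate:
    """Posterior draws of (theta, V_I) and the implied age distribution.

    The lognormal population distribution from the training fit is the
    prior on theta (only beta for the reduced model, with k fixed at its
    population value); V_I is a random variable N(y_0, s1 + s2 y_0)
    re-drawn with every realization.  Sampling is adaptive random-walk
    Metropolis with ``chains`` chains of ``n_draws / chains`` retained
    draws; convergence is checked by split-Rhat < 1.01 and bulk ESS > 400.
    """
    model_name = prior.model_name
    k_pop = prior.fixed.get("k")
    sigma = task.sigma
    y0 = task.V_I
    g0 = float(sigma[0] + sigma[1] * y0)
    m = np.log(prior.mu)
    d = prior.n_random
    omega = prior.omega
    active = np.diag(omega) > 1e-12
    d_act = int(active.sum())
    if d_act:
        om_act = omega[np.ix_(active, active)]
        # whitened coordinates: z = L^-1 (phi - m) mixes well even when the
        # prior correlation is close to 1 (the Gompertz alpha-beta ridge)
        L_act = np.linalg.cholesky(om_act + 1e-14 * np.eye(d_act))
    keep_per_chain = max(n_draws // chains, 1)

    V_inj = task.inj.V_inj
    times = task.times

    def logpost(x):
        # x: (C, d_act + 1) whitened state -> (C,)
        C = x.shape[0]
        phi = np.tile(m, (C, 1))
        if d_act:
            phi[:, active] = m[active] + x[:, :d_act] @ L_act.T
        V_I = x[:, d_act]
        ok = V_I > 0
        lp = np.full(C, -np.inf)
        V_safe = np.where(ok, V_I, 1.0)
        theta = np.exp(phi)
        if model_name == "gompertz":
            alpha, beta = theta[:, 0], theta[:, 1]
        else:
            beta = theta[:, 0]
            alpha = k_pop * beta
        ab = alpha / beta
        logV = (math.log(V_inj) + ab[:, None]
                + (np.log(V_safe / V_inj) - ab)[:, None]
                * np.exp(-beta[:, None] * times[None, :]))
        f = np.exp(np.minimum(logV, 700.0))
        g = np.maximum(sigma[0] + sigma[1] * f, 1e-12)
        z = (task.y[None, :] - f) / g
        ll = np.sum(-np.log(g) - 0.5 * z * z - 0.5 * _LOG2PI, axis=1)
        prior = -0.5 * ((V_I - y0) / g0) ** 2
        if d_act:
            prior = prior - 0.5 * np.sum(x[:, :d_act] ** 2, axis=1)
        lp[ok] = (ll + prior)[ok]
        return lp

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x0 = np.concatenate([
        0.5 * rng.standard_normal((chains, d_act)),
        np.maximum(y0 * (1.0 + 0.1 * rng.standard_normal((chains, 1))),
                   0.1 * y0),
    ], axis=1)
    scale0 = np.concatenate([np.ones(d_act), [0.5 * max(g0, 1e-6)]])
    all_draws = _adaptive_metropolis(
        logpost, x0, keep_per_chain, warmup, thin, rng, scale0)

    rhat, ess = _convergence_diagnostics(all_draws)
    converged = bool(rhat < 1.01 and ess > 400)

    flat = all_draws.reshape(-1, d_act + 1)
    phi_draws = np.tile(m, (flat.shape[0], 1))
    if d_act:
        phi_draws[:, active] = m[active] + flat[:, :d_act] @ L_act.T
    theta_draws = np.exp(phi_draws)
    VI_draws = flat[:, d_act]
    ages = age_from_theta(model_name, theta_draws, VI_draws, task.inj.V_inj,
                          _fixed_for(model_name, k_pop))
    ok = np.isfinite(ages)
    infeasible = 1.0 - ok.sum() / ages.size
    if not ok.any():
        raise AllInfeasibleError(
            f"all posterior draws infeasible for animal {task.animal_id}")
    valid_ages = ages[ok]
    lo, hi = np.percentile(valid_ages, [2.5, 97.5])
    return BayesEstimate(
        model_name=model_name, draws_theta=theta_draws, draws_VI=VI_draws,
        ages=valid_ages, a_hat=float(np.median(valid_ages)),
        pi=(float(lo), float(hi)), infeasible_fraction=float(infeasible),
        rhat=float(rhat), ess=float(ess), converged=converged, k_pop=k_pop)


def _convergence_diagnostics(draws):
    """Max split-Rhat and min bulk ESS across dimensions (via arviz)."""
    import arviz as az

    ds = az.convert_to_dataset({"x": draws})
    rhat = float(np.nanmax(az.rhat(ds)["x"].values))
    ess = float(np.nanmin(az.ess(ds)["x"].values))
    return rhat, ess


@dataclass
class AgePredictionResult:
    animal_id: object
    method: str  # "LM" | "Bayesian"
    model_name: str
    a_true: float
    a_hat: float | None
    pi: tuple | None
    valid: bool
    flags: dict = field(default_factory=dict)

    @property
    def relative_error(self) -> float | None:
        if self.a_hat is None or self.a_true == 0:
            return None
        return (self.a_hat - self.a_true) / self.a_true

    @property
    def pi_width(self) -> float | None:
        return None if self.pi is None else self.pi[1] - self.pi[0]

    @property
    def covered(self) -> bool | None:
        if self.pi is None:
            return None
        return self.pi[0] <= self.a_true <= self.pi[1]


def predict_age(estimate, task: PredictionTask) -> AgePredictionResult:
    """Uniform view of an LM or Bayesian estimate as an age prediction."""
    if isinstance(estimate, LMEstimate):
        flags = {"singular_fim": estimate.singular,
                 "unreliable_pi": estimate.unreliable_pi,
                 "infeasible_fraction": estimate.infeasible_fraction}
        return AgePredictionResult(
            animal_id=task.animal_id, method="LM",
            model_name=estimate.model_name, a_true=task.a_true,
            a_hat=estimate.a_hat, pi=estimate.pi,
            valid=estimate.a_hat is not None, flags=flags)
    if isinstance(estimate, BayesEstimate):
        flags = {"infeasible_fraction": estimate.infeasible_fraction,
                 "rhat": estimate.rhat, "ess": estimate.ess,
                 "non_converged": not estimate.converged}
        return AgePredictionResult(
            animal_id=task.animal_id, method="Bayesian",
            model_name=estimate.model_name, a_true=task.a_true,
            a_hat=estimate.a_hat, pi=estimate.pi, valid=True, flags=flags)
    raise TypeError(type(estimate))
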