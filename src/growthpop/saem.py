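"""Stochastic-approximation EM (SAEM) engine for the growth-law NLME models.

The hierarchical model is

    y_ij = f(t_ij; theta_i) + (sigma1 + sigma2 f) eps_ij,   eps ~ N(0, 1)
    log theta_i = m + eta_i,                                eta ~ N(0, omega)

with f a closed-form growth curve started at (0, V_inj).  Sizes are
positive, and when the generator conditions the noise on positivity the
matching zero-truncated Gaussian density is used (``positivity="truncated"``,
an extra ``-log Phi(f/g)`` per observation; negligible whenever the signal
dwarfs the additive noise).

One SAEM iteration performs
  1. an E-step: vectorized random-walk Metropolis moves of the individual
     log-parameters phi_i = log theta_i across all animals at once
     (full-covariance and component-wise kernels, proposal scale adapted to
     30-50% acceptance);
  2. a stochastic-approximation update of the sufficient statistics
     (sum phi_i, sum phi_i phi_i^T) with step 1 during exploration and
     1/(iter - K1) during smoothing;
  3. exact M-step updates of (m, omega) from the smoothed statistics, and
     smoothed conditional-likelihood optimization of sigma (and of extra
     fixed effects such as the reduced-Gompertz k).

During the exploratory phase the variance parameters are annealed (not
allowed to shrink faster than 5% per iteration) so the chains explore
before the random effects collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, log_ndtr, logsumexp

from .models import FIXED_PARAM_NAMES, RANDOM_PARAM_NAMES, curve_population

__all__ = ["SAEMSettings", "FitError", "SAEMProblem", "run_saem"]

_LOG2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """SAEM divergence; carries the convergence trace for post-mortem."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class SAEMSettings:
    n_exploration: int = 300
    n_smoothing: int = 100
    n_mh_full: int = 2
    n_mh_comp: int = 1
    target_accept: float = 0.35
    anneal: float = 0.95
    n_score_iters: int = 200
    omega_floor: float = 1e-10


class SAEMProblem:
    """Data + model bound together with vectorized likelihood evaluations."""

    def __init__(self, cohort, model_name, error_model="combined",
                 positivity="truncated", omega_structure=None):
        if model_name not in RANDOM_PARAM_NAMES:
            raise ValueError(f"unknown model {model_name!r}")
        self.model_name = model_name
        self.error_model = error_model
        self.positivity = positivity
        self.t, self.y, self.idx, self.N = cohort.flat_arrays()
        self.V_inj = cohort.inj.V_inj
        self.d = len(RANDOM_PARAM_NAMES[model_name])
        self.static_fixed = {}
        if model_name == "lambda_gompertz":
            if cohort.inj.lambda_invitro is None:
                raise ValueError("lambda_gompertz needs InjectionSpec.lambda_invitro")
            self.static_fixed["lambda_invitro"] = cohort.inj.lambda_invitro
        self.estimated_fixed_names = FIXED_PARAM_NAMES[model_name]
        if omega_structure is None:
            omega_structure = "full" if model_name in ("gompertz", "lambda_gompertz") else "diagonal"
        self.omega_structure = omega_structure
        self.n_per_animal = np.bincount(self.idx, minlength=self.N)

    # -- likelihood ---------------------------------------------------------

    def _fixed(self, fixed_estimates):
        out = dict(self.static_fixed)
        if fixed_estimates:
            out.update(fixed_estimates)
        return out

    def predict(self, phi, fixed_estimates=None):
        """Model curve per observation for individual log-params phi (N,d)."""
        theta = np.exp(phi)
        return curve_population(self.model_name, theta[self.idx], self.t,
                                self.V_inj, self._fixed(fixed_estimates))

    def obs_loglik_from_f(self, f, sigma):
        """Per-observation log density given the predicted curve."""
        g = np.maximum(sigma[0] + sigma[1] * f, 1e-12)
        z = (self.y - f) / g
        ll = -np.log(g) - 0.5 * z * z - 0.5 * _LOG2PI
        if self.positivity == "truncated":
            ll = ll - log_ndtr(f / g)
        return ll

    def individual_loglik(self, phi, sigma, fixed_estimates=None):
        """Conditional log p(y_i | phi_i) per animal, shape (N,)."""
        f = self.predict(phi, fixed_estimates)
        ll = self.obs_loglik_from_f(f, sigma)
        return np.bincount(self.idx, weights=ll, minlength=self.N)

    def single_animal_loglik(self, i, phi_i, sigma, fixed_estimates=None):
        mask = self.idx == i
        t, y = self.t[mask], self.y[mask]
        theta = np.exp(np.atleast_2d(phi_i))
        f = curve_population(self.model_name, theta[:, None, :], t[None, :],
                             self.V_inj, self._fixed(fixed_estimates))
        g = np.maximum(sigma[0] + sigma[1] * f, 1e-12)
        z = (y[None, :] - f) / g
        ll = -np.log(g) - 0.5 * z * z - 0.5 * _LOG2PI
        if self.positivity == "truncated":
            ll = ll - log_ndtr(f / g)
        out = ll.sum(axis=1)
        return out[0] if np.ndim(phi_i) == 1 else out


def _prior_loglik(phi, m, omega_inv, omega_logdet):
    dev = phi - m
    quad = np.einsum("nd,de,ne->n", dev, omega_inv, dev)
    d = phi.shape[1]
    return -0.5 * (quad + omega_logdet + d * _LOG2PI)


def _safe_inv(omega, floor=1e-10):
    w, V = np.linalg.eigh(omega)
    w = np.maximum(w, floor)
    inv = (V / w) @ V.T
    logdet = float(np.sum(np.log(w)))
    return inv, logdet


def _project_omega(omega, structure, floor):
    omega = 0.5 * (omega + omega.T)
    if structure == "diagonal" or omega.shape[0] == 1:
        omega = np.diag(np.diag(omega))
    w, V = np.linalg.eigh(omega)
    if w.min() < floor:
        omega = (V * np.maximum(w, floor)) @ V.T
        if structure == "diagonal" or omega.shape[0] == 1:
            omega = np.diag(np.diag(omega))
    return omega


# -- initialization ---------------------------------------------------------

def naive_pooled_fit(problem: SAEMProblem):
    """Deterministic pooled starting values (mu, sigma, extra fixed effects).

    A coarse grid/least-squares fit of the structural curve to the pooled
    data on the log scale, then a small Gaussian-likelihood fit of sigma on
    the pooled residuals.
    """
    t, y, V_inj = problem.t, problem.y, problem.V_inj
    logy = np.log(y)
    name = problem.model_name
    fixed = {}
    if name == "exponential":
        # late times: the signal dwarfs the additive noise there
        late = t >= np.median(t)
        slope = max(np.polyfit(t[late], logy[late], 1)[0], 1e-3)
        mu = np.array([slope])
    elif name in ("gompertz", "reduced_gompertz", "lambda_gompertz"):
        betas = np.geomspace(0.01, 0.5, 40)
        best = None
        for b in betas:
            x = 1.0 - np.exp(-b * t)
            if name == "lambda_gompertz":
                lam = problem.static_fixed["lambda_invitro"]
                # log V = log V_hat + (lam/b) x
                c = float(np.mean(logy - (lam / b) * x))
                sse = float(np.sum((logy - c - (lam / b) * x) ** 2))
                cand = (sse, b, c)
            else:
                a = float(np.dot(x, logy - math.log(V_inj)) / np.dot(x, x))
                sse = float(np.sum((logy - math.log(V_inj) - a * x) ** 2))
                cand = (sse, b, a)
            if best is None or cand[0] < best[0]:
                best = cand
        _, b, a = best
        if name == "gompertz":
            mu = np.array([max(a, 0.1) * b, b])
        elif name == "reduced_gompertz":
            mu = np.array([b])
            fixed["k"] = max(a, 0.1)
        else:
            mu = np.array([b, max(math.exp(a), 1e-6 * V_inj)])
    elif name == "logistic":
        # coarse log-scale SSE grid over (rho, K)
        ymax = float(np.max(y))
        rhos = np.geomspace(0.03, 1.5, 40)
        Ks = np.geomspace(0.4 * ymax, 4.0 * ymax, 25)
        R, Kg = np.meshgrid(rhos, Ks, indexing="ij")
        e = np.exp(np.minimum(R[..., None] * t[None, None, :], 500.0))
        logf = np.log(Kg[..., None] * V_inj * e
                      / (Kg[..., None] + V_inj * (e - 1.0)))
        sse = np.sum((logf - logy[None, None, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        mu = np.array([rhos[i], Ks[j]])
    else:  # pragma: no cover
        raise ValueError(name)

    # per-animal refinement: log-scale least squares from the pooled start;
    # residuals against individual fits separate measurement noise from
    # inter-animal variability when initializing sigma
    phi0 = _individual_phi_init(problem, np.log(mu), fixed)
    f0 = problem.predict(phi0, fixed)
    r = np.abs(y - f0)
    med = max(float(np.median(r)), 1e-6)

    def nll_sigma(x):
        s = np.exp(x)
        sigma = np.array([0.0, s[0]]) if problem.error_model == "proportional" else s
        return -problem.obs_loglik_from_f(f0, sigma).sum()

    if problem.error_model == "proportional":
        x0 = np.log([max(med / max(np.median(f0), 1e-9), 1e-3)])
    else:
        x0 = np.log([med, max(med / max(np.median(f0), 1e-9), 1e-3)])
    res = minimize(nll_sigma, x0, method="Nelder-Mead",
                   options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-3})
    s = np.exp(res.x)
    sigma0 = np.array([0.0, s[0]]) if problem.error_model == "proportional" else s
    return mu, sigma0, fixed, phi0


def _individual_phi_init(problem, m, fixed):
    """Per-animal log-scale least-squares starting values for phi."""
    phi0 = np.empty((problem.N, problem.d))
    for i in range(problem.N):
        mask = problem.idx == i
        t_i, logy_i = problem.t[mask], np.log(problem.y[mask])

        def sse(p):
            theta = np.exp(p)[None, :]
            f = curve_population(problem.model_name, theta[:, None, :],
                                 t_i[None, :], problem.V_inj,
                                 problem._fixed(fixed))
            return float(np.sum((np.log(np.maximum(f[0], 1e-300)) - logy_i) ** 2))

        res = minimize(sse, m, method="Nelder-Mead",
                       options={"maxiter": 300, "xatol": 1e-6, "fatol": 1e-10})
        phi0[i] = res.x if np.all(np.isfinite(res.x)) else m
    return phi0


# -- conditional M-step pieces ---------------------------------------------

def _optimize_sigma(problem, f, sigma):
    def nll(x):
        s = np.exp(x)
        sig = np.array([0.0, s[0]]) if problem.error_model == "proportional" else s
        return -problem.obs_loglik_from_f(f, sig).sum()

    if problem.error_model == "proportional":
        x0 = np.log([max(sigma[1], 1e-8)])
    else:
        x0 = np.log(np.maximum(sigma, 1e-8))
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 120, "xatol": 1e-4, "fatol": 1e-4})
    s = np.exp(res.x)
    return np.array([0.0, s[0]]) if problem.error_model == "proportional" else s


def _optimize_k(problem, phi, sigma, k):
    def nll(kval):
        return -problem.individual_loglik(phi, sigma, {"k": kval}).sum()

    res = minimize_scalar(nll, bounds=(0.3 * k, 3.0 * k), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


# -- main loop --------------------------------------------------------------

@dataclass
class SAEMState:
    m: np.ndarray
    omega: np.ndarray
    sigma: np.ndarray
    fixed: dict
    phi: np.ndarray
    trace: list = field(default_factory=list)
    accept_rate: float = 0.0


def _mh_sweeps(problem, phi, cur_ll, m, omega, sigma, fixed, rng, scales, settings):
    """In-place Metropolis sweeps over all animals; returns updated state."""
    omega_inv, omega_logdet = _safe_inv(omega)
    L = np.linalg.cholesky(omega + 1e-10 * np.eye(problem.d))
    cur_prior = _prior_loglik(phi, m, omega_inv, omega_logdet)
    n_acc = n_prop = 0
    for _ in range(settings.n_mh_full):
        step = scales["full"] * (rng.standard_normal((problem.N, problem.d)) @ L.T)
        cand = phi + step
        cand_ll = problem.individual_loglik(cand, sigma, fixed)
        cand_prior = _prior_loglik(cand, m, omega_inv, omega_logdet)
        logr = (cand_ll + cand_prior) - (cur_ll + cur_prior)
        accept = np.log(rng.uniform(size=problem.N)) < logr
        phi[accept] = cand[accept]
        cur_ll = np.where(accept, cand_ll, cur_ll)
        cur_prior = np.where(accept, cand_prior, cur_prior)
        n_acc += int(accept.sum()); n_prop += problem.N
    sd = np.sqrt(np.maximum(np.diag(omega), 1e-10))
    for _ in range(settings.n_mh_comp):
        for j in range(problem.d):
            cand = phi.copy()
            cand[:, j] += scales["comp"] * sd[j] * rng.standard_normal(problem.N)
            cand_ll = problem.individual_loglik(cand, sigma, fixed)
            cand_prior = _prior_loglik(cand, m, omega_inv, omega_logdet)
            logr = (cand_ll + cand_prior) - (cur_ll + cur_prior)
            accept = np.log(rng.uniform(size=problem.N)) < logr
            phi[accept] = cand[accept]
            cur_ll = np.where(accept, cand_ll, cur_ll)
            cur_prior = np.where(accept, cand_prior, cur_prior)
            n_acc += int(accept.sum()); n_prop += problem.N
    return phi, cur_ll, n_acc / max(n_prop, 1)


def run_saem(problem: SAEMProblem, settings: SAEMSettings, seed=0,
             init=None) -> SAEMState:
    rng = np.random.default_rng(seed)
    if init is None:
        mu0, sigma0, fixed0, phi0 = naive_pooled_fit(problem)
    else:
        mu0, sigma0, fixed0 = init
        phi0 = np.tile(np.log(np.asarray(mu0, dtype=float)), (problem.N, 1))
    m = np.log(mu0)
    omega = 0.1 * np.eye(problem.d)
    sigma = np.asarray(sigma0, dtype=float)
    fixed = dict(fixed0)
    phi = phi0.copy()
    cur_ll = problem.individual_loglik(phi, sigma, fixed)
    s1 = problem.N * m.copy()
    s2 = problem.N * (np.outer(m, m) + omega)
    scales = {"full": 0.6, "comp": 0.6}
    trace = []
    K1, K2 = settings.n_exploration, settings.n_smoothing
    for it in range(K1 + K2):
        gamma = 1.0 if it < K1 else 1.0 / (it - K1 + 1)
        exploring = it < K1
        phi, cur_ll, acc = _mh_sweeps(problem, phi, cur_ll, m, omega, sigma,
                                      fixed, rng, scales, settings)
        # Robbins-Monro adaptation of proposal scales towards target accept
        adapt = min(0.3, 3.0 / math.sqrt(it + 1))
        for key in scales:
            scales[key] = float(np.clip(
                scales[key] * math.exp(adapt * (acc - settings.target_accept)),
                1e-3, 10.0))
        # sufficient statistics
        S1 = phi.sum(axis=0)
        S2 = phi.T @ phi
        s1 = s1 + gamma * (S1 - s1)
        s2 = s2 + gamma * (S2 - s2)
        # exact M-step for (m, omega)
        m_new = s1 / problem.N
        omega_new = s2 / problem.N - np.outer(m_new, m_new)
        omega_new = _project_omega(omega_new, problem.omega_structure,
                                   settings.omega_floor)
        if exploring:  # annealing: bounded shrinkage of the variances
            dd = np.diag(omega_new).copy()
            lo = settings.anneal * np.diag(omega)
            infl = np.where(dd < lo, np.sqrt(lo / np.maximum(dd, 1e-300)), 1.0)
            omega_new = omega_new * np.outer(infl, infl)
        m, omega = m_new, omega_new
        # extra fixed effects (e.g. reduced-Gompertz k), smoothed
        for name in problem.estimated_fixed_names:
            k_opt = _optimize_k(problem, phi, sigma, fixed[name])
            fixed[name] = fixed[name] + gamma * (k_opt - fixed[name])
        # error parameters, smoothed conditional optimum
        f = problem.predict(phi, fixed)
        sig_opt = _optimize_sigma(problem, f, sigma)
        sigma_new = sigma + gamma * (sig_opt - sigma)
        if exploring:
            keep = sigma > 0
            sigma_new[keep] = np.maximum(sigma_new[keep],
                                         settings.anneal * sigma[keep])
        sigma = sigma_new
        cur_ll = problem.individual_loglik(phi, sigma, fixed)
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(omega))
                and np.all(np.isfinite(sigma))):
            raise FitError("SAEM update diverged to non-finite values", trace)
        trace.append({
            "iter": it, "m": m.copy(), "omega_diag": np.diag(omega).copy(),
            "sigma": sigma.copy(), "fixed": dict(fixed), "accept": acc,
        })
    return SAEMState(m=m, omega=omega, sigma=sigma, fixed=fixed, phi=phi,
                     trace=trace, accept_rate=acc)


# -- empirical Bayes modes --------------------------------------------------

def ebe_modes(problem, m, omega, sigma, fixed, phi_start=None):
    """Per-animal mode of p(phi_i | y_i, phi_hat); start at eta = 0.

    Non-converged animals fall back to the population value and are
    flagged.  Returns (phi_modes, flags).
    """
    omega_inv, omega_logdet = _safe_inv(omega)
    modes = np.empty((problem.N, problem.d))
    flags = np.zeros(problem.N, dtype=bool)
    for i in range(problem.N):
        def neg_logpost(p):
            dev = p - m
            prior = -0.5 * float(dev @ omega_inv @ dev)
            return -(problem.single_animal_loglik(i, p, sigma, fixed) + prior)

        starts = [m.copy()]
        if phi_start is not None:
            starts.append(phi_start[i])
        best = None
        for x0 in starts:
            res = minimize(neg_logpost, x0, method="Nelder-Mead",
                           options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
        if not best.success and not np.isfinite(best.fun):
            modes[i] = m
            flags[i] = True
        else:
            modes[i] = best.x
    return modes, flags


# -- marginal likelihood by importance sampling ----------------------------

def _fd_hessian(fun, x, step=1e-4):
    d = x.size
    H = np.empty((d, d))
    f0 = fun(x)
    for a in range(d):
        for b in range(a, d):
            ea = np.zeros(d); ea[a] = step
            eb = np.zeros(d); eb[b] = step
            if a == b:
                H[a, a] = (fun(x + ea) - 2 * f0 + fun(x - ea)) / step**2
            else:
                H[a, b] = H[b, a] = (
                    fun(x + ea + eb) - fun(x + ea - eb)
                    - fun(x - ea + eb) + fun(x - ea - eb)
                ) / (4 * step**2)
    return H


def loglik_importance_sampling(problem, m, omega, sigma, fixed, M=10000,
                               seed=0, df=5.0, phi_modes=None):
    """-2 log L(phi_hat) by per-animal importance sampling.

    Heavy-tailed Student-t proposal centered at the conditional mode with
    Laplace covariance.  Returns (minus2ll, mc_se, ess_fraction_min).
    With degenerate random effects (omega ~ 0) the integral collapses and
    the exact conditional likelihood at the mode is returned.
    """
    rng = np.random.default_rng(seed)
    d = problem.d
    if np.allclose(omega, 0, atol=1e-12):
        phi = np.tile(m, (problem.N, 1))
        ll = problem.individual_loglik(phi, sigma, fixed)
        return -2.0 * float(ll.sum()), 0.0, 1.0
    omega_inv, omega_logdet = _safe_inv(omega)
    if phi_modes is None:
        phi_modes, _ = ebe_modes(problem, m, omega, sigma, fixed)
    total = 0.0
    var_total = 0.0
    min_essfrac = 1.0
    for i in range(problem.N):
        mode = phi_modes[i]

        def neg_logpost(p):
            dev = p - m
            return -(problem.single_animal_loglik(i, p, sigma, fixed)
                     - 0.5 * float(dev @ omega_inv @ dev))

        H = _fd_hessian(neg_logpost, mode)
        w, V = np.linalg.eigh(0.5 * (H + H.T))
        w = np.maximum(w, 1e-6)
        cov = (V / w) @ V.T
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
        z = rng.standard_normal((M, d))
        u = rng.chisquare(df, size=M)
        x = mode[None, :] + (z @ L.T) * np.sqrt(df / u)[:, None]
        # multivariate t log-density
        dev = x - mode[None, :]
        sol = np.linalg.solve(L, dev.T).T
        maha = np.einsum("md,md->m", sol, sol)
        logdetL = float(np.sum(np.log(np.diag(L))))
        logq = (gammaln((df + d) / 2) - gammaln(df / 2)
                - 0.5 * d * math.log(df * math.pi) - logdetL
                - 0.5 * (df + d) * np.log1p(maha / df))
        ll = problem.single_animal_loglik(i, x, sigma, fixed)
        devm = x - m[None, :]
        quad = np.einsum("md,de,me->m", devm, omega_inv, devm)
        logprior = -0.5 * (quad + omega_logdet + d * _LOG2PI)
        logw = ll + logprior - logq
        logw = np.where(np.isfinite(logw), logw, -np.inf)
        li = logsumexp(logw) - math.log(M)
        total += li
        wnorm = np.exp(logw - logsumexp(logw))
        ess = 1.0 / np.sum(wnorm**2)
        min_essfrac = min(min_essfrac, ess / M)
        var_total += float(np.var(np.exp(logw - li)) / M)
    mc_se = 2.0 * math.sqrt(max(var_total, 0.0))
    return -2.0 * total, mc_se, min_essfrac


# -- score-based standard errors -------------------------------------------

def _omega_index_pairs(d, structure):
    pairs = [(a, a) for a in range(d)]
    if structure == "full":
        pairs += [(a, b) for a in range(d) for b in range(a + 1, d)]
    return pairs


def score_standard_errors(problem, m, omega, sigma, fixed, settings, seed=0):
    """Covariance of the population estimates from marginal scores.

    Fisher's identity: the marginal score per animal equals the conditional
    expectation of the complete-data score, estimated here with Metropolis
    draws at the final estimate.  The information matrix is the sum of
    outer products of the per-animal expected scores.
    """
    rng = np.random.default_rng(seed)
    d = problem.d
    omega_inv, omega_logdet = _safe_inv(omega)
    pairs = _omega_index_pairs(d, problem.omega_structure)
    active_sigma = [j for j in range(2) if sigma[j] > 0 or
                    (j == 0 and problem.error_model == "combined")]
    fixed_names = list(problem.estimated_fixed_names)
    n_par = d + len(pairs) + len(active_sigma) + len(fixed_names)
    phi = np.tile(m, (problem.N, 1))
    cur_ll = problem.individual_loglik(phi, sigma, fixed)
    scales = {"full": 0.6, "comp": 0.6}
    burn = settings.n_score_iters // 4
    acc_scores = np.zeros((problem.N, n_par))
    count = 0
    h = 1e-5
    for it in range(settings.n_score_iters):
        phi, cur_ll, acc = _mh_sweeps(problem, phi, cur_ll, m, omega, sigma,
                                      fixed, rng, scales, settings)
        scales["full"] = float(np.clip(
            scales["full"] * math.exp(0.1 * (acc - settings.target_accept)),
            1e-3, 10.0))
        scales["comp"] = scales["full"]
        if it < burn:
            continue
        dev = phi - m
        sc = [dev @ omega_inv]  # score wrt m
        Minner = np.einsum("na,nb->nab", dev, dev)
        grad_omega = 0.5 * (np.einsum("ac,ncd,db->nab", omega_inv, Minner, omega_inv)
                            - omega_inv[None, :, :])
        cols = []
        for (a, b) in pairs:
            mult = 1.0 if a == b else 2.0
            cols.append(mult * grad_omega[:, a, b])
        sc.append(np.stack(cols, axis=1))
        # sigma / fixed-effect scores by central differences of the
        # conditional log-likelihood
        fd_cols = []
        for j in active_sigma:
            sp = sigma.copy(); sp[j] += h
            sm_ = sigma.copy(); sm_[j] = max(sm_[j] - h, 0.0)
            lp = problem.individual_loglik(phi, sp, fixed)
            lm = problem.individual_loglik(phi, sm_, fixed)
            fd_cols.append((lp - lm) / (sp[j] - sm_[j]))
        for name in fixed_names:
            fp = dict(fixed); fp[name] = fixed[name] + h
            fm = dict(fixed); fm[name] = fixed[name] - h
            lp = problem.individual_loglik(phi, sigma, fp)
            lm = problem.individual_loglik(phi, sigma, fm)
            fd_cols.append((lp - lm) / (2 * h))
        if fd_cols:
            sc.append(np.stack(fd_cols, axis=1))
        acc_scores += np.concatenate(sc, axis=1)
        count += 1
    sbar = acc_scores / max(count, 1)
    info = sbar.T @ sbar
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # unpack into named relative standard errors (percent)
    rse = {}
    names = RANDOM_PARAM_NAMES[problem.model_name]
    pos = 0
    for l, name in enumerate(names):
        rse[f"mu_{name}"] = 100.0 * se[pos]  # se on log scale = relative se
        pos += 1
    for (a, b) in pairs:
        if a == b:
            sd_a = math.sqrt(max(omega[a, a], 1e-300))
            rse[f"omega_{names[a]}"] = 100.0 * se[pos] / (2 * sd_a**2)
        else:
            rse[f"omega_{names[a]}_{names[b]}"] = (
                100.0 * se[pos] / abs(omega[a, b]) if omega[a, b] != 0 else np.inf)
        pos += 1
    for j in active_sigma:
        rse[f"sigma{j + 1}"] = (100.0 * se[pos] / sigma[j]
                                if sigma[j] > 0 else np.inf)
        pos += 1
    for name in fixed_names:
        rse[name] = 100.0 * se[pos] / abs(fixed[name])
        pos += 1
    return rse, cov
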