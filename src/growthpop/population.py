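"""Population (nonlinear mixed-effects) analysis of tumor growth cohorts.

The central objects follow the model/results pattern:

>>> model = PopulationModel(cohort, "gompertz")
>>> fit = model.fit(seed=1)
>>> print(fit.summary())

``PopulationModel.fit`` runs SAEM; the returned :class:`PopulationResults`
carries the population estimates (typical values mu, random-effect
covariance omega, error parameters sigma), their relative standard errors,
information criteria from an importance-sampled -2 log-likelihood,
per-animal empirical Bayes estimates, and diagnostics entry points.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import saem as _saem
from .cohort import Cohort
from .models import FIXED_PARAM_NAMES, RANDOM_PARAM_NAMES, model_from_theta
from .params import PopulationParams

__all__ = [
    "NLMEModelSpec",
    "PopulationModel",
    "PopulationResults",
    "information_criteria",
    "count_parameters",
    "regress_alpha_beta",
    "fit_all_models",
]


@dataclass(frozen=True)
class NLMEModelSpec:
    """Which structural model, random effects and error model to estimate.

    Defaults encode the estimation conventions of the analysis: the
    Gompertz model carries correlated random effects on (alpha, beta); the
    reduced Gompertz has a single random beta and a purely fixed k; the
    logistic and exponential use diagonal random-effect covariances; the
    error model is combined (sigma1 + sigma2 f) unless proportional is
    requested (sigma1 fixed to 0, used for fluorescence signals).
    """

    model_name: str
    error_model: str = "combined"
    positivity: str = "truncated"

    def __post_init__(self):
        if self.model_name not in RANDOM_PARAM_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.error_model not in ("combined", "proportional"):
            raise ValueError("error_model must be 'combined' or 'proportional'")

    @property
    def omega_structure(self) -> str:
        return "full" if self.model_name in ("gompertz", "lambda_gompertz") else "diagonal"

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.model_name, self.error_model)


def count_parameters(model_name: str, error_model: str = "combined") -> int:
    """Total number of estimated population scalars P.

    Fixed effects + distinct omega entries (variances, plus the
    correlation for the full-covariance Gompertz family) + error
    parameters.  Gives P = 7 / 5 / 6 / 4 for the Gompertz / reduced
    Gompertz / logistic / exponential models with a combined error model.
    """
    d = len(RANDOM_PARAM_NAMES[model_name])
    n_fixed = len(FIXED_PARAM_NAMES[model_name])
    n_corr = d * (d - 1) // 2 if model_name in ("gompertz", "lambda_gompertz") else 0
    n_sigma = 1 if error_model == "proportional" else 2
    return d + n_fixed + d + n_corr + n_sigma


def information_criteria(minus2ll: float, P: int, N: int):
    """AIC = -2LL + 2P and BIC = -2LL + P ln N (N = number of animals)."""
    if P < 0 or N < 1:
        raise ValueError("P must be >= 0 and N >= 1")
    return minus2ll + 2.0 * P, minus2ll + P * math.log(N)


class PopulationModel:
    """NLME growth model bound to a cohort, fitted by SAEM."""

    def __init__(self, cohort: Cohort, spec, settings: _saem.SAEMSettings | None = None):
        if isinstance(spec, str):
            spec = NLMEModelSpec(spec)
        self.cohort = cohort
        self.spec = spec
        self.settings = settings or _saem.SAEMSettings()
        self.problem = _saem.SAEMProblem(
            cohort, spec.model_name, spec.error_model, spec.positivity,
            spec.omega_structure)
        if cohort.n_animals < 2:
            raise ValueError("population estimation needs at least 2 animals")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, V_inj: float, model_name: str,
                       unit: str = "mm3", **kwargs) -> "PopulationModel":
        from .models import InjectionSpec
        cohort = Cohort(df, InjectionSpec(V_inj), unit)
        return cls(cohort, model_name, **kwargs)

    def fit(self, seed: int = 0, compute_rse: bool = True,
            loglik_samples: int = 0) -> "PopulationResults":
        """Run SAEM.  Deterministic given the seed.

        ``loglik_samples > 0`` also estimates -2LL by importance sampling
        (and hence AIC/BIC) as part of the fit; otherwise call
        :meth:`PopulationResults.loglik` lazily.
        """
        state = _saem.run_saem(self.problem, self.settings, seed=seed)
        params = PopulationParams(
            self.spec.model_name, np.exp(state.m), state.omega, state.sigma,
            {k: v for k, v in state.fixed.items()
             if k in FIXED_PARAM_NAMES[self.spec.model_name]})
        rse = {}
        if compute_rse:
            rse, _ = _saem.score_standard_errors(
                self.problem, state.m, state.omega, state.sigma, state.fixed,
                self.settings, seed=seed + 1)
        res = PopulationResults(self, params, state, rse)
        if loglik_samples:
            res.loglik(M=loglik_samples, seed=seed + 2)
        return res


@dataclass
class PopulationResults:
    model: PopulationModel
    params: PopulationParams
    state: "_saem.SAEMState"
    rse: dict = field(default_factory=dict)
    _minus2ll: float | None = None
    _loglik_se: float | None = None
    _ebes: np.ndarray | None = None
    _ebe_flags: np.ndarray | None = None

    # -- convenience accessors ---------------------------------------------

    @property
    def spec(self) -> NLMEModelSpec:
        return self.model.spec

    @property
    def mu(self) -> np.ndarray:
        return self.params.mu

    @property
    def omega(self) -> np.ndarray:
        return self.params.omega

    @property
    def sigma(self) -> np.ndarray:
        return self.params.sigma

    @property
    def corr(self):
        return self.params.corr

    @property
    def N(self) -> int:
        return self.model.cohort.n_animals

    @property
    def converged(self) -> bool:
        return bool(np.all(np.isfinite(self.params.mu)))

    # -- likelihood and criteria -------------------------------------------

    def loglik(self, M: int = 10000, seed: int = 0) -> float:
        """Importance-sampling estimate of -2 log L (cached)."""
        if self._minus2ll is None:
            full = dict(self.model.problem.static_fixed)
            full.update(self.params.fixed)
            m2ll, mc_se, essfrac = _saem.loglik_importance_sampling(
                self.model.problem, np.log(self.params.mu), self.params.omega,
                self.params.sigma, full, M=M, seed=seed,
                phi_modes=self._ebes if self._ebes is not None else None)
            self._minus2ll = m2ll
            self._loglik_se = mc_se
            self.low_ess = essfrac < 0.05
        return self._minus2ll

    @property
    def minus2ll(self) -> float:
        return self.loglik()

    @property
    def aic(self) -> float:
        return information_criteria(self.minus2ll, self.spec.n_parameters, self.N)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self.minus2ll, self.spec.n_parameters, self.N)[1]

    # -- individual estimates ----------------------------------------------

    def ebe_modes(self) -> pd.DataFrame:
        """Empirical Bayes estimates (conditional modes) per animal."""
        if self._ebes is None:
            full = dict(self.model.problem.static_fixed)
            full.update(self.params.fixed)
            phi, flags = _saem.ebe_modes(
                self.model.problem, np.log(self.params.mu), self.params.omega,
                self.params.sigma, full, phi_start=self.state.phi)
            self._ebes = phi
            self._ebe_flags = flags
        theta = np.exp(self._ebes)
        names = list(self.params.param_names)
        df = pd.DataFrame(theta, columns=names)
        df.insert(0, "ID", self.model.cohort.ids)
        df["flagged"] = self._ebe_flags
        return df

    def individual_models(self):
        """Growth-model instances built from the EBEs, keyed by animal."""
        df = self.ebe_modes()
        names = list(self.params.param_names)
        out = {}
        for _, row in df.iterrows():
            theta = row[names].to_numpy(dtype=float)
            out[row["ID"]] = model_from_theta(self.params.model_name, theta,
                                              self.params.fixed)
        return out

    # -- diagnostics --------------------------------------------------------

    def iwres(self) -> pd.DataFrame:
        from .diagnostics import iwres
        return iwres(self)

    def vpc(self, n_replicates: int = 200, bins: int = 8, seed: int = 0) -> pd.DataFrame:
        from .diagnostics import vpc
        return vpc(self, n_replicates=n_replicates, bins=bins, seed=seed)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        lines = []
        name = self.params.model_name
        lines.append(f"Population fit: {name} model, "
                     f"{self.spec.error_model} error, N = {self.N} animals, "
                     f"{self.model.cohort.n_obs} observations")
        lines.append(f"{'Par.':<12}{'Estimate':>12}{'omega (SD)':>12}{'R.S.E.(%)':>12}")
        sd = self.params.omega_sd
        for l, pname in enumerate(self.params.param_names):
            r = self.rse.get(f"mu_{pname}", float("nan"))
            lines.append(f"{pname:<12}{self.mu[l]:>12.4g}{sd[l]:>12.3g}{r:>12.3g}")
        for fname, fval in self.params.fixed.items():
            r = self.rse.get(fname, float("nan"))
            lines.append(f"{fname:<12}{fval:>12.4g}{'-':>12}{r:>12.3g}")
        s1, s2 = self.sigma
        lines.append(f"{'sigma1':<12}{s1:>12.4g}{'-':>12}"
                     f"{self.rse.get('sigma1', float('nan')):>12.3g}")
        lines.append(f"{'sigma2':<12}{s2:>12.4g}{'-':>12}"
                     f"{self.rse.get('sigma2', float('nan')):>12.3g}")
        if self.corr is not None:
            lines.append(f"random-effect correlation: {self.corr:.3f}")
        if self._minus2ll is not None:
            lines.append(f"-2LL = {self.minus2ll:.1f}  AIC = {self.aic:.1f}  "
                         f"BIC = {self.bic:.1f}  (P = {self.spec.n_parameters})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "params": self.params.to_dict(),
            "rse": {k: float(v) for k, v in self.rse.items()},
            "error_model": self.spec.error_model,
            "n_animals": self.N,
            "n_obs": self.model.cohort.n_obs,
        }
        if self._minus2ll is not None:
            out["minus2ll"] = float(self.minus2ll)
            out["aic"] = float(self.aic)
            out["bic"] = float(self.bic)
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def regress_alpha_beta(alpha, beta, fit_intercept: bool = False):
    """OLS regression alpha_i = k beta_i (+ c) across animals.

    Returns (k, c, r_squared).  By default the intercept is fixed to 0
    (it is empirically small); ``fit_intercept=True`` estimates it.  The
    coefficient of determination is computed against the centered total
    sum of squares in both cases so the two variants are comparable.
    """
    import statsmodels.api as sm

    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.size < 3:
        raise ValueError("need at least 3 animals")
    if np.var(beta) < 1e-30:
        raise ValueError("degenerate variance of beta")
    X = sm.add_constant(beta) if fit_intercept else beta[:, None]
    fit = sm.OLS(alpha, X).fit()
    if fit_intercept:
        c, k = fit.params
    else:
        k, c = float(fit.params[0]), 0.0
    resid = alpha - (k * beta + c)
    ss_tot = float(np.sum((alpha - alpha.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(k), float(c), float(r2)


def fit_all_models(cohort, model_names=("gompertz", "reduced_gompertz",
                                        "logistic", "exponential"),
                   error_model="combined", settings=None, seed=0,
                   loglik_samples=2000):
    """Fit several structural models and rank them by AIC.

    Returns (results dict, ranking DataFrame shaped like the usual
    model-comparison table: model, -2LL, AIC, BIC).
    """
    results = {}
    rows = []
    for j, name in enumerate(model_names):
        model = PopulationModel(cohort, NLMEModelSpec(name, error_model),
                                settings=settings)
        res = model.fit(seed=seed + j, loglik_samples=loglik_samples)
        results[name] = res
        rows.append({"model": name, "minus2LL": res.minus2ll,
                     "AIC": res.aic, "BIC": res.bic})
    table = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    return results, table
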