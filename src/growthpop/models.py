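"""Structural tumor growth laws and their closed-form machinery.

All models describe the volume (or fluorescence signal) of an experimental
tumor after injection of a known quantity of cells.  By convention the
injection happens at t = 0 with size ``V_inj``, and ``alpha`` denotes the
specific growth rate (1/V dV/dt) at that time and size.  Every model is
solved in closed form from an arbitrary initial condition (t_I, V_I), which
makes backward (t < t_I) evaluation and the tumor-age inversion exact.

Models
------
Exponential      dV/dt = alpha V
Logistic         dV/dt = rho (1 - V/K) V
Gompertz         dV/dt = (alpha - beta log(V/V_inj)) V
ReducedGompertz  Gompertz with alpha = k beta, k a population constant
FixedSGRGompertz Gompertz variant with the SGR at initiation fixed to the
                 in-vitro proliferation rate lambda and an effective
                 injected volume V_hat_inj <= V_inj (engraftment fraction
                 V_hat_inj / V_inj)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainError",
    "InfeasibleAgeError",
    "NegativeAgeWarning",
    "InjectionSpec",
    "InitialCondition",
    "Exponential",
    "Logistic",
    "Gompertz",
    "ReducedGompertz",
    "FixedSGRGompertz",
    "engraftment_fraction",
    "rho_from_alpha",
    "alpha_from_rho",
    "MODEL_NAMES",
    "model_from_theta",
]

# guard against overflow in exp() during optimizer excursions
_MAX_LOG = 700.0


class DomainError(ValueError):
    """Raised for parameter or state values outside the model's domain."""


class InfeasibleAgeError(DomainError):
    """Raised when a size at or above the carrying capacity is inverted."""


class NegativeAgeWarning(UserWarning):
    """Emitted when the inverted age is negative (V_I below V_inj)."""


@dataclass(frozen=True)
class InjectionSpec:
    """Injection conditions shared by all animals of a group.

    V_inj is the size corresponding to the injected cells (mm^3 or
    photons/s); t_inj is fixed at 0.  ``lambda_invitro`` is the optional
    in-vitro proliferation rate (day^-1) used by :class:`FixedSGRGompertz`.
    """

    V_inj: float
    t_inj: float = 0.0
    lambda_invitro: float | None = None

    def __post_init__(self) -> None:
        if not (self.V_inj > 0):
            raise DomainError(f"V_inj must be > 0, got {self.V_inj}")
        if self.t_inj != 0.0:
            raise DomainError("t_inj is fixed at 0 by convention")


@dataclass(frozen=True)
class InitialCondition:
    t_I: float
    V_I: float

    def __post_init__(self) -> None:
        if not (self.V_I > 0):
            raise DomainError(f"V_I must be > 0, got {self.V_I}")


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise DomainError(f"{name} must be positive and finite, got {value}")


class GrowthModel:
    """Common closed-form interface of the growth laws."""

    def solve(self, inj, init, times):
        """Evaluate V(t) on the closed-form solution started at (t_I, V_I)."""
        raise NotImplementedError

    def specific_growth_rate(self, inj, V):
        """(1/V) dV/dt at size V."""
        raise NotImplementedError

    def carrying_capacity(self, inj):
        """Asymptotic maximal size, or None for unbounded models."""
        return None

    def tumor_age(self, inj, V_I):
        """Time elapsed growing from V_inj to V_I along the model curve.

        Satisfies ``solve(inj, (0, V_I), [-age]) == V_inj``.
        """
        raise NotImplementedError

    def _check_age_domain(self, inj, V_I):
        if not (V_I > 0):
            raise DomainError(f"V_I must be > 0, got {V_I}")
        K = self.carrying_capacity(inj)
        if K is not None and V_I >= K:
            raise InfeasibleAgeError(
                f"V_I = {V_I} is at or above the carrying capacity {K}"
            )
        if V_I < inj.V_inj:
            warnings.warn(
                "V_I below V_inj: inverted age is negative", NegativeAgeWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class Exponential(GrowthModel):
    alpha: float

    def __post_init__(self) -> None:
        _require_positive(alpha=self.alpha)

    def solve(self, inj, init, times):
        t = np.asarray(times, dtype=float)
        logV = np.log(init.V_I) + self.alpha * (t - init.t_I)
        return np.exp(np.minimum(logV, _MAX_LOG))

    def specific_growth_rate(self, inj, V):
        if np.any(np.asarray(V) <= 0):
            raise DomainError("V must be > 0")
        return np.broadcast_to(self.alpha, np.shape(V)).astype(float) if np.ndim(V) else self.alpha

    def tumor_age(self, inj, V_I):
        self._check_age_domain(inj, V_I)
        return math.log(V_I / inj.V_inj) / self.alpha


@dataclass(frozen=True)
class Logistic(GrowthModel):
    rho: float
    K: float

    def __post_init__(self) -> None:
        _require_positive(rho=self.rho, K=self.K)

    def solve(self, inj, init, times):
        t = np.asarray(times, dtype=float)
        e = np.exp(np.minimum(self.rho * (t - init.t_I), _MAX_LOG))
        return self.K * init.V_I * e / (self.K + init.V_I * (e - 1.0))

    def specific_growth_rate(self, inj, V):
        V = np.asarray(V, dtype=float)
        if np.any(V <= 0):
            raise DomainError("V must be > 0")
        out = self.rho * (1.0 - V / self.K)
        return float(out) if out.ndim == 0 else out

    def carrying_capacity(self, inj):
        return self.K

    def tumor_age(self, inj, V_I):
        self._check_age_domain(inj, V_I)
        # invert V(t) = K V_inj e^{rho t} / (K + V_inj (e^{rho t} - 1))
        num = V_I * (self.K - inj.V_inj)
        den = inj.V_inj * (self.K - V_I)
        return math.log(num / den) / self.rho


def rho_from_alpha(alpha: float, K: float, V_inj: float) -> float:
    """Logistic growth coefficient rho = alpha K / (K - V_inj)."""
    if not (K > V_inj):
        raise DomainError("K must exceed V_inj")
    return alpha * K / (K - V_inj)


def alpha_from_rho(rho: float, K: float, V_inj: float) -> float:
    """Specific growth rate at injection implied by the logistic rho."""
    if not (K > V_inj):
        raise DomainError("K must exceed V_inj")
    return rho * (K - V_inj) / K


def _gompertz_solve(alpha, beta, inj, init, times):
    t = np.asarray(times, dtype=float)
    ab = alpha / beta
    logV = (
        np.log(inj.V_inj)
        + ab
        + (np.log(init.V_I / inj.V_inj) - ab) * np.exp(-beta * (t - init.t_I))
    )
    return np.exp(np.minimum(logV, _MAX_LOG))


def _gompertz_age(alpha, beta, inj, V_I):
    ab = alpha / beta
    return (math.log(ab) - math.log(ab - math.log(V_I / inj.V_inj))) / beta


@dataclass(frozen=True)
class Gompertz(GrowthModel):
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _require_positive(alpha=self.alpha, beta=self.beta)

    def solve(self, inj, init, times):
        return _gompertz_solve(self.alpha, self.beta, inj, init, times)

    def specific_growth_rate(self, inj, V):
        V = np.asarray(V, dtype=float)
        if np.any(V <= 0):
            raise DomainError("V must be > 0")
        out = self.alpha - self.beta * np.log(V / inj.V_inj)
        return float(out) if out.ndim == 0 else out

    def carrying_capacity(self, inj):
        return inj.V_inj * math.exp(self.alpha / self.beta)

    def tumor_age(self, inj, V_I):
        self._check_age_domain(inj, V_I)
        return _gompertz_age(self.alpha, self.beta, inj, V_I)


@dataclass(frozen=True)
class ReducedGompertz(GrowthModel):
    """Gompertz law with the individual SGR tied to beta via alpha = k beta.

    ``k`` is dimensionless and constant within a population; ``beta`` is the
    single individual parameter.
    """

    beta: float
    k: float

    def __post_init__(self) -> None:
        _require_positive(beta=self.beta, k=self.k)

    @property
    def alpha(self) -> float:
        return self.k * self.beta

    def solve(self, inj, init, times):
        return _gompertz_solve(self.alpha, self.beta, inj, init, times)

    def specific_growth_rate(self, inj, V):
        return Gompertz(self.alpha, self.beta).specific_growth_rate(inj, V)

    def carrying_capacity(self, inj):
        return inj.V_inj * math.exp(self.k)

    def tumor_age(self, inj, V_I):
        self._check_age_domain(inj, V_I)
        return _gompertz_age(self.alpha, self.beta, inj, V_I)


@dataclass(frozen=True)
class FixedSGRGompertz(GrowthModel):
    """Gompertz variant with SGR fixed to lambda at an effective inoculum.

    dV/dt = (lambda - beta log(V / V_hat_inj)) V with V(0) = V_hat_inj,
    where lambda is the in-vitro proliferation rate (from the
    :class:`InjectionSpec`) and V_hat_inj <= V_inj is the size of the
    successfully engrafted cells.
    """

    beta: float
    V_hat_inj: float

    def __post_init__(self) -> None:
        _require_positive(beta=self.beta, V_hat_inj=self.V_hat_inj)

    def _lambda(self, inj):
        if inj.lambda_invitro is None:
            raise DomainError("InjectionSpec.lambda_invitro is required")
        if self.V_hat_inj > inj.V_inj:
            raise DomainError("V_hat_inj must not exceed V_inj")
        return inj.lambda_invitro

    def solve(self, inj, init, times):
        lam = self._lambda(inj)
        hat = InjectionSpec(self.V_hat_inj, lambda_invitro=inj.lambda_invitro)
        return _gompertz_solve(lam, self.beta, hat, init, times)

    def specific_growth_rate(self, inj, V):
        lam = self._lambda(inj)
        V = np.asarray(V, dtype=float)
        if np.any(V <= 0):
            raise DomainError("V must be > 0")
        out = lam - self.beta * np.log(V / self.V_hat_inj)
        return float(out) if out.ndim == 0 else out

    def carrying_capacity(self, inj):
        lam = self._lambda(inj)
        return self.V_hat_inj * math.exp(lam / self.beta)

    def tumor_age(self, inj, V_I):
        lam = self._lambda(inj)
        K = self.carrying_capacity(inj)
        if V_I >= K:
            raise InfeasibleAgeError(f"V_I = {V_I} at or above capacity {K}")
        hat = InjectionSpec(self.V_hat_inj, lambda_invitro=lam)
        return _gompertz_age(lam, self.beta, hat, V_I)


def engraftment_fraction(V_hat_inj: float, inj: InjectionSpec) -> float:
    """Fraction of the nominal inoculum that successfully engrafted."""
    if not (0 < V_hat_inj <= inj.V_inj):
        raise DomainError(
            f"V_hat_inj must lie in (0, V_inj], got {V_hat_inj} with V_inj={inj.V_inj}"
        )
    return V_hat_inj / inj.V_inj


# ---------------------------------------------------------------------------
# registry used by the fitting machinery: vectorized curves parameterized by
# a per-animal theta row, with the population initial condition (0, V_inj)
# or a backward initial condition (0, V_I).
# ---------------------------------------------------------------------------

MODEL_NAMES = (
    "exponential",
    "logistic",
    "gompertz",
    "reduced_gompertz",
    "lambda_gompertz",
)

# names of the parameters carrying random effects, per model
RANDOM_PARAM_NAMES = {
    "exponential": ("alpha",),
    "logistic": ("rho", "K"),
    "gompertz": ("alpha", "beta"),
    "reduced_gompertz": ("beta",),
    "lambda_gompertz": ("beta", "V_hat_inj"),
}

# extra fixed effects without random components
FIXED_PARAM_NAMES = {
    "exponential": (),
    "logistic": (),
    "gompertz": (),
    "reduced_gompertz": ("k",),
    "lambda_gompertz": (),
}


def model_from_theta(name, theta, fixed=None):
    """Build a growth-model instance from a random-effect parameter row."""
    theta = np.asarray(theta, dtype=float)
    fixed = fixed or {}
    if name == "exponential":
        return Exponential(alpha=theta[0])
    if name == "logistic":
        return Logistic(rho=theta[0], K=theta[1])
    if name == "gompertz":
        return Gompertz(alpha=theta[0], beta=theta[1])
    if name == "reduced_gompertz":
        return ReducedGompertz(beta=theta[0], k=fixed["k"])
    if name == "lambda_gompertz":
        return FixedSGRGompertz(beta=theta[0], V_hat_inj=theta[1])
    raise ValueError(f"unknown model {name!r}")


def curve_population(name, theta, t, V_inj, fixed=None):
    """Vectorized V(t) with initial condition (0, V_inj).

    theta has shape (..., d) and t broadcasts against theta[..., 0]; the
    usual call aligns one theta row per observation.
    """
    theta = np.asarray(theta, dtype=float)
    t = np.asarray(t, dtype=float)
    fixed = fixed or {}
    if name == "exponential":
        logV = np.log(V_inj) + theta[..., 0] * t
        return np.exp(np.minimum(logV, _MAX_LOG))
    if name == "logistic":
        rho, K = theta[..., 0], theta[..., 1]
        e = np.exp(np.minimum(rho * t, _MAX_LOG))
        return K * V_inj * e / (K + V_inj * (e - 1.0))
    if name == "gompertz":
        ab = theta[..., 0] / theta[..., 1]
        logV = np.log(V_inj) + ab * (1.0 - np.exp(-theta[..., 1] * t))
        return np.exp(np.minimum(logV, _MAX_LOG))
    if name == "reduced_gompertz":
        beta = theta[..., 0]
        k = fixed["k"]
        logV = np.log(V_inj) + k * (1.0 - np.exp(-beta * t))
        return np.exp(np.minimum(logV, _MAX_LOG))
    if name == "lambda_gompertz":
        beta, V_hat = theta[..., 0], theta[..., 1]
        lam = fixed["lambda_invitro"]
        logV = np.log(V_hat) + (lam / beta) * (1.0 - np.exp(-beta * t))
        return np.exp(np.minimum(logV, _MAX_LOG))
    raise ValueError(f"unknown model {name!r}")


def curve_from_VI(name, theta, t, V_I, V_inj, fixed=None):
    """Vectorized V(t) with initial condition (0, V_I) (backward setting).

    Only the Gompertz family is needed for backward prediction.
    """
    theta = np.asarray(theta, dtype=float)
    t = np.asarray(t, dtype=float)
    fixed = fixed or {}
    if name == "gompertz":
        alpha, beta = theta[..., 0], theta[..., 1]
    elif name == "reduced_gompertz":
        beta = theta[..., 0]
        alpha = fixed["k"] * beta
    else:
        raise ValueError(f"backward curve not defined for model {name!r}")
    ab = alpha / beta
    logV = np.log(V_inj) + ab + (np.log(V_I / V_inj) - ab) * np.exp(-beta * t)
    return np.exp(np.minimum(logV, _MAX_LOG))


def age_from_theta(name, theta, V_I, V_inj, fixed=None):
    """Vectorized tumor age (time from V_inj to V_I); NaN where infeasible."""
    theta = np.asarray(theta, dtype=float)
    fixed = fixed or {}
    V_I = np.asarray(V_I, dtype=float)
    if name == "gompertz":
        alpha, beta = theta[..., 0], theta[..., 1]
    elif name == "reduced_gompertz":
        beta = theta[..., 0]
        alpha = fixed["k"] * beta
    elif name == "exponential":
        alpha = theta[..., 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(V_I > 0, np.log(V_I / V_inj) / alpha, np.nan)
        return out
    else:
        raise ValueError(f"age formula not defined for model {name!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = alpha / beta
        arg = ab - np.log(V_I / V_inj)
        out = np.where(
            (arg > 0) & (V_I > 0), (np.log(ab) - np.log(np.maximum(arg, 1e-300))) / beta,
            np.nan,
        )
    return out
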