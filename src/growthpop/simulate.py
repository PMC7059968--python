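"""Synthetic cohorts with the statistical structure the analysis assumes.

Animals draw lognormal, possibly correlated, individual parameters around
the population typical values; measurements follow the combined residual
error model y = f + (sigma1 + sigma2 f) eps conditioned on positivity
(negative draws are re-sampled); follow-up stops at the first measurement
exceeding the design cap (that triggering measurement is kept, mirroring
the sacrifice protocol).

Design presets emulate the three experimental groups analysed in the
package's validation study: a breast cell line measured by caliper volume
(66 animals, cap 2 cm^3), a lung cell line measured by volume (20 animals,
cap 1.5 cm^3) and a breast cell line followed by fluorescence imaging
(8 animals, proportional error).  Measurement days start when tumors reach
palpable size rather than at injection; volume designs are twice/thrice
weekly so that the nominal observation totals match the experimental ones
(~581/66, ~188/20, 64/8).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .models import InjectionSpec, curve_population
from .params import PopulationParams

__all__ = [
    "StudyDesign",
    "DESIGN_PRESETS",
    "POPULATION_PRESETS",
    "design_preset",
    "population_preset",
    "sample_individual_params",
    "simulate_measurements",
    "generate_cohort",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    n_animals: int
    V_inj: float
    unit: str
    schedule: tuple
    cap: float | None = None
    lambda_invitro: float | None = None

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise DesignError("n_animals must be >= 1")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0:
            raise DesignError("schedule must not be empty")
        if np.any(sched <= 0) or np.any(np.diff(sched) <= 0):
            raise DesignError("schedule must be strictly increasing and positive")
        if self.cap is not None and not (self.cap > self.V_inj):
            raise DesignError("cap must exceed V_inj")

    @property
    def inj(self) -> InjectionSpec:
        return InjectionSpec(self.V_inj, lambda_invitro=self.lambda_invitro)


DESIGN_PRESETS = {
    # twice weekly from palpable size (~day 11) to day 39; cap 2000 mm3
    "breast-volume": StudyDesign(
        n_animals=66, V_inj=1.0, unit="mm3",
        schedule=(11, 14, 18, 21, 25, 28, 32, 35, 39), cap=2000.0,
    ),
    # faster line, thrice weekly, cap 1500 mm3
    "lung-volume": StudyDesign(
        n_animals=20, V_inj=1.0, unit="mm3",
        schedule=(8, 10, 12, 15, 17, 19, 22, 24, 26, 29), cap=1500.0,
    ),
    # fluorescence signal, proportional error, fixed 8-point follow-up
    "breast-fluorescence": StudyDesign(
        n_animals=8, V_inj=1.22e7, unit="photons/s",
        schedule=(7, 10, 14, 17, 21, 24, 28, 31), cap=None,
    ),
}

# population parameters of the four growth laws for the breast-volume group
# (typical values, random-effect SDs, correlation, error parameters), plus
# plausible values for the two smaller groups.
POPULATION_PRESETS = {
    ("breast-volume", "gompertz"): PopulationParams.from_sd_corr(
        "gompertz", mu=(0.58, 0.072), omega_sd=(0.19, 0.26), corr=0.981,
        sigma=(20.5, 0.11)),
    ("breast-volume", "reduced_gompertz"): PopulationParams.from_sd_corr(
        "reduced_gompertz", mu=(0.075,), omega_sd=(0.13,),
        sigma=(14.8, 0.17), fixed={"k": 7.87}),
    ("breast-volume", "logistic"): PopulationParams.from_sd_corr(
        "logistic", mu=(0.325, 1303.0), omega_sd=(0.138, 0.25),
        sigma=(58.9, 0.12)),
    ("breast-volume", "exponential"): PopulationParams.from_sd_corr(
        "exponential", mu=(0.231,), omega_sd=(0.08,), sigma=(272.0, 0.26)),
    ("lung-volume", "gompertz"): PopulationParams.from_sd_corr(
        "gompertz", mu=(0.61, 0.065), omega_sd=(0.16, 0.2), corr=0.967,
        sigma=(15.0, 0.1)),
    ("lung-volume", "reduced_gompertz"): PopulationParams.from_sd_corr(
        "reduced_gompertz", mu=(0.067,), omega_sd=(0.12,),
        sigma=(12.0, 0.12), fixed={"k": 9.42}),
    ("breast-fluorescence", "gompertz"): PopulationParams.from_sd_corr(
        "gompertz", mu=(0.63, 0.07), omega_sd=(0.1, 0.11), corr=0.998,
        sigma=(0.0, 0.2)),
    ("breast-fluorescence", "reduced_gompertz"): PopulationParams.from_sd_corr(
        "reduced_gompertz", mu=(0.072,), omega_sd=(0.1,),
        sigma=(0.0, 0.2), fixed={"k": 9.0}),
}


def design_preset(name: str, **overrides) -> StudyDesign:
    try:
        design = DESIGN_PRESETS[name]
    except KeyError:
        raise DesignError(
            f"unknown design preset {name!r}; available: {sorted(DESIGN_PRESETS)}"
        ) from None
    return replace(design, **overrides) if overrides else design


def population_preset(design_name: str, model_name: str) -> PopulationParams:
    try:
        return POPULATION_PRESETS[(design_name, model_name)]
    except KeyError:
        raise DesignError(
            f"no population preset for ({design_name!r}, {model_name!r})"
        ) from None


def sample_individual_params(pop: PopulationParams, n: int, seed) -> np.ndarray:
    """Sample n individual parameter rows theta_i = mu exp(eta_i).

    ``seed`` may be an int, a SeedSequence, or a Generator.  Returns an
    (n, d) array on the natural scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    d = pop.n_random
    if np.allclose(pop.omega, 0):
        eta = np.zeros((n, d))
    else:
        eta = rng.multivariate_normal(np.zeros(d), pop.omega, size=n,
                                      method="svd")
    return pop.mu[None, :] * np.exp(eta)


def simulate_measurements(theta, pop_or_sigma, design: StudyDesign, rng,
                          max_resample: int = 1000):
    """Simulate one animal's record from its parameter row.

    Returns (times, y).  Noise follows the combined error model conditioned
    on positivity; follow-up is truncated after the first observation
    exceeding the cap (that observation is kept).
    """
    if isinstance(pop_or_sigma, PopulationParams):
        sigma = pop_or_sigma.sigma
        model_name = pop_or_sigma.model_name
        fixed = pop_or_sigma.fixed
    else:
        raise TypeError("pass the PopulationParams so the model is known")
    rng = np.random.default_rng(rng)
    t = np.asarray(design.schedule, dtype=float)
    lam = design.lambda_invitro
    fixed = dict(fixed)
    if lam is not None:
        fixed.setdefault("lambda_invitro", lam)
    f = curve_population(model_name, np.asarray(theta, float)[None, :], t,
                         design.V_inj, fixed)
    g = sigma[0] + sigma[1] * f
    y = f + g * rng.standard_normal(f.shape)
    for _ in range(max_resample):
        bad = y <= 0
        if not bad.any():
            break
        y[bad] = f[bad] + g[bad] * rng.standard_normal(int(bad.sum()))
    else:  # pragma: no cover - astronomically unlikely with sane designs
        y = np.where(y <= 0, f, y)
    if design.cap is not None:
        above = np.nonzero(y > design.cap)[0]
        if above.size:
            stop = above[0] + 1  # keep the triggering measurement
            t, y = t[:stop], y[:stop]
    return t, y


def generate_cohort(pop: PopulationParams, design: StudyDesign, seed=0) -> Cohort:
    """Generate a full cohort; reproducible given the seed.

    One master seed; per-animal streams are spawned from it so the cohort
    is invariant to the order of generation.
    """
    ss = np.random.SeedSequence(seed)
    child_param, *children = ss.spawn(design.n_animals + 1)
    theta = sample_individual_params(pop, design.n_animals, child_param)
    frames = []
    for i in range(design.n_animals):
        t, y = simulate_measurements(theta[i], pop, design, children[i])
        frames.append(pd.DataFrame({"ID": i + 1, "TIME": t, "OBS": y}))
    df = pd.concat(frames, ignore_index=True)
    meta = {
        "generating_params": pop.to_dict(),
        "theta_true": theta,
        "seed": seed,
        "design": {
            "n_animals": design.n_animals, "V_inj": design.V_inj,
            "unit": design.unit, "schedule": list(design.schedule),
            "cap": design.cap,
        },
    }
    return Cohort(df, design.inj, design.unit, meta)
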