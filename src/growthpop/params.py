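"""Population-parameter container shared by the simulator and the fitters."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .models import FIXED_PARAM_NAMES, RANDOM_PARAM_NAMES


@dataclass
class PopulationParams:
    """Population distribution phi = (mu, omega, sigma) of a growth model.

    mu
        fixed effects (typical values, natural scale) of the parameters
        carrying random effects, ordered as in ``RANDOM_PARAM_NAMES``.
    omega
        covariance matrix of the log-scale random effects
        (log theta_i = log mu + eta_i, eta_i ~ N(0, omega)).
    sigma
        residual error parameters [sigma1, sigma2] of the combined model
        e = (sigma1 + sigma2 f) eps; sigma1 = 0 gives a proportional model.
    fixed
        extra fixed effects without random components, e.g. {"k": 7.87}
        for the reduced Gompertz model.
    """

    model_name: str
    mu: np.ndarray
    omega: np.ndarray
    sigma: np.ndarray
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        d = self.mu.size
        if self.omega.shape != (d, d):
            raise ValueError(f"omega must be {d}x{d}, got {self.omega.shape}")
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        eigs = np.linalg.eigvalsh(self.omega)
        if eigs.min() < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        if np.any(self.mu <= 0):
            raise ValueError("fixed effects must be positive (lognormal model)")
        # both-zero sigma is allowed so exactly noiseless cohorts can be
        # simulated; estimation never produces it
        if np.any(self.sigma < 0):
            raise ValueError("sigma components must be >= 0")
        expected = RANDOM_PARAM_NAMES[self.model_name]
        if d != len(expected):
            raise ValueError(
                f"{self.model_name} has random parameters {expected}, got {d} values"
            )
        for name in FIXED_PARAM_NAMES[self.model_name]:
            if name not in self.fixed:
                raise ValueError(f"missing fixed effect {name!r}")

    @classmethod
    def from_sd_corr(cls, model_name, mu, omega_sd, corr=None, sigma=(0.0, 0.1),
                     fixed=None):
        """Build from random-effect standard deviations and a correlation."""
        sd = np.atleast_1d(np.asarray(omega_sd, dtype=float))
        omega = np.diag(sd**2)
        if corr is not None and sd.size == 2:
            omega[0, 1] = omega[1, 0] = corr * sd[0] * sd[1]
        return cls(model_name, np.asarray(mu, float), omega, np.asarray(sigma, float),
                   dict(fixed or {}))

    @property
    def param_names(self):
        return RANDOM_PARAM_NAMES[self.model_name]

    @property
    def n_random(self) -> int:
        return self.mu.size

    @property
    def omega_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.omega))

    @property
    def corr(self) -> float | None:
        """Random-effect correlation (2-parameter models only)."""
        if self.n_random != 2:
            return None
        sd = self.omega_sd
        if np.any(sd == 0):
            return 0.0
        return float(self.omega[0, 1] / (sd[0] * sd[1]))

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "mu": self.mu.tolist(),
            "omega": self.omega.tolist(),
            "sigma": self.sigma.tolist(),
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_dict(cls, d) -> "PopulationParams":
        return cls(d["model_name"], np.asarray(d["mu"]), np.asarray(d["omega"]),
                   np.asarray(d["sigma"]), dict(d.get("fixed", {})))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PopulationParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
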