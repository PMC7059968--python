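"""Goodness-of-fit diagnostics for population fits.

Visual predictive checks (VPC), individual weighted residuals (IWRES),
observations-vs-predictions pairs and prediction-distribution envelopes,
all returned as tidy DataFrames ready for CSV export or plotting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import curve_population
from .simulate import sample_individual_params

__all__ = ["vpc", "iwres", "observations_vs_predictions",
           "prediction_distribution", "plot_vpc"]

_PCTS = (10.0, 50.0, 90.0)


def _time_bins(t, bins, min_per_bin=3):
    """Quantile bin edges over observation times; sparse bins merged."""
    edges = np.unique(np.quantile(t, np.linspace(0, 1, bins + 1)))
    edges[-1] += 1e-9
    while len(edges) > 2:
        counts, _ = np.histogram(t, edges)
        if counts.min() >= min_per_bin:
            break
        j = int(np.argmin(counts))
        drop = j + 1 if j < len(counts) - 1 else j
        edges = np.delete(edges, drop)
        warnings.warn("merged a time bin with < 3 observations")
    return edges


def vpc(results, n_replicates: int = 200, bins: int = 8, seed: int = 0,
        ci: float = 90.0) -> pd.DataFrame:
    """Visual predictive check table.

    Simulates ``n_replicates`` cohorts from the estimated population
    distribution on the observed design and compares, per time bin, the
    empirical 10/50/90th percentiles with the simulated percentiles'
    confidence band.
    """
    problem = results.model.problem
    params = results.params
    t, y = problem.t, problem.y
    idx, N = problem.idx, problem.N
    edges = _time_bins(t, bins)
    binof = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    rng = np.random.default_rng(seed)
    fixed = dict(problem.static_fixed)
    fixed.update(params.fixed)

    sim_pcts = np.empty((n_replicates, n_bins, len(_PCTS)))
    for r in range(n_replicates):
        theta = sample_individual_params(params, N, rng)
        f = curve_population(params.model_name, theta[idx], t,
                             problem.V_inj, fixed)
        g = params.sigma[0] + params.sigma[1] * f
        ysim = f + g * rng.standard_normal(f.shape)
        bad = ysim <= 0
        for _ in range(100):
            if not bad.any():
                break
            ysim[bad] = f[bad] + g[bad] * rng.standard_normal(int(bad.sum()))
            bad = ysim <= 0
        for b in range(n_bins):
            sim_pcts[r, b] = np.percentile(ysim[binof == b], _PCTS)

    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    rows = []
    for b in range(n_bins):
        mask = binof == b
        emp = np.percentile(y[mask], _PCTS)
        for p, pct in enumerate(_PCTS):
            rows.append({
                "bin": b,
                "t_mid": float(t[mask].mean()),
                "percentile": pct,
                "empirical": float(emp[p]),
                "predicted_median": float(np.median(sim_pcts[:, b, p])),
                "predicted_lo": float(np.percentile(sim_pcts[:, b, p], lo_q)),
                "predicted_hi": float(np.percentile(sim_pcts[:, b, p], hi_q)),
                "n_obs": int(mask.sum()),
            })
    df = pd.DataFrame(rows)
    df["inside"] = (df["empirical"] >= df["predicted_lo"]) & (
        df["empirical"] <= df["predicted_hi"])
    return df


def _individual_predictions(results):
    problem = results.model.problem
    ebes = results.ebe_modes()
    names = list(results.params.param_names)
    theta = ebes[names].to_numpy(dtype=float)
    fixed = dict(problem.static_fixed)
    fixed.update(results.params.fixed)
    f = curve_population(results.params.model_name, theta[problem.idx],
                         problem.t, problem.V_inj, fixed)
    return f


def iwres(results) -> pd.DataFrame:
    """Individual weighted residuals (y - f(theta_i)) / (s1 + s2 f)."""
    problem = results.model.problem
    f = _individual_predictions(results)
    g = np.maximum(results.sigma[0] + results.sigma[1] * f, 1e-12)
    res = (problem.y - f) / g
    ids = np.asarray(results.model.cohort.ids, dtype=object)[problem.idx]
    return pd.DataFrame({"ID": ids, "TIME": problem.t, "IWRES": res})


def observations_vs_predictions(results) -> pd.DataFrame:
    problem = results.model.problem
    f = _individual_predictions(results)
    ids = np.asarray(results.model.cohort.ids, dtype=object)[problem.idx]
    return pd.DataFrame({"ID": ids, "TIME": problem.t,
                         "OBS": problem.y, "PRED": f})


def prediction_distribution(results, n_samples: int = 1000, n_times: int = 50,
                            seed: int = 0) -> pd.DataFrame:
    """Envelope of model curves (no residual error) over the observed span."""
    problem = results.model.problem
    params = results.params
    rng = np.random.default_rng(seed)
    grid = np.linspace(problem.t.min(), problem.t.max(), n_times)
    theta = sample_individual_params(params, n_samples, rng)
    fixed = dict(problem.static_fixed)
    fixed.update(params.fixed)
    f = curve_population(params.model_name, theta[:, None, :], grid[None, :],
                         problem.V_inj, fixed)
    pct = np.percentile(f, [5, 50, 95], axis=0)
    return pd.DataFrame({"TIME": grid, "p5": pct[0], "p50": pct[1],
                         "p95": pct[2]})


def plot_vpc(vpc_df: pd.DataFrame, ax=None):  # pragma: no cover - optional
    """Simple matplotlib rendering of a VPC table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for pct, grp in vpc_df.groupby("percentile"):
        ax.fill_between(grp["t_mid"], grp["predicted_lo"], grp["predicted_hi"],
                        alpha=0.2)
        ax.plot(grp["t_mid"], grp["empirical"], "o-", label=f"empirical {pct:g}%")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("size")
    ax.legend()
    return ax
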