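import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from growthpop import InjectionSpec, PopulationParams, SAEMSettings
from growthpop.simulate import design_preset, generate_cohort, population_preset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def inj():
    return InjectionSpec(1.0)


# SAEM settings trimmed for test runtime; fits remain well converged at
# these synthetic-data sizes
FAST_SAEM = SAEMSettings(n_exploration=150, n_smoothing=60, n_score_iters=80)


@pytest.fixture(scope="session")
def fast_settings():
    return FAST_SAEM


@pytest.fixture(scope="session")
def breast_design():
    return design_preset("breast-volume")


@pytest.fixture(scope="session")
def gompertz_pop():
    return population_preset("breast-volume", "gompertz")


@pytest.fixture(scope="session")
def reduced_pop():
    return population_preset("breast-volume", "reduced_gompertz")


@pytest.fixture(scope="session")
def gompertz_cohort(gompertz_pop, breast_design):
    return generate_cohort(gompertz_pop, breast_design, seed=42)


@pytest.fixture(scope="session")
def reduced_cohort(reduced_pop, breast_design):
    return generate_cohort(reduced_pop, breast_design, seed=7)


@pytest.fixture(scope="session")
def gompertz_fit(gompertz_cohort):
    """Shared full-scale Gompertz SAEM fit on the synthetic breast cohort."""
    from growthpop import PopulationModel

    return PopulationModel(gompertz_cohort, "gompertz").fit(
        seed=1, compute_rse=False)


@pytest.fixture(scope="session")
def small_gompertz_cohort(gompertz_pop):
    from dataclasses import replace

    design = replace(design_preset("breast-volume"), n_animals=20)
    return generate_cohort(gompertz_pop, design, seed=5)
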