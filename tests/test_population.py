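"""SAEM estimation, information criteria, EBEs and diagnostics."""

import numpy as np
import pytest

from growthpop import (
    NLMEModelSpec,
    PopulationModel,
    PopulationParams,
    SAEMSettings,
    information_criteria,
    regress_alpha_beta,
)
from growthpop.population import count_parameters
from growthpop.saem import SAEMProblem, loglik_importance_sampling
from growthpop.simulate import StudyDesign, generate_cohort

from conftest import FAST_SAEM


class TestInformationCriteria:
    # printed model-comparison rows for the 66-animal breast cohort:
    # (-2LL, P, AIC, BIC)
    TABLE = [
        ("gompertz", 7129, 7, 7143, 7158),
        ("reduced_gompertz", 7259, 5, 7269, 7280),
        ("logistic", 7584, 6, 7596, 7609),
        ("exponential", 8652, 4, 8660, 8669),
    ]

    @pytest.mark.parametrize("name,m2ll,P,aic,bic", TABLE)
    def test_printed_table_identities(self, name, m2ll, P, aic, bic):
        """AIC/BIC recomputed from -2LL with the frozen P convention."""
        got_aic, got_bic = information_criteria(m2ll, P, N=66)
        assert round(got_aic) == aic
        assert round(got_bic) == bic

    @pytest.mark.parametrize("name,m2ll,P,aic,bic", TABLE)
    def test_parameter_counting_convention(self, name, m2ll, P, aic, bic):
        assert count_parameters(name, "combined") == P

    def test_zero_parameters(self):
        aic, bic = information_criteria(1234.0, 0, 10)
        assert aic == 1234.0 and bic == 1234.0


class TestRegression:
    def test_exact_proportional_pairs(self):
        beta = np.linspace(0.04, 0.12, 12)
        k, c, r2 = regress_alpha_beta(7.87 * beta, beta)
        assert k == pytest.approx(7.87)
        assert c == 0.0
        assert r2 == pytest.approx(1.0)

    def test_intercept_estimated_on_request(self):
        beta = np.linspace(0.04, 0.12, 12)
        k, c, r2 = regress_alpha_beta(5.0 * beta + 0.1, beta, fit_intercept=True)
        assert k == pytest.approx(5.0) and c == pytest.approx(0.1)

    def test_degenerate_beta_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            regress_alpha_beta([0.5, 0.6, 0.7], [0.07, 0.07, 0.07])

    def test_needs_three_animals(self):
        with pytest.raises(ValueError, match="3 animals"):
            regress_alpha_beta([0.5, 0.6], [0.06, 0.07])

    def test_high_random_effect_correlation_gives_high_r2(self, gompertz_fit):
        ebes = gompertz_fit.ebe_modes()
        _, _, r2 = regress_alpha_beta(ebes["alpha"], ebes["beta"],
                                      fit_intercept=True)
        assert r2 > 0.9


def _tiny_cohort(n=12, seed=0, sd=1e-4, sigma=(0.5, 0.01)):
    pop = PopulationParams.from_sd_corr("gompertz", (0.58, 0.072),
                                        (sd, sd), 0.0, sigma)
    design = StudyDesign(n, 1.0, "mm3", (11, 14, 18, 21, 25, 28, 32, 35, 39),
                         cap=None)
    return pop, generate_cohort(pop, design, seed=seed)


class TestSAEM:
    def test_noiseless_limit_recovers_mu_within_1pct(self):
        pop, cohort = _tiny_cohort()
        fit = PopulationModel(cohort, "gompertz", settings=FAST_SAEM).fit(
            seed=1, compute_rse=False)
        np.testing.assert_allclose(fit.mu, pop.mu, rtol=0.01)

    def test_same_seed_identical_estimates(self):
        _, cohort = _tiny_cohort(n=8)
        fits = [PopulationModel(cohort, "gompertz", settings=FAST_SAEM).fit(
            seed=3, compute_rse=False) for _ in range(2)]
        np.testing.assert_array_equal(fits[0].mu, fits[1].mu)
        np.testing.assert_array_equal(fits[0].omega, fits[1].omega)
        np.testing.assert_array_equal(fits[0].sigma, fits[1].sigma)

    def test_homogeneous_data_drives_omega_to_zero(self):
        _, cohort = _tiny_cohort(n=16, seed=2)
        fit = PopulationModel(cohort, "gompertz", settings=FAST_SAEM).fit(
            seed=1, compute_rse=False)
        assert np.all(fit.params.omega_sd < 1e-2)

    def test_needs_two_animals(self, gompertz_pop):
        design = StudyDesign(1, 1.0, "mm3", (11, 14, 18))
        cohort = generate_cohort(gompertz_pop, design, seed=0)
        with pytest.raises(ValueError, match="2 animals"):
            PopulationModel(cohort, "gompertz")


class TestLogLikelihood:
    def test_degenerate_omega_matches_closed_form(self):
        pop, cohort = _tiny_cohort(n=6)
        problem = SAEMProblem(cohort, "gompertz")
        m = np.log(pop.mu)
        sigma = np.asarray(pop.sigma)
        m2ll, se, _ = loglik_importance_sampling(
            problem, m, np.zeros((2, 2)), sigma, {}, M=100, seed=0)
        direct = problem.individual_loglik(np.tile(m, (6, 1)), sigma).sum()
        assert m2ll == pytest.approx(-2 * direct)
        assert se == 0.0

    def test_monte_carlo_variance_shrinks_with_draws(self, small_gompertz_cohort,
                                                     gompertz_fit):
        problem = SAEMProblem(small_gompertz_cohort, "gompertz")
        params = gompertz_fit.params
        m = np.log(params.mu)
        vals = {}
        for M in (100, 400):
            vals[M] = [loglik_importance_sampling(
                problem, m, params.omega, params.sigma, {}, M=M, seed=s)[0]
                for s in range(8)]
        assert np.var(vals[400]) < np.var(vals[100])

    def test_misspecified_exponential_has_larger_minus2ll(
            self, small_gompertz_cohort, fast_settings):
        fits = {}
        for name in ("gompertz", "exponential"):
            fits[name] = PopulationModel(
                small_gompertz_cohort, name, settings=fast_settings).fit(
                seed=2, compute_rse=False, loglik_samples=500)
        assert fits["exponential"].minus2ll > fits["gompertz"].minus2ll + 50
        assert fits["exponential"].aic > fits["gompertz"].aic


class TestEBE:
    def test_noiseless_single_animal_recovery(self):
        pop, cohort = _tiny_cohort(n=4, sd=0.15, sigma=(0.05, 0.001))
        fit = PopulationModel(cohort, "gompertz", settings=FAST_SAEM).fit(
            seed=1, compute_rse=False)
        ebes = fit.ebe_modes()
        true = cohort.meta["theta_true"]
        got = ebes[["alpha", "beta"]].to_numpy()
        np.testing.assert_allclose(got, true, rtol=0.02)

    def test_sparse_animal_shrinks_towards_population(self, gompertz_cohort):
        # truncate the first animal to a single observation
        df = gompertz_cohort.data.copy()
        first = gompertz_cohort.ids[0]
        keep = ~((df["ID"] == first) & (df.groupby("ID").cumcount() > 0))
        from growthpop import Cohort
        cohort = Cohort(df[keep], gompertz_cohort.inj, gompertz_cohort.unit)
        fit = PopulationModel(cohort, "gompertz", settings=FAST_SAEM).fit(
            seed=1, compute_rse=False)
        ebes = fit.ebe_modes().set_index("ID")
        dist = np.abs(np.log(ebes[["alpha", "beta"]]) - np.log(fit.mu)).sum(axis=1)
        rich = [a for a, t, _ in cohort.per_animal() if len(t) >= 8]
        assert dist.loc[first] < np.median(dist.loc[rich])


class TestDiagnostics:
    def test_iwres_zero_when_data_equals_curve(self):
        pop, cohort = _tiny_cohort(n=4, sd=1e-6, sigma=(0.0, 1e-9))
        fit = PopulationModel(cohort, "gompertz", settings=FAST_SAEM).fit(
            seed=1, compute_rse=False)
        iw = fit.iwres()
        assert np.all(np.abs(iw["IWRES"]) < 0.2)

    def test_iwres_standardization_under_true_model(self, gompertz_fit):
        iw = gompertz_fit.iwres()
        assert -0.1 < iw["IWRES"].mean() < 0.1
        # EBE plug-in shrinks residuals by ~sqrt(1 - p/n_i)
        assert 0.8 < iw["IWRES"].std() < 1.05

    def test_iwres_skewness_flags_exponential_misfit(
            self, gompertz_pop, fast_settings):
        # a follow-up spanning early growth exposes the exponential misfit
        from scipy.stats import skew
        design = StudyDesign(24, 1.0, "mm3",
                             (6, 9, 13, 16, 20, 23, 27, 30, 34, 37), cap=2000.0)
        cohort = generate_cohort(gompertz_pop, design, seed=21)
        sk = {}
        for name in ("gompertz", "exponential"):
            fit = PopulationModel(cohort, name, settings=fast_settings).fit(
                seed=4, compute_rse=False)
            sk[name] = abs(skew(fit.iwres()["IWRES"]))
        assert sk["exponential"] > sk["gompertz"]

    def test_vpc_calibrated_under_true_model(self, gompertz_fit):
        v = gompertz_fit.vpc(n_replicates=200, seed=0)
        assert (v.groupby("bin")["percentile"].apply(
            lambda s: list(s) == sorted(s)).all())
        assert v["inside"].mean() >= 0.8

    def test_vpc_bands_collapse_without_noise_or_variability(self):
        pop, cohort = _tiny_cohort(n=6, sd=1e-8, sigma=(1e-6, 0.0))
        fit = PopulationModel(cohort, "gompertz", settings=FAST_SAEM).fit(
            seed=1, compute_rse=False)
        v = fit.vpc(n_replicates=50, seed=0)
        width = (v["predicted_hi"] - v["predicted_lo"]) / v["predicted_median"]
        assert np.all(width < 1e-3)

    def test_vpc_detects_exponential_misspecification(
            self, small_gompertz_cohort, fast_settings):
        fit = PopulationModel(small_gompertz_cohort, "exponential",
                              settings=fast_settings).fit(seed=4, compute_rse=False)
        v = fit.vpc(n_replicates=200, seed=0)
        assert (~v["inside"]).mean() > 0.3

    def test_percentile_bands_ordered_in_every_bin(self, gompertz_fit):
        v = gompertz_fit.vpc(n_replicates=100, seed=1)
        for _, grp in v.groupby("bin"):
            med = grp.sort_values("percentile")["predicted_median"].to_numpy()
            assert np.all(np.diff(med) >= 0)


def test_spec_validation():
    with pytest.raises(ValueError, match="unknown model"):
        NLMEModelSpec("cubic")
    with pytest.raises(ValueError, match="error_model"):
        NLMEModelSpec("gompertz", "multiplicative")
    assert NLMEModelSpec("gompertz").omega_structure == "full"
    assert NLMEModelSpec("logistic").omega_structure == "diagonal"
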