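"""Backward age prediction: LM route, Fisher information, Bayesian route."""

import math

import numpy as np
import pytest

from growthpop import (
    Gompertz,
    InjectionSpec,
    PopulationParams,
    PredictionTask,
    ReducedGompertz,
    bayes_posterior_sample,
    lm_fit_last3,
    predict_age,
    tasks_from_cohort,
)
from growthpop.backward import (
    LMEstimate,
    fisher_information,
    lm_prediction_interval,
    loglik_last3,
)
from growthpop.models import InitialCondition, curve_from_VI

INJ = InjectionSpec(1.0)
T3 = np.array([0.0, 3.0, 7.0])


def _noiseless_task(model, a_true=30.0, sigma=(20.5, 0.0), inj=INJ,
                    times=T3, animal="x"):
    """Exact 3-point task from a known model grown for a_true days."""
    V_I = float(model.solve(inj, InitialCondition(0.0, inj.V_inj), [a_true])[0])
    y = model.solve(inj, InitialCondition(0.0, V_I), times)
    return PredictionTask(animal, times, y, a_true, inj, np.asarray(sigma))


REDUCED_PRIOR = PopulationParams.from_sd_corr(
    "reduced_gompertz", mu=(0.075,), omega_sd=(0.13,), sigma=(14.8, 0.17),
    fixed={"k": 7.87})
GOMPERTZ_PRIOR = PopulationParams.from_sd_corr(
    "gompertz", mu=(0.58, 0.072), omega_sd=(0.19, 0.26), corr=0.981,
    sigma=(20.5, 0.11))


class TestTasks:
    def test_tasks_keep_last_three_and_reanchor_clock(self, reduced_cohort):
        sigma = (14.8, 0.17)
        tasks = tasks_from_cohort(reduced_cohort, sigma)
        assert len(tasks) == reduced_cohort.n_animals
        for task, (animal, t, y) in zip(tasks, reduced_cohort.per_animal()):
            assert task.animal_id == animal
            assert task.times[0] == 0.0
            assert task.a_true == t[-3]
            np.testing.assert_array_equal(task.y, y[-3:])

    def test_exactly_three_increasing_observations_required(self):
        with pytest.raises(ValueError):
            PredictionTask("x", [0.0, 1.0], [10.0, 20.0], 5.0, INJ, (1.0, 0.0))
        with pytest.raises(ValueError, match="increasing"):
            PredictionTask("x", [0.0, 2.0, 1.0], [10, 20, 30], 5.0, INJ, (1, 0))


class TestLikelihoodMaximization:
    def test_noise_free_gompertz_recovers_parameters_and_age(self):
        model = Gompertz(0.6, 0.08)
        task = _noiseless_task(model)
        est = lm_fit_last3(task, "gompertz", theta_ref=np.array([0.58, 0.072]),
                           seed=0)
        np.testing.assert_allclose(est.theta_hat, [0.6, 0.08], rtol=1e-4)
        np.testing.assert_allclose(est.theta_hat, np.exp(est.gamma_hat))
        assert abs(est.a_hat - 30.0) < 1e-4
        assert est.s2 < 1e-10

    def test_noise_free_reduced_recovers_beta(self):
        model = ReducedGompertz(0.075, 7.87)
        task = _noiseless_task(model, sigma=(14.8, 0.0))
        est = lm_fit_last3(task, "reduced_gompertz", k_pop=7.87,
                           theta_ref=np.array([0.06]), seed=0)
        assert est.theta_hat[0] == pytest.approx(0.075, rel=1e-5)
        assert abs(est.a_hat - 30.0) < 1e-4

    def test_s2_divisor_depends_on_parameter_count(self):
        """s^2 uses 3 - p degrees of freedom: /1 for Gompertz, /2 reduced."""
        rng = np.random.default_rng(0)
        model = ReducedGompertz(0.08, 7.87)
        task = _noiseless_task(model, sigma=(10.0, 0.0))
        noisy = task.y + rng.normal(0, 10.0, 3)
        noisy[0] = task.y[0]  # keep the anchor point
        task = PredictionTask("x", task.times, noisy, 30.0, INJ, (10.0, 0.0))
        for name, k_pop, p in (("reduced_gompertz", 7.87, 1), ("gompertz", None, 2)):
            est = lm_fit_last3(task, name, k_pop=k_pop, seed=1)
            f = curve_from_VI(name, est.theta_hat, task.times, task.V_I, 1.0,
                              {"k": 7.87} if k_pop else None)
            ssq = float(np.sum(((task.y - f) / 10.0) ** 2))
            assert est.s2 == pytest.approx(ssq / (3 - p), rel=1e-9)

    def test_reduced_model_needs_population_k(self):
        task = _noiseless_task(ReducedGompertz(0.075, 7.87))
        with pytest.raises(ValueError, match="population k"):
            lm_fit_last3(task, "reduced_gompertz", k_pop=None)


class TestFisherInformation:
    def test_homoscedastic_reduction_is_jtj_over_sigma1sq(self):
        """With sigma2 = 0 the information is J^T J / sigma1^2."""
        task = _noiseless_task(Gompertz(0.6, 0.08), sigma=(12.0, 0.0))
        gamma = np.log([0.6, 0.08])
        fim = fisher_information(gamma, task, "gompertz")
        step = 1e-6
        J = np.empty((2, 3))
        for l in range(2):
            e = np.zeros(2); e[l] = step
            fp = curve_from_VI("gompertz", np.exp(gamma + e), task.times,
                               task.V_I, 1.0)
            fm = curve_from_VI("gompertz", np.exp(gamma - e), task.times,
                               task.V_I, 1.0)
            J[l] = (fp - fm) / (2 * step)
        np.testing.assert_allclose(fim, J @ J.T / 12.0**2, rtol=1e-6)

    @pytest.mark.parametrize("theta", [(0.5, 0.06), (0.7, 0.1), (0.3, 0.04)])
    def test_symmetric_positive_semidefinite(self, theta):
        task = _noiseless_task(Gompertz(*theta), sigma=(15.0, 0.1))
        fim = fisher_information(np.log(theta), task, "gompertz")
        np.testing.assert_allclose(fim, fim.T)
        assert np.all(np.linalg.eigvalsh(fim) >= -1e-8)

    def test_matches_negative_expected_hessian_of_loglik(self):
        """Oracle: FD Hessian of the exact expected log-likelihood."""
        theta0 = np.array([0.6, 0.08])
        task = _noiseless_task(Gompertz(*theta0), sigma=(14.8, 0.17))
        gamma0 = np.log(theta0)
        f0 = curve_from_VI("gompertz", theta0, task.times, task.V_I, 1.0)
        g0 = task.sigma[0] + task.sigma[1] * f0

        def expected_ll(gamma):
            # E_y[l(gamma)] for y ~ N(f(gamma0), g(gamma0)^2), closed form
            f = curve_from_VI("gompertz", np.exp(gamma), task.times, task.V_I, 1.0)
            g = task.sigma[0] + task.sigma[1] * f
            return float(np.sum(
                -np.log(g) - 0.5 * ((f0 - f) ** 2 + g0**2) / g**2
                - 0.5 * math.log(2 * math.pi)))

        h = 1e-4
        H = np.empty((2, 2))
        for a in range(2):
            for b in range(2):
                ea = np.zeros(2); ea[a] = h
                eb = np.zeros(2); eb[b] = h
                H[a, b] = (expected_ll(gamma0 + ea + eb)
                           - expected_ll(gamma0 + ea - eb)
                           - expected_ll(gamma0 - ea + eb)
                           + expected_ll(gamma0 - ea - eb)) / (4 * h * h)
        fim = fisher_information(gamma0, task, "gompertz")
        np.testing.assert_allclose(fim, -H, rtol=1e-4)


class TestPredictionInterval:
    def test_vanishing_covariance_collapses_pi_to_point(self):
        model = ReducedGompertz(0.075, 7.87)
        task = _noiseless_task(model, sigma=(14.8, 0.0))
        est = lm_fit_last3(task, "reduced_gompertz", k_pop=7.87, seed=0)
        est.cov = np.array([[1e-18]])
        lo, hi = lm_prediction_interval(est, task, n_draws=500, seed=1)
        assert hi - lo < 1e-3
        assert lo <= est.a_hat <= hi

    def test_pi_width_grows_with_s2(self):
        model = ReducedGompertz(0.075, 7.87)
        task = _noiseless_task(model, sigma=(14.8, 0.0))
        est = lm_fit_last3(task, "reduced_gompertz", k_pop=7.87, seed=0)
        base_cov = np.array([[1e-6]])
        widths = []
        for scale in (1.0, 4.0, 16.0):
            est.cov = base_cov * scale  # cov scales linearly in s^2
            lo, hi = lm_prediction_interval(est, task, n_draws=2000, seed=2)
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_infeasible_draws_counted_and_flagged(self):
        # V_I close to the point-estimate capacity: parameter draws whose
        # alpha/beta falls below log(V_I) are infeasible and must be dropped
        model = Gompertz(0.58, 0.072)
        V_I = 2500.0
        y = model.solve(INJ, InitialCondition(0.0, V_I), T3)
        task = PredictionTask("x", T3, y, 80.0, INJ, (14.8, 0.0))
        est = LMEstimate(model_name="gompertz", theta_hat=np.array([0.58, 0.072]),
                         gamma_hat=np.log([0.58, 0.072]),
                         cov=np.diag([0.05**2, 0.008**2]), s2=1.0, a_hat=None,
                         pi=None, singular=False)
        lm_prediction_interval(est, task, n_draws=1000, seed=3)
        assert 0.0 < est.infeasible_fraction < 1.0
        assert est.pi is not None


class TestBayes:
    def test_degenerate_prior_concentrates_at_mu(self):
        prior = PopulationParams("reduced_gompertz", (0.075,),
                                 np.zeros((1, 1)), (14.8, 0.17), {"k": 7.87})
        task = _noiseless_task(ReducedGompertz(0.075, 7.87), sigma=(14.8, 0.17))
        est = bayes_posterior_sample(task, prior, n_draws=400, warmup=200,
                                     seed=0)
        assert np.all(est.draws_theta[:, 0] == pytest.approx(0.075))
        # age spread driven only by V_I measurement uncertainty
        assert np.std(est.ages) < 2.0

    def test_default_draw_count_is_2000(self):
        task = _noiseless_task(ReducedGompertz(0.075, 7.87), sigma=(14.8, 0.17))
        est = bayes_posterior_sample(task, REDUCED_PRIOR, seed=1)
        assert len(est.draws_VI) == 2000
        assert est.pi[0] <= est.a_hat <= est.pi[1]
        assert est.rhat < 1.01 and est.ess > 400

    def test_time_translation_equivariance(self, reduced_cohort):
        """Shifting the measurement clock leaves the predicted age unchanged."""
        sigma = (14.8, 0.17)
        task = tasks_from_cohort(reduced_cohort, sigma)[0]
        shifted = PredictionTask(task.animal_id, task.times, task.y,
                                 task.a_true + 11.0, task.inj, sigma)
        a = bayes_posterior_sample(task, REDUCED_PRIOR, n_draws=400,
                                   warmup=200, seed=5)
        b = bayes_posterior_sample(shifted, REDUCED_PRIOR, n_draws=400,
                                   warmup=200, seed=5)
        assert a.a_hat == pytest.approx(b.a_hat)

    def test_unit_coherence_of_lm_and_bayes(self):
        """Rescaling V_inj, sizes and sigma1 by a common factor is neutral."""
        model = ReducedGompertz(0.08, 7.87)
        task = _noiseless_task(model, a_true=25.0, sigma=(14.8, 0.17))
        c = 50.0
        inj_c = InjectionSpec(c * INJ.V_inj)
        task_c = PredictionTask("x", task.times, c * task.y, task.a_true,
                                inj_c, (c * 14.8, 0.17))
        lm_a = lm_fit_last3(task, "reduced_gompertz", k_pop=7.87, seed=2)
        lm_b = lm_fit_last3(task_c, "reduced_gompertz", k_pop=7.87, seed=2)
        assert lm_a.a_hat == pytest.approx(lm_b.a_hat, rel=1e-6)
        prior_c = PopulationParams("reduced_gompertz", REDUCED_PRIOR.mu,
                                   REDUCED_PRIOR.omega, (c * 14.8, 0.17),
                                   {"k": 7.87})
        ba = bayes_posterior_sample(task, REDUCED_PRIOR, n_draws=400,
                                    warmup=200, seed=3)
        bb = bayes_posterior_sample(task_c, prior_c, n_draws=400,
                                    warmup=200, seed=3)
        assert ba.a_hat == pytest.approx(bb.a_hat, rel=1e-9)

    def test_reduced_pis_narrower_than_gompertz_on_matched_tasks(
            self, reduced_cohort):
        """One individual parameter buys precision: the reduced model's
        Bayesian intervals are narrower than the full Gompertz ones in the
        mean over matched tasks (per-task differences are often near-ties
        on self-consistent synthetic data)."""
        sigma = (14.8, 0.17)
        tasks = tasks_from_cohort(reduced_cohort, sigma)[:12]
        red_w, gom_w = [], []
        for i, task in enumerate(tasks):
            red = bayes_posterior_sample(task, REDUCED_PRIOR, n_draws=1000,
                                         warmup=400, seed=100 + i)
            gom = bayes_posterior_sample(task, GOMPERTZ_PRIOR, n_draws=1000,
                                         warmup=400, seed=200 + i)
            red_w.append(red.pi[1] - red.pi[0])
            gom_w.append(gom.pi[1] - gom.pi[0])
        assert np.mean(red_w) < np.mean(gom_w)
        assert np.mean(np.array(red_w) < np.array(gom_w)) >= 0.5


class TestPredictAge:
    def test_anchor_at_injection_size_gives_age_zero(self):
        y = np.array([1.0, 1.0001, 1.0002])
        task = PredictionTask("x", T3, y, 0.5, INJ, (0.01, 0.0))
        est = lm_fit_last3(task, "reduced_gompertz", k_pop=7.87,
                           theta_ref=np.array([0.075]), seed=0)
        pred = predict_age(est, task)
        assert abs(pred.a_hat) < 0.5

    def test_result_fields_consistent(self, reduced_cohort):
        task = tasks_from_cohort(reduced_cohort, (14.8, 0.17))[1]
        est = bayes_posterior_sample(task, REDUCED_PRIOR, n_draws=400,
                                     warmup=200, seed=9)
        pred = predict_age(est, task)
        assert pred.method == "Bayesian"
        assert pred.pi_width == pytest.approx(est.pi[1] - est.pi[0])
        assert pred.covered == (est.pi[0] <= task.a_true <= est.pi[1])

    def test_loglik_is_finite_and_peaked_at_truth(self):
        task = _noiseless_task(ReducedGompertz(0.075, 7.87), sigma=(14.8, 0.0))
        ll_true = loglik_last3([0.075], task, "reduced_gompertz", k_pop=7.87)
        ll_off = loglik_last3([0.12], task, "reduced_gompertz", k_pop=7.87)
        assert ll_true > ll_off
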