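"""Censored MLE fits checked against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import optimize

import ddm
from ddm.errors import ComparisonError, DomainError, FitError
from ddm.parametric import censored_loglik

from conftest import build_cohort


def cohort_from(gen, n, seed, floor=1e-9):
    design = ddm.StudyDesign(n, censor_horizon=24.0, duration_floor=floor,
                             seed=seed)
    return ddm.generate_cohort(design, gen)


class TestExponential:
    def test_uncensored_mean(self):
        fit = ddm.fit_exponential(build_cohort([(2, True), (4, True), (6, True)]))
        assert fit.params["theta"] == pytest.approx(4.0)

    def test_censored_closed_form(self):
        # total time 1 + 3 + 5 over 2 events
        fit = ddm.fit_exponential(
            build_cohort([(1, True), (3, True), (5, False)])
        )
        assert fit.params["theta"] == pytest.approx(4.5)

    def test_closed_form_matches_numeric_maximum(self):
        cohort = cohort_from(ddm.GeneratorSpec.exponential(5.99), 300, seed=4,
                             floor=0.5)
        fit = ddm.fit_exponential(cohort)
        res = optimize.minimize_scalar(
            lambda th: -censored_loglik("exponential", {"theta": th}, cohort),
            bounds=(0.1, 50.0), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.params["theta"] == pytest.approx(res.x, abs=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(FitError):
            ddm.fit_exponential(build_cohort([(24, False)]))

    def test_added_censoring_never_raises_hazard(self):
        base = [(1, True), (3, True), (7, True)]
        theta0 = ddm.fit_exponential(build_cohort(base)).params["theta"]
        theta1 = ddm.fit_exponential(
            build_cohort(base + [(24, False), (24, False)])
        ).params["theta"]
        assert theta1 >= theta0  # hazard 1/theta decreases with added exposure


class TestWeibull:
    def test_two_point_fit_matches_grid_search(self):
        cohort = build_cohort([(1.0, True), (math.e, True)])
        fit = ddm.fit_weibull(cohort)
        assert fit.converged
        # brute-force oracle: dense grid over (alpha, beta), then refined
        best = None
        a_grid = np.linspace(0.5, 4.0, 200)
        b_grid = np.linspace(0.3, 5.0, 200)
        for _ in range(3):
            lls = np.array([
                [censored_loglik("weibull", {"alpha": a, "beta": b}, cohort)
                 for b in b_grid]
                for a in a_grid
            ])
            i, j = np.unravel_index(np.argmax(lls), lls.shape)
            best = (a_grid[i], b_grid[j])
            a_grid = np.linspace(best[0] * 0.97, best[0] * 1.03, 200)
            b_grid = np.linspace(best[1] * 0.97, best[1] * 1.03, 200)
        assert fit.params["alpha"] == pytest.approx(best[0], abs=1e-3)
        assert fit.params["beta"] == pytest.approx(best[1], abs=1e-3)

    def test_shape_one_reduces_to_exponential_likelihood(self, reference_cohort):
        for theta in (2.0, 5.99, 11.0):
            ll_weib = censored_loglik(
                "weibull", {"alpha": theta, "beta": 1.0}, reference_cohort
            )
            ll_exp = censored_loglik(
                "exponential", {"theta": theta}, reference_cohort
            )
            assert ll_weib == pytest.approx(ll_exp, rel=1e-12)

    def test_single_distinct_event_time_rejected(self):
        with pytest.raises(FitError):
            ddm.fit_weibull(build_cohort([(2, True), (2, True), (24, False)]))


class TestLogNormal:
    def test_two_point_log_moments(self):
        fit = ddm.fit_lognormal(build_cohort([(1.0, True), (math.exp(2.0), True)]))
        assert fit.params["mu"] == pytest.approx(1.0, abs=1e-4)
        assert fit.params["sigma"] == pytest.approx(1.0, abs=1e-4)

    def test_uncensored_fit_equals_log_moment_closed_form(self):
        # without censoring the MLE is the mean and (divide-by-n) sd of ln t
        rng = np.random.default_rng(8)
        times = np.exp(rng.normal(1.15, 1.14, size=200))
        cohort = ddm.Cohort(times, np.ones(200, dtype=bool))
        fit = ddm.fit_lognormal(cohort)
        logs = np.log(times)
        assert fit.params["mu"] == pytest.approx(logs.mean(), abs=1e-4)
        assert fit.params["sigma"] == pytest.approx(logs.std(ddof=0), abs=1e-4)


class TestFittedOptimaAreMaxima:
    @pytest.mark.parametrize("fitter", [ddm.fit_exponential, ddm.fit_weibull,
                                        ddm.fit_lognormal])
    def test_loglik_beats_random_perturbations(self, fitter,
                                               lognormal_cohort_10k):
        cohort = lognormal_cohort_10k
        fit = fitter(cohort)
        assert fit.converged
        rng = np.random.default_rng(13)
        for _ in range(100):
            perturbed = {
                name: value * math.exp(rng.normal(0, 0.05))
                if name != "mu" else value + rng.normal(0, 0.05)
                for name, value in fit.params.items()
            }
            assert censored_loglik(fit.family, perturbed, cohort) <= fit.loglik


class TestParameterRecovery:
    """Each family's censored MLE recovers the generating parameters."""

    CASES = {
        "exponential": (ddm.GeneratorSpec.exponential(5.99), ddm.fit_exponential),
        "weibull": (ddm.GeneratorSpec.weibull(5.61, 0.85), ddm.fit_weibull),
        "lognormal": (ddm.GeneratorSpec.lognormal(1.15, 1.14), ddm.fit_lognormal),
    }

    @pytest.mark.parametrize("family", CASES)
    def test_bias_within_three_mc_standard_errors(self, family):
        gen, fitter = self.CASES[family]
        estimates = {name: [] for name in gen.params}
        n_reps, n = 40, 500
        for rep in range(n_reps):
            cohort = cohort_from(gen, n, seed=1000 + rep)
            fit = fitter(cohort)
            for name in estimates:
                estimates[name].append(fit.params[name])
        for name, values in estimates.items():
            values = np.asarray(values)
            se = values.std(ddof=1) / math.sqrt(n_reps)
            assert abs(values.mean() - gen.params[name]) < 3 * se + 1e-9


class TestSurvivalFunction:
    def test_exponential_starts_at_one(self):
        fit = ddm.ParametricFit("exponential", {"theta": 5.99}, 0.0, True, 1, 0)
        assert ddm.survival_function(fit, 1e-12) == pytest.approx(1.0)

    def test_lognormal_median(self):
        fit = ddm.ParametricFit("lognormal", {"mu": 1.15, "sigma": 1.14},
                                0.0, True, 1, 0)
        assert ddm.survival_function(fit, math.exp(1.15)) == pytest.approx(0.5)

    def test_weibull_at_scale_is_inverse_e(self):
        fit = ddm.ParametricFit("weibull", {"alpha": 5.61, "beta": 0.85},
                                0.0, True, 1, 0)
        assert ddm.survival_function(fit, 5.61) == pytest.approx(math.exp(-1))

    def test_nonpositive_time_rejected(self):
        fit = ddm.ParametricFit("exponential", {"theta": 5.99}, 0.0, True, 1, 0)
        with pytest.raises(DomainError):
            ddm.survival_function(fit, 0.0)


class TestCompareModels:
    def test_lognormal_data_ranks_lognormal_first(self, lognormal_cohort_10k):
        ranked = ddm.compare_models(ddm.fit_all(lognormal_cohort_10k))
        assert ranked[0].family == "lognormal"

    def test_single_fit_returned_unchanged(self, reference_cohort):
        fit = ddm.fit_exponential(reference_cohort)
        assert ddm.compare_models([fit]) == [fit]

    def test_exponential_data_nesting_aic_bound(self):
        # under a true exponential the Weibull's likelihood gain is the
        # half-chi-square LR statistic, so AIC_exp <= AIC_weib + 2 unless
        # the LR draw is extreme
        cohort = cohort_from(ddm.GeneratorSpec.exponential(6.0), 10_000, seed=3)
        fits = {f.family: f for f in ddm.fit_all(cohort)}
        assert fits["exponential"].aic <= fits["weibull"].aic + 2.0

    def test_mismatched_cohorts_rejected(self, reference_cohort,
                                         lognormal_cohort_10k):
        with pytest.raises(ComparisonError):
            ddm.compare_models([
                ddm.fit_exponential(reference_cohort),
                ddm.fit_exponential(lognormal_cohort_10k),
            ])
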