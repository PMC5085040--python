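"""Censored likelihoods, ML fitting, and delta-method uncertainty."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txinit import (
    InitiationModel,
    IntervalRecord,
    ObservationDesign,
    censored_loglik,
    delta_method_interval,
    fit_censored_gamma,
    fit_model,
    normal_ci95,
    sample_intervals,
)
from txinit.inference import ModelStructure
from txinit.simulate import ConditionMeta, simulate_condition

COND = ConditionMeta("C1")


def grid_frame(w, delta=60.0):
    """Grid-censor iid intervals with a uniform detection phase."""
    rng = np.random.default_rng(0)
    u = rng.uniform(0, delta, len(w))
    gap = delta * np.maximum(np.floor((w + u) / delta), 1.0)
    return pd.DataFrame({"lb_s": gap - delta, "ub_s": gap})


class TestCensoredLoglik:
    def test_right_censored_exponential_closed_form(self):
        r = [IntervalRecord("a", "C1", 2.0, math.inf)]
        assert censored_loglik(InitiationModel((1.0,)), r) == pytest.approx(-2.0)

    def test_total_probability_record(self):
        r = [IntervalRecord("a", "C1", 0.0, math.inf)]
        m = InitiationModel((0.3, 0.2), k_on=0.1, k_off=0.5)
        assert censored_loglik(m, r) == pytest.approx(0.0, abs=1e-12)

    def test_interval_dialect_closed_form(self):
        r = [IntervalRecord("a", "C1", 0.0, 60.0)]
        ll = censored_loglik(InitiationModel((0.01,)), r, dialect="interval")
        assert ll == pytest.approx(math.log(1 - math.exp(-0.6)), rel=1e-12)

    def test_phase_dialect_matches_simulated_gap_frequencies(self, rng):
        # the phase-averaged record probability is the law of the detection gap
        m = InitiationModel((0.01,), k_on=0.005, k_off=0.02)
        w = sample_intervals(m, 200000, rng)
        u = rng.uniform(0, 60, w.size)
        gap = 60 * np.maximum(np.floor((w + u) / 60), 1)  # gap 0 pools into 1
        for g in (60.0, 120.0, 300.0):
            emp = np.mean(gap == g)
            p = math.exp(censored_loglik(m, [IntervalRecord("a", "C1", g - 60, g)]))
            assert p == pytest.approx(emp, abs=4 * math.sqrt(emp / w.size) + 1e-4)

    def test_likelihood_additivity_under_duplication(self):
        recs = [IntervalRecord("a", "C1", 0.0, 60.0),
                IntervalRecord("b", "C1", 120.0, 180.0),
                IntervalRecord("c", "C1", 300.0, math.inf)]
        m = InitiationModel((0.004,), k_on=0.01, k_off=0.02)
        assert censored_loglik(m, recs + recs) == pytest.approx(
            2 * censored_loglik(m, recs), rel=1e-12)

    def test_zero_probability_gives_minus_inf(self):
        dist = stats.uniform(0, 10)  # no support beyond 10
        r = [IntervalRecord("a", "C1", 20.0, math.inf)]
        assert censored_loglik(dist, r) == -math.inf

    def test_permutation_invariance_of_seq_rates(self):
        recs = [IntervalRecord("a", "C1", 60.0, 120.0),
                IntervalRecord("b", "C1", 600.0, math.inf)]
        a = censored_loglik(InitiationModel((0.01, 0.002)), recs)
        b = censored_loglik(InitiationModel((0.002, 0.01)), recs)
        assert a == pytest.approx(b, rel=1e-9)

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError):
            censored_loglik(InitiationModel((1.0,)), [], dialect="midpoint")


class TestFitModel:
    def test_exponential_recovery_within_3se(self, rng):
        w = sample_intervals(InitiationModel((0.01,)), 5000, rng)
        fit = fit_model(grid_frame(w), ModelStructure(1, False), n_starts=3, seed=0)
        se = fit.standard_errors()[0]
        assert abs(fit.estimates[0] - math.log(0.01)) < 3 * se

    def test_duplication_doubles_loglik(self, rng):
        m = InitiationModel((0.004,), k_on=0.01, k_off=0.02)
        df = simulate_condition(m, ObservationDesign(n_cells=60), COND, rng)
        fit1 = fit_model(df, ModelStructure(1, True), n_starts=3, seed=1)
        df2 = pd.concat([df, df], ignore_index=True)
        # exact additivity at the fitted point ...
        assert censored_loglik(fit1.model, df2) == pytest.approx(
            2 * fit1.loglik, rel=1e-12)
        # ... and the re-fitted optimum doubles too
        fit2 = fit_model(df2, ModelStructure(1, True), n_starts=3, seed=1)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-5)

    def test_switching_recovery_study_design(self, rng):
        # study-like windows and grid; true rates (k_on, k_off, k1)
        true = np.log([0.002, 0.02, 0.001])
        m = InitiationModel((0.001,), k_on=0.002, k_off=0.02)
        df = simulate_condition(m, ObservationDesign(n_cells=3000), COND, rng)
        fit = fit_model(df, ModelStructure(1, True), n_starts=6, seed=2)
        z = (fit.estimates - true) / fit.standard_errors()
        assert np.all(np.abs(z) < 4.0)

    def test_optimum_at_least_truth(self, rng):
        m = InitiationModel((1 / 700,))
        wins = 0
        for rep in range(10):
            df = simulate_condition(m, ObservationDesign(n_cells=80), COND, rng)
            fit = fit_model(df, ModelStructure(1, False), n_starts=3, seed=rep)
            wins += fit.loglik >= censored_loglik(m, df) - 1e-9
        assert wins >= 5

    def test_censoring_aware_estimator_beats_naive_mean(self, rng):
        # with >=30% right-censoring the naive mean of bounded intervals
        # underestimates; the censored ML estimate does not
        true_mean = 3200.0
        m = InitiationModel((1 / true_mean,))
        design = ObservationDesign(n_cells=120)
        ml_means, naive_means, cens_fracs = [], [], []
        for rep in range(60):
            df = simulate_condition(m, design, COND, rng)
            cens_fracs.append(np.isinf(df["ub_s"]).mean())
            fit = fit_model(df, ModelStructure(1, False), n_starts=3, seed=rep)
            ml_means.append(1.0 / math.exp(fit.estimates[0]))
            b = df[np.isfinite(df["ub_s"])]
            naive_means.append(float((b["lb_s"] + b["ub_s"]).mean() / 2))
        assert np.mean(cens_fracs) > 0.30
        ml_means = np.array(ml_means)
        bias = ml_means.mean() - true_mean
        assert abs(bias) < 2 * ml_means.std(ddof=1) / math.sqrt(len(ml_means))
        assert np.mean(naive_means) < 0.8 * true_mean

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            fit_model([], ModelStructure(1, False))


class TestCensoredGamma:
    def test_exponential_data_median_to_mean(self, rng):
        w = sample_intervals(InitiationModel((1 / 500,)), 20000, rng)
        _, mom = fit_censored_gamma(grid_frame(w), seed=0)
        assert mom.median_to_mean == pytest.approx(math.log(2), abs=0.02)

    def test_shape_recovery(self, rng):
        w = rng.gamma(2.2, 400.0, size=5000)
        fit, mom = fit_censored_gamma(grid_frame(w), seed=0)
        se = fit.standard_errors()[0]
        assert abs(fit.estimates[0] - math.log(2.2)) < 3 * se
        assert mom.mean == pytest.approx(2.2 * 400.0, rel=0.05)

    def test_median_to_mean_invariant_under_pure_scaling(self, rng):
        # scaling every rate by a common temperature factor leaves the
        # interval shape (hence median/mean) unchanged
        ratios = []
        for scale in (1.0, 1.6, 2.2):
            m = InitiationModel((0.002 / scale,), k_on=0.01 / scale, k_off=0.02 / scale)
            df = simulate_condition(m, ObservationDesign(n_cells=600), COND,
                                    np.random.default_rng(11))
            _, mom = fit_censored_gamma(df, seed=1)
            ratios.append(mom.median_to_mean)
        assert np.ptp(ratios) < 0.06

    def test_all_censored_not_identifiable(self):
        recs = [IntervalRecord("a", "C1", 300.0, math.inf)] * 5
        with pytest.raises(ValueError):
            fit_censored_gamma(recs)


class TestDeltaMethod:
    def test_identity_transform_halfwidth(self, rng):
        w = sample_intervals(InitiationModel((0.01,)), 3000, rng)
        fit = fit_model(grid_frame(w), ModelStructure(1, False), n_starts=3, seed=0)
        res = delta_method_interval(fit, lambda th: th[0])
        lo, hi = res["ci95"]
        assert (hi - lo) / 2 == pytest.approx(1.96 * res["sd"], rel=1e-6)
        assert res["sd"] == pytest.approx(fit.standard_errors()[0], rel=1e-4)

    def test_nonconverged_fit_rejected(self):
        from txinit.inference import FitResult
        fit = FitResult("x", np.zeros(1), 0.0, np.eye(1), 1, 0, False, 1)
        with pytest.raises(ValueError):
            delta_method_interval(fit, lambda th: th[0])

    @pytest.mark.parametrize("est,sd,upper", [(22.5, 14.6, 51.116), (77.1, 6.64, 90.1144)])
    def test_printed_ci_pairs(self, est, sd, upper):
        lo, hi = normal_ci95(est, sd)
        assert hi == pytest.approx(upper, abs=5e-4)
        assert lo == pytest.approx(est - 1.96 * sd)
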