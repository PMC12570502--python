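"""Model-independent exponential fitting: recovery, model choice, lower limits."""

import numpy as np
import pytest

from rnapkin import (
    TimeCourse,
    compare_exponential_models,
    estimate_lower_limit,
    fit_double_exponential,
    fit_single_exponential,
)
from rnapkin.expfit import DegenerateDataError


def single_exp_tc(A, k, times=None, sd=0.0, seed=0):
    t = times if times is not None else np.geomspace(5e-3, 10.0, 25)
    y = A * (1 - np.exp(-k * t))
    if sd:
        y = np.clip(y + np.random.default_rng(seed).normal(0, sd, t.shape), 0, 1)
    return TimeCourse(t, {"product": y})


def double_exp_tc(Af, kf, As, ks, times=None, sd=0.0, seed=0):
    t = times if times is not None else np.geomspace(5e-3, 10.0, 25)
    y = Af * (1 - np.exp(-kf * t)) + As * (1 - np.exp(-ks * t))
    if sd:
        y = np.clip(y + np.random.default_rng(seed).normal(0, sd, t.shape), 0, 1)
    return TimeCourse(t, {"product": y})


class TestSingleExponential:
    def test_noise_free_recovery_is_exact(self):
        fit = fit_single_exponential(single_exp_tc(0.8, 1.0))
        assert fit.amplitudes[0] == pytest.approx(0.8, abs=1e-6)
        assert fit.rates[0] == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_response_is_degenerate(self):
        t = np.geomspace(5e-3, 10, 10)
        with pytest.raises(DegenerateDataError):
            fit_single_exponential(TimeCourse(t, {"product": np.zeros_like(t)}))

    def test_refit_of_own_prediction_is_fixed_point(self):
        fit = fit_single_exponential(single_exp_tc(0.9, 1.47, sd=0.02, seed=1))
        refit = fit_single_exponential(
            TimeCourse(np.geomspace(5e-3, 10, 25), {"product": fit.predict(np.geomspace(5e-3, 10, 25))})
        )
        assert refit.rates[0] == pytest.approx(fit.rates[0], rel=1e-4)
        assert refit.amplitudes[0] == pytest.approx(fit.amplitudes[0], rel=1e-4)

    def test_recovery_median_within_ten_percent(self):
        """Across 200 noisy datasets (sd 0.03) the median rate error stays <= 10%."""
        errs = []
        for seed in range(200):
            fit = fit_single_exponential(single_exp_tc(0.9, 1.47, sd=0.03, seed=seed))
            errs.append(abs(fit.rates[0] - 1.47) / 1.47)
        assert np.median(errs) <= 0.10


class TestDoubleExponential:
    def test_noise_free_biexponential_recovery(self):
        fit = fit_double_exponential(double_exp_tc(0.5, 1.47, 0.4, 0.35))
        assert fit.rates[0] == pytest.approx(1.47, rel=1e-4)
        assert fit.rates[1] == pytest.approx(0.35, rel=1e-4)
        assert fit.rates[0] >= fit.rates[1]

    def test_single_exponential_truth_flags_identifiability(self):
        fit = fit_double_exponential(single_exp_tc(0.8, 1.0))
        assert fit.identifiability_warning
        assert fit.rates[0] == pytest.approx(fit.rates[1], rel=0.5)

    def test_sse_never_worse_than_single(self):
        for seed in range(5):
            tc = double_exp_tc(0.5, 1.47, 0.4, 0.35, sd=0.03, seed=seed)
            f1, f2 = fit_single_exponential(tc), fit_double_exponential(tc)
            assert f2.sse <= f1.sse + 1e-12

    def test_monte_carlo_recovery_of_published_rates(self):
        """Rates generated at the published fast/slow pair (1.47, 0.35 s-1;
        ratio only ~4, a hard biexponential) are recovered over repeated
        noisy 3-replicate draws on the 25-point study grid.  Expected medians
        computed by this same Monte-Carlo oracle: ~15% for the fast rate and
        ~31% for the slow rate (the slow phase carries less information on a
        grid ending at 10 s)."""
        t = np.geomspace(5e-3, 10.0, 25)
        rng_errs_f, rng_errs_s = [], []
        for seed in range(100):
            reps = [
                double_exp_tc(0.45, 1.47, 0.45, 0.35, times=t, sd=0.03, seed=1000 * seed + r)
                for r in range(3)
            ]
            mean = np.mean([r.species("product") for r in reps], axis=0)
            fit = fit_double_exponential(TimeCourse(t, {"product": mean}))
            rng_errs_f.append(abs(fit.rates[0] - 1.47) / 1.47)
            rng_errs_s.append(abs(fit.rates[1] - 0.35) / 0.35)
        assert np.median(rng_errs_f) <= 0.25
        assert np.median(rng_errs_s) <= 0.35


class TestModelComparison:
    def test_biexponential_truth_prefers_order_two(self):
        tc = double_exp_tc(0.5, 3.0, 0.4, 0.2, sd=0.005, seed=0)
        cmp = compare_exponential_models(
            fit_single_exponential(tc), fit_double_exponential(tc)
        )
        assert cmp["preferred_order"] == 2

    def test_single_truth_rarely_prefers_order_two(self):
        prefer1 = 0
        for seed in range(100):
            tc = single_exp_tc(0.8, 1.0, sd=0.03, seed=seed)
            cmp = compare_exponential_models(
                fit_single_exponential(tc), fit_double_exponential(tc)
            )
            prefer1 += cmp["preferred_order"] == 1
        assert prefer1 >= 90

    def test_mixed_rates_fit_worse_by_single(self):
        tc = double_exp_tc(0.45, 1.47, 0.45, 0.35)
        f1, f2 = fit_single_exponential(tc), fit_double_exponential(tc)
        assert f1.sse > f2.sse

    def test_mismatched_data_rejected(self):
        f1 = fit_single_exponential(single_exp_tc(0.8, 1.0))
        f2 = fit_double_exponential(double_exp_tc(0.5, 2.0, 0.3, 0.2, times=np.geomspace(5e-3, 10, 30)))
        with pytest.raises(ValueError):
            compare_exponential_models(f1, f2)


class TestLowerLimit:
    def test_plateaued_data_sets_flag(self):
        fit = estimate_lower_limit(single_exp_tc(0.9, 2000.0))
        assert fit.lower_limit_flag

    def test_slow_data_does_not_set_flag(self):
        fit = estimate_lower_limit(single_exp_tc(0.9, 1.0))
        assert not fit.lower_limit_flag

    @pytest.mark.parametrize("true_k", [600.0, 1000.0, 5000.0])
    def test_reported_bound_never_exceeds_true_rate(self, true_k):
        for seed in range(5):
            fit = estimate_lower_limit(single_exp_tc(0.9, true_k, sd=0.02, seed=seed))
            assert fit.lower_limit_flag
            assert fit.rates[0] <= true_k
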