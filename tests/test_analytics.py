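"""Metric formulas against brute-force arithmetic, binned curves, the
response-share chi-square and latency summaries."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import fivechoice as fc
from fivechoice.trials import Trial
from conftest import run_stochastic_5cswm, run_stochastic_5csrtt


def make_trials(correct=0, incorrect=0, premature=0, omission=0,
                latency=800.0, spacing_ms=10_000):
    """Synthetic classified attention-task trials with evenly spaced onsets."""
    trials = []
    classes = (["correct"] * correct + ["incorrect"] * incorrect
               + ["premature"] * premature + ["omission"] * omission)
    for i, cls in enumerate(classes):
        t = Trial(index=i, start_ms=i * spacing_ms, cls=cls)
        if cls != "premature":
            t.stim_onset_ms = i * spacing_ms + 5000
        if cls == "correct":
            t.response_latency_ms = latency
            t.reward_latency_ms = latency + 300
        trials.append(t)
    return trials


class TestAttentionMetrics:
    def test_hand_arithmetic_example(self):
        s = fc.compute_5csrtt_metrics(make_trials(10, 5, 5, 5))
        assert s.trials == 25
        assert s.accuracy == pytest.approx(100 * 10 / 15)
        assert s.pct_omissions == pytest.approx(20.0)
        assert s.pct_premature == pytest.approx(20.0)

    def test_all_correct(self):
        s = fc.compute_5csrtt_metrics(make_trials(correct=12))
        assert (s.accuracy, s.pct_omissions, s.pct_premature) == (100.0, 0.0, 0.0)
        assert s.mean_response_latency_ms == 800.0

    def test_all_omissions_leaves_accuracy_undefined(self):
        s = fc.compute_5csrtt_metrics(make_trials(omission=9))
        assert s.pct_omissions == 100.0
        assert s.accuracy is None

    def test_fifty_randomized_fixtures_match_brute_force(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            c, i, p, o = (int(v) for v in rng.integers(0, 40, size=4))
            s = fc.compute_5csrtt_metrics(make_trials(c, i, p, o))
            n = c + i + p + o
            assert s.trials == n
            assert s.accuracy == (100.0 * c / (c + i) if c + i else None)
            assert s.pct_omissions == (100.0 * o / n if n else None)
            assert s.pct_premature == (100.0 * p / n if n else None)

    def test_class_swap_complement_identity(self):
        s1 = fc.compute_5csrtt_metrics(make_trials(correct=30, incorrect=10))
        s2 = fc.compute_5csrtt_metrics(make_trials(correct=10, incorrect=30))
        assert s1.accuracy + s2.accuracy == pytest.approx(100.0)


class TestWorkingMemoryMetrics:
    def test_perfect_agent_scores_100(self):
        params = fc.AgentParams(p_respond=1.0, p_correct_given_response=1.0,
                                premature_hazard_per_s=0.0)
        _, trials = run_stochastic_5cswm(seed=0, agent_params=params)
        s = fc.compute_5cswm_metrics(trials)
        assert s.trials > 30
        assert s.sp_accuracy == 100.0 and s.cp_accuracy == 100.0
        assert s.sp_pct_omissions == 0.0 and s.cp_pct_omissions == 0.0

    def test_uniform_choice_phase_gives_50pct(self):
        params = fc.AgentParams(p_respond=1.0, p_correct_given_response=1.0,
                                premature_hazard_per_s=0.0,
                                p_match_given_response=0.5)
        trials = []
        for seed in range(4):
            trials += run_stochastic_5cswm(seed=seed, agent_params=params)[1]
        s = fc.compute_5cswm_metrics(trials)
        n_cp = s.cp_match + s.cp_nonmatch
        assert n_cp > 100
        ci = 2.576 * np.sqrt(0.25 / n_cp)
        assert abs(s.cp_accuracy / 100 - 0.5) <= ci

    def test_sp_omission_excluded_from_cp_denominators(self):
        trials = [Trial(0, 0, cls="sp_omission"),
                  Trial(1, 10_000, cls="cp_match"),
                  Trial(2, 20_000, cls="cp_nonmatch")]
        s = fc.compute_5cswm_metrics(trials)
        assert s.sp_pct_omissions == pytest.approx(100 / 3)
        assert s.cp_accuracy == pytest.approx(50.0)
        assert s.cp_pct_omissions == 0.0

    def test_no_cp_trials_leaves_cp_metrics_undefined(self):
        s = fc.compute_5cswm_metrics([Trial(0, 0, cls="sp_omission")])
        assert s.cp_accuracy is None and s.cp_pct_omissions is None


class TestBinnedMetrics:
    def test_thirty_minute_session_three_minute_bins(self):
        _, trials = run_stochastic_5csrtt(seed=1)
        bm = fc.time_binned_metrics(trials, duration_ms=30 * 60_000)
        assert bm.n_bins == 10
        assert sum(bm.trial_counts) == len(trials)

    def test_empty_bin_metrics_are_undefined(self):
        trials = make_trials(correct=2, spacing_ms=1000)  # all in bin 0
        bm = fc.time_binned_metrics(trials, duration_ms=30 * 60_000)
        assert bm.trial_counts[5] == 0
        assert bm.accuracy[5] is None and bm.pct_omissions[5] is None
        assert bm.accuracy[0] == 100.0

    def test_uniform_trial_times_give_even_counts(self):
        _, trials = run_stochastic_5csrtt(seed=6)
        bm = fc.time_binned_metrics(trials, duration_ms=30 * 60_000)
        p = stats.chisquare(bm.trial_counts).pvalue
        assert p > 1e-4  # steady-state trial flow is near-uniform over bins

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            fc.time_binned_metrics([], duration_ms=1000, bin_width_ms=0)


class TestResponseShareTest:
    def test_identical_tables_statistic_zero(self):
        r = fc.response_share_test([10, 5, 3, 2], [10, 5, 3, 2])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.df == 3

    def test_matches_brute_force_expected_counts(self):
        a, b = [10, 10, 10, 10], [40, 0, 0, 0]
        r = fc.response_share_test(a, b)
        # brute force Pearson sum over the 2x4 table
        table = np.array([a, b], dtype=float)
        row = table.sum(1, keepdims=True)
        col = table.sum(0, keepdims=True)
        expected = row @ col / table.sum()
        brute = float(((table - expected) ** 2 / expected).sum())
        assert r.statistic == pytest.approx(brute)
        assert brute == pytest.approx(48.0)
        assert r.df == 3

    def test_double_zero_category_pooled(self):
        r = fc.response_share_test([10, 5, 0, 5], [8, 7, 0, 1])
        assert r.df == 2
        assert r.pooled_categories == ("premature",)

    def test_zero_vectors_rejected(self):
        with pytest.raises(ValueError):
            fc.response_share_test([0, 0, 0, 0], [0, 0, 0, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fc.response_share_test([1, -2, 3, 4], [1, 2, 3, 4])


class TestLatencySummary:
    def test_single_trial_all_quantiles_equal(self):
        out = fc.latency_summary(make_trials(correct=1, latency=800.0))
        assert set(out) == {"correct"}
        c = out["correct"]
        assert c["mean"] == c["median"] == c["q25"] == c["q75"] == 800.0
        assert sum(c["hist_counts"]) == 1

    def test_omissions_contribute_no_latency(self):
        out = fc.latency_summary(make_trials(correct=2, omission=5))
        assert "omission" not in out
        assert out["correct"]["n"] == 2

    def test_lognormal_sample_mean_within_ci(self):
        mu, sigma = np.log(850.0), 0.35
        params = fc.AgentParams(p_respond=1.0, p_correct_given_response=1.0,
                                premature_hazard_per_s=0.0,
                                response_latency_log_mu=mu,
                                response_latency_log_sigma=sigma)
        _, trials = run_stochastic_5csrtt(seed=3, agent_params=params,
                                          duration_ms=10**8, max_trials=1500)
        out = fc.latency_summary(trials)
        dist_mean = np.exp(mu + sigma**2 / 2)
        dist_sd = dist_mean * np.sqrt(np.exp(sigma**2) - 1)
        n = out["correct"]["n"]
        assert n == 1500
        assert abs(out["correct"]["mean"] - dist_mean) <= 3 * dist_sd / np.sqrt(n)

    def test_no_latencies_empty_summary(self):
        assert fc.latency_summary(make_trials(omission=3)) == {}
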