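"""Task-cycle semantics: response windows, rewards, time-outs, house-light
polarity, challenges, opto schedules and working-memory trial structure."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import fivechoice as fc
from conftest import (probe_cswm_draws, probe_cue_sequence,
                      run_scripted_5csrtt, run_stochastic_5csrtt,
                      run_stochastic_5cswm)


class TestFiveCSRTTCycle:
    def test_correct_poke_rewards_20ul(self):
        seed = 3
        cue = probe_cue_sequence(seed, 1)[0]
        log, trials = run_scripted_5csrtt([(6000, "poke", cue)], seed=seed,
                                          duration_ms=10_000)
        rewards = log.filter("reward")
        assert len(rewards) == 1
        assert rewards[0].payload_dict()["vol_ul"] == "20.0"
        assert trials[0].cls == "correct"

    def test_incorrect_poke_triggers_5s_timeout_with_houselight_bracket(self):
        seed = 3
        cue = probe_cue_sequence(seed, 1)[0]
        wrong = cue % 5 + 1
        log, trials = run_scripted_5csrtt([(6000, "poke", wrong)], seed=seed,
                                          duration_ms=12_000)
        assert trials[0].cls == "incorrect"
        ts = log.filter("timeout_start")[0]
        te = log.filter("timeout_end")[0]
        assert (ts.time, te.time) == (6000, 11000)  # exactly 5 s
        off = [e for e in log.filter("houselight_off") if e.time == 6000]
        on = [e for e in log.filter("houselight_on") if e.time == 11000]
        assert off and on

    @pytest.mark.parametrize(
        "poke_t,expected",
        [
            (8999, "correct"),   # stimulus-off (7000) + LH (2000) - 1 ms
            (9000, "omission"),  # exactly LH end: half-open window
            (9001, "omission"),  # past LH end
            (7000, "correct"),   # exactly SD end still counts (enters LH)
        ],
    )
    def test_limited_hold_boundary(self, poke_t, expected):
        seed = 9
        cue = probe_cue_sequence(seed, 1)[0]
        log, trials = run_scripted_5csrtt([(poke_t, "poke", cue)], seed=seed,
                                          duration_ms=13_500)
        assert trials[0].cls == expected

    def test_iti_initiated_by_receptacle_exit(self):
        seed = 3
        cue = probe_cue_sequence(seed, 1)[0]
        log, _ = run_scripted_5csrtt(
            [(6000, "poke", cue), (7000, "receptacle_entry", None),
             (9500, "receptacle_exit", None)], seed=seed, duration_ms=12_000)
        iti_starts = [e.time for e in log.filter("iti_start")]
        assert iti_starts == [0, 9500]


class TestHabituation:
    def _run(self, actions, duration_ms=60_000, params=None):
        agent = fc.ScriptedAgent([fc.ScriptedAction(*a) for a in actions])
        return fc.run_session(fc.build_habituation(params), agent, 0, duration_ms)

    def test_three_pokes_three_rewards_120ul(self):
        log = self._run([(1000, "poke", 1), (2000, "receptacle_entry", None),
                         (3000, "receptacle_exit", None), (4000, "poke", 4),
                         (5000, "receptacle_entry", None),
                         (6000, "receptacle_exit", None), (7000, "poke", 2)])
        rewards = log.filter("reward")
        assert len(rewards) == 3
        assert sum(float(r.payload_dict()["vol_ul"]) for r in rewards) == 120.0

    def test_no_pokes_no_rewards_session_runs_to_duration(self):
        log = self._run([], duration_ms=90_000)
        assert not log.filter("reward")
        assert log.events[-1].name == "session_end"
        assert log.events[-1].time == 90_000

    def test_default_reward_is_40ul_per_poke(self):
        log = self._run([(500, "poke", 5)])
        assert log.filter("reward")[0].payload_dict()["vol_ul"] == "40.0"

    def test_all_five_holes_lit_for_whole_session(self):
        log = self._run([], duration_ms=10_000)
        ons = sorted(int(e.payload) for e in log.filter("hole_light_on"))
        assert ons == [1, 2, 3, 4, 5]
        offs = [e for e in log.filter("hole_light_off")]
        assert all(e.time == 10_000 for e in offs)  # only at session end


class TestFiveCSWM:
    def test_sp_then_cp_match_rewards_10_then_60(self):
        seed = 4
        target, _distractor = probe_cswm_draws(seed, 1)[0]
        actions = [
            (6000, "poke", target),            # SP correct (SP starts at 5000)
            (7000, "receptacle_entry", None),  # collect small reward
            (9000, "receptacle_exit", None),   # delay (2 s) starts
            (11500, "poke", target),           # CP at 11000: match
            (12500, "receptacle_entry", None),
            (14000, "receptacle_exit", None),
        ]
        agent = fc.ScriptedAgent([fc.ScriptedAction(*a) for a in actions])
        log = fc.run_session(fc.build_5cswm(), agent, seed, 20_000)
        vols = [e.payload_dict()["vol_ul"] for e in log.filter("reward")]
        assert vols == ["10.0", "60.0"]
        trials = fc.segment_trials(log)
        assert trials[0].cls == "cp_match"
        assert log.filter("cp_start")[0].time == 11_000  # exit + 2 s delay

    def test_sp_omission_aborts_trial_without_cp(self):
        agent = fc.ScriptedAgent([])
        log = fc.run_session(fc.build_5cswm(), agent, 0, 22_000)
        trials = fc.segment_trials(log)
        assert trials[0].cls == "sp_omission"
        assert not log.filter("cp_start")
        # 5 s time-out follows the 10 s SP window (SP starts at 5 s)
        assert log.filter("timeout_start")[0].time == 15_000

    def test_sp_incorrect_aborts_trial(self):
        seed = 4
        target, _ = probe_cswm_draws(seed, 1)[0]
        wrong = target % 5 + 1
        agent = fc.ScriptedAgent([fc.ScriptedAction(6000, "poke", wrong)])
        log = fc.run_session(fc.build_5cswm(), agent, seed, 20_000)
        trials = fc.segment_trials(log)
        assert trials[0].cls == "sp_incorrect"
        assert not log.filter("cp_start")

    def test_cp_presents_sample_plus_one_distractor(self):
        log, trials = run_stochastic_5cswm(
            seed=8, agent_params=fc.AgentParams(p_respond=1.0,
                                                p_correct_given_response=1.0))
        cp_trials = [t for t in trials if t.cls and t.cls.startswith("cp")]
        assert cp_trials
        for t in cp_trials:
            lit = [e for e in t.events
                   if e.name == "hole_light_on" and e.time == t.cp_onset_ms]
            holes = sorted(int(e.payload) for e in lit)
            assert len(holes) == 2 and t.target_hole in holes

    def test_cp_never_without_sp_correct(self):
        _, trials = run_stochastic_5cswm(seed=9)
        for t in trials:
            if t.cls.startswith("cp"):
                assert t.sp_latency_ms is not None
                assert t.response_hole == t.target_hole

    def test_houselight_polarity_inverted_between_paradigms(self):
        log_att, _ = run_stochastic_5csrtt(seed=1, duration_ms=10 * 60_000)
        log_wm, _ = run_stochastic_5cswm(seed=1, duration_ms=10 * 60_000)
        # attention task: light on from start; off exactly during time-outs
        assert log_att.filter("houselight_on")[0].time == 0
        for e in log_att.filter("timeout_start"):
            assert any(o.time == e.time for o in log_att.filter("houselight_off"))
        # working-memory task: no light at start; on exactly during time-outs
        first_on = log_wm.filter("houselight_on")
        first_to = log_wm.filter("timeout_start")
        assert first_to and first_on
        assert first_on[0].time == first_to[0].time


class TestChallenges:
    def test_attention_challenge_shortens_sd_only(self):
        base = fc.FiveCSRTTParams()
        ch = fc.make_challenge(base, "attention")
        assert ch.sd_ms == 800
        assert ch.iti_ms == 5000
        assert (ch.lh_ms, ch.timeout_ms, ch.reward_ul) == (2000, 5000, 20.0)

    def test_fixed_iti_challenge(self):
        ch = fc.make_challenge(fc.FiveCSRTTParams(), "fixed_iti", 9000)
        log, trials = run_stochastic_5csrtt(
            seed=2, params=ch, duration_ms=10 * 60_000,
            agent_params=fc.AgentParams(premature_hazard_per_s=0.0))
        gaps = [t.stim_onset_ms - t.start_ms for t in trials
                if t.stim_onset_ms is not None]
        assert gaps and all(g == 9000 for g in gaps)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown challenge"):
            fc.make_challenge(fc.FiveCSRTTParams(), "sound", 1)

    def test_variable_iti_reproducible_and_uniform(self):
        ch = fc.make_challenge(fc.FiveCSRTTParams(), "variable_iti")
        assert ch.iti_ms == (5000, 7500, 12500)
        quiet = fc.AgentParams(premature_hazard_per_s=0.0, p_respond=1.0,
                               p_correct_given_response=1.0)
        gaps_by_run = []
        for _ in range(2):
            _, trials = run_stochastic_5csrtt(seed=6, params=ch,
                                              agent_params=quiet,
                                              duration_ms=30 * 60_000)
            gaps_by_run.append([t.stim_onset_ms - t.start_ms for t in trials])
        assert gaps_by_run[0] == gaps_by_run[1]  # seeded reproducibility
        gaps = np.asarray(gaps_by_run[0])
        assert set(gaps) <= {5000, 7500, 12500}
        counts = [int((gaps == v).sum()) for v in (5000, 7500, 12500)]
        assert sum(counts) > 100
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3  # consistent with uniform sampling


class TestOptoSchedules:
    def test_iti_anchor_brackets_every_iti_onset(self):
        machine = fc.build_5csrtt()
        fc.attach_opto_schedule(machine, fc.OptoSchedule("iti_onset", 4000))
        log = fc.run_session(machine, fc.StochasticAgent(), 3, 10 * 60_000)
        iti_times = [e.time for e in log.filter("iti_start")]
        highs = [e.time for e in log.filter("ttl_high")]
        lows = [e.time for e in log.filter("ttl_low")]
        assert highs[: len(iti_times)] == iti_times[: len(highs)]
        for h, lo in zip(highs, lows):
            assert lo - h == 4000

    def test_reward_collection_anchor(self):
        seed = 3
        cue = probe_cue_sequence(seed, 1)[0]
        machine = fc.build_5csrtt()
        fc.attach_opto_schedule(
            machine, fc.OptoSchedule("reward_collection", 2000, ttl_channel=2))
        agent = fc.ScriptedAgent([fc.ScriptedAction(6000, "poke", cue),
                                  fc.ScriptedAction(7200, "receptacle_entry")])
        log = fc.run_session(machine, agent, seed, 12_000)
        highs = log.filter("ttl_high")
        assert len(highs) == 1 and highs[0].time == 7200
        assert highs[0].payload == "2"
        assert log.filter("ttl_low")[0].time == 9200

    def test_no_schedule_no_ttl_events(self):
        log, _ = run_stochastic_5csrtt(seed=0, duration_ms=5 * 60_000)
        assert not log.filter("ttl_high") and not log.filter("ttl_low")

    def test_bad_channel_rejected(self):
        with pytest.raises(ValueError, match="ttl_channel"):
            fc.OptoSchedule("iti_onset", 4000, ttl_channel=9)


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_response_class_partition(self, seed):
        _, trials = run_stochastic_5csrtt(seed=seed)
        s = fc.compute_5csrtt_metrics(trials)
        assert s.correct + s.incorrect + s.premature + s.omission == s.trials

    def test_reward_conservation_5csrtt(self):
        log, trials = run_stochastic_5csrtt(seed=5)
        s = fc.summarize_session(log, trials)
        assert s.total_reward_ul == 20.0 * s.correct

    def test_reward_conservation_5cswm(self):
        log, trials = run_stochastic_5cswm(seed=5)
        s = fc.summarize_session(log, trials)
        assert s.total_reward_ul == 10.0 * s.sp_correct + 60.0 * s.cp_match

    def test_nonpositive_duration_params_rejected(self):
        with pytest.raises(ValueError):
            fc.FiveCSRTTParams(sd_ms=0)
        with pytest.raises(ValueError):
            fc.FiveCSWMParams(delay_ms=-1)
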