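"""Shared fixtures: parameter sets, scripted-session helpers.

Scripted traces need to know which hole the task will cue (the cue sequence
is drawn from the task's seeded generator), so ``probe_cues`` runs a silent
probe session first and returns the cue sequence for a seed; scripts are then
authored against it and the session re-run with the same seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from fivechoice import (AgentParams, FiveCSRTTParams, FiveCSWMParams,
                        ScriptedAction, ScriptedAgent, StochasticAgent,
                        build_5csrtt, build_5cswm, run_session, segment_trials)


@pytest.fixture
def baseline():
    return FiveCSRTTParams()


@pytest.fixture
def wm_params():
    return FiveCSWMParams()


def probe_cue_sequence(seed: int, n: int = 10) -> list[int]:
    """Cue holes the baseline attention task will draw for this seed.

    The task stream is the first child of the session seed; cue holes are
    consecutive ``integers(1, 6)`` draws, one per stimulus presentation.
    """
    task_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    return [int(task_rng.integers(1, 6)) for _ in range(n)]


def probe_cswm_draws(seed: int, n: int = 10) -> list[tuple[int, int]]:
    """(sample hole, distractor hole) pairs the working-memory task draws."""
    task_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    out = []
    for _ in range(n):
        target = int(task_rng.integers(1, 6))
        others = [h for h in range(1, 6) if h != target]
        out.append((target, others[int(task_rng.integers(0, len(others)))]))
    return out


def run_scripted_5csrtt(actions, seed=0, params=None, duration_ms=60_000):
    log = run_session(build_5csrtt(params or FiveCSRTTParams()),
                      ScriptedAgent([ScriptedAction(*a) for a in actions]),
                      seed, duration_ms)
    return log, segment_trials(log)


def run_stochastic_5csrtt(seed=0, params=None, agent_params=None,
                          duration_ms=30 * 60 * 1000, max_trials=None):
    log = run_session(build_5csrtt(params or FiveCSRTTParams()),
                      StochasticAgent(agent_params or AgentParams()),
                      seed, duration_ms, max_trials=max_trials)
    return log, segment_trials(log)


def run_stochastic_5cswm(seed=0, params=None, agent_params=None,
                         duration_ms=30 * 60 * 1000):
    log = run_session(build_5cswm(params or FiveCSWMParams()),
                      StochasticAgent(agent_params or AgentParams()),
                      seed, duration_ms)
    return log, segment_trials(log)
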