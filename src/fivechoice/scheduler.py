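"""Criterion-based training-stage progression.

Subjects advance from habituation through attention-task stages of increasing
difficulty when their trailing sessions meet all of a stage's thresholds on
the three key variables — accuracy, %omissions and the absolute number of
correct responses — for a required number of consecutive sessions.

The habituation rule is fixed by the protocol: at least 30 rewards in each of
two consecutive sessions.  The stage 1–5 parameter and criterion values are
lab-configurable; the defaults shipped here are editable placeholders with a
conventional difficulty ramp (long stimulus, short ITI early; 2 s SD / 5 s
ITI at baseline), not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .agents import StochasticAgent
from .analytics import summarize_session
from .engine import run_session
from .events import SessionSummary
from .tasks import FiveCSRTTParams, HabituationParams, build_5csrtt, build_habituation

__all__ = [
    "StageCriteria",
    "TrainingStage",
    "TrainingPlan",
    "MissingMetricError",
    "evaluate_transition",
    "run_training_simulation",
    "default_5csrtt_plan",
]


class MissingMetricError(ValueError):
    """A criterion needs a metric the session summary does not carry."""


@dataclass(frozen=True)
class StageCriteria:
    """Thresholds a session must meet; ``None`` thresholds are not checked.
    ``consecutive`` is the number of trailing sessions that must all pass."""

    min_accuracy: Optional[float] = None
    max_pct_omissions: Optional[float] = None
    min_correct: Optional[int] = None
    min_rewards: Optional[int] = None
    consecutive: int = 2

    def __post_init__(self):
        if self.consecutive < 1:
            raise ValueError("consecutive must be >= 1")

    def session_passes(self, s: SessionSummary) -> bool:
        checks = [
            ("accuracy", self.min_accuracy, s.accuracy, False),
            ("pct_omissions", self.max_pct_omissions, s.pct_omissions, True),
            ("correct", self.min_correct, s.correct, False),
            ("rewards", self.min_rewards, s.rewards, False),
        ]
        for name, threshold, value, is_max in checks:
            if threshold is None:
                continue
            if value is None:
                raise MissingMetricError(
                    f"criterion needs metric {name!r} but the session summary "
                    f"does not define it")
            if is_max and value > threshold:
                return False
            if not is_max and value < threshold:
                return False
        return True


@dataclass(frozen=True)
class TrainingStage:
    name: str
    params: object            # HabituationParams or FiveCSRTTParams
    criteria: StageCriteria


@dataclass
class TrainingPlan:
    stages: Sequence[TrainingStage]

    def index(self, stage_name: str) -> int:
        for i, st in enumerate(self.stages):
            if st.name == stage_name:
                return i
        raise KeyError(stage_name)


def default_5csrtt_plan(session_ms: int = 30 * 60 * 1000) -> TrainingPlan:
    """Habituation + five attention-task stages.

    Only the habituation criterion (>= 30 rewards, 2 consecutive sessions) is
    a protocol constant; stage parameters and criteria are placeholders meant
    to be edited per lab.
    """
    hab = TrainingStage(
        "habituation",
        HabituationParams(session_ms=session_ms),
        StageCriteria(min_rewards=30, consecutive=2),
    )
    ramp = [  # (sd_ms, iti_ms) placeholder difficulty ramp
        ("stage1", 8000, 2000),
        ("stage2", 4000, 2000),
        ("stage3", 2000, 2000),
        ("stage4", 2000, 5000),
        ("stage5", 2000, 5000),
    ]
    crit = StageCriteria(min_accuracy=80.0, max_pct_omissions=50.0,
                         min_correct=30, consecutive=2)
    stages = [hab] + [
        TrainingStage(name, FiveCSRTTParams(sd_ms=sd, iti_ms=iti,
                                            session_ms=session_ms), crit)
        for name, sd, iti in ramp
    ]
    return TrainingPlan(stages)


def evaluate_transition(history: Sequence[SessionSummary],
                        criteria: StageCriteria) -> bool:
    """True iff the last ``criteria.consecutive`` sessions each meet every
    threshold.  ``history`` holds the summaries of the current stage only,
    oldest first; the decision depends on nothing before the trailing block."""
    if not history:
        raise ValueError("history must contain at least one session")
    k = criteria.consecutive
    if len(history) < k:
        return False
    return all(criteria.session_passes(s) for s in list(history)[-k:])


@dataclass
class TrainingTrajectory:
    """Sessions-per-stage outcome of a simulated training run."""

    sessions_per_stage: dict = field(default_factory=dict)
    histories: dict = field(default_factory=dict)
    completed: bool = False
    final_stage: str = ""


def _build(stage: TrainingStage):
    if isinstance(stage.params, HabituationParams):
        return build_habituation(stage.params)
    return build_5csrtt(stage.params)


def run_training_simulation(agent_params, plan: Optional[TrainingPlan] = None,
                            max_sessions: int = 60, seed: int = 0,
                            session_ms: Optional[int] = None) -> TrainingTrajectory:
    """Simulate daily sessions, applying the transition rule after each.

    The same stochastic subject (no learning) runs every session; each
    session gets its own child seed from ``seed`` so the whole trajectory is
    reproducible.  ``completed`` is False when ``max_sessions`` ran out
    before the final stage's criterion was reached.
    """
    plan = plan or default_5csrtt_plan()
    traj = TrainingTrajectory()
    child_seeds = np.random.SeedSequence(seed).generate_state(max_sessions) % (2**31)
    stage_idx = 0
    for session_i in range(max_sessions):
        stage = plan.stages[stage_idx]
        params = stage.params
        if session_ms is not None:
            params = replace(params, session_ms=session_ms)
        machine = _build(TrainingStage(stage.name, params, stage.criteria))
        agent = StochasticAgent(agent_params)
        log = run_session(machine, agent, int(child_seeds[session_i]),
                          params.session_ms, meta={"stage": stage.name})
        summary = summarize_session(log)
        summary.stage = stage.name
        traj.histories.setdefault(stage.name, []).append(summary)
        traj.sessions_per_stage[stage.name] = \
            traj.sessions_per_stage.get(stage.name, 0) + 1
        if evaluate_transition(traj.histories[stage.name], stage.criteria):
            stage_idx += 1
            if stage_idx >= len(plan.stages):
                traj.completed = True
                traj.final_stage = stage.name
                return traj
    traj.final_stage = plan.stages[stage_idx].name
    return traj
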