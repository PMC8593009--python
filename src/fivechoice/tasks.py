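"""Operant paradigms as state-machine builders.

Three paradigms are provided:

* **habituation** — all five stimulus holes lit for the whole session; any
  hole poke earns a 40 µl reward at the illuminated receptacle.
* **5-CSRTT** (5-choice serial reaction time task) — the classic sustained-
  attention cycle: inter-trial interval (ITI, started by receptacle exit
  after reward collection or by the end of a time-out), a single hole lit for
  the stimulus duration (SD), a limited-hold (LH) window after light-off.
  A poke into the cued hole during SD or LH is *correct* and earns 20 µl;
  a poke during the ITI is *premature*, into an uncued hole *incorrect*, and
  no poke an *omission* — each triggers a time-out with the house light
  switched off (it is on otherwise).
* **5-CSWM** (5-choice spatial working memory, delayed matching to position)
  — a sample phase (SP: one hole lit, small 10 µl reward on a correct poke),
  a delay that starts when the SP reward collection ends, then a choice phase
  (CP: the sample hole plus one distractor lit) where re-poking the sample
  hole earns the large 60 µl reward.  SP/CP errors or omissions abort the
  trial into a time-out; house-light polarity is inverted relative to the
  5-CSRTT (off during the task, on during time-outs).

Timing windows are half-open ``[start, end)``: a poke at exactly SD end is
still a stimulus-period response, a poke at exactly LH end is not scored and
the trial is an omission.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

from .engine import (EngineFault, N_HOLES, N_TTL, PumpCalibration,
                     StateMachine, params_meta)  # noqa: F401  (re-export)
from .trials import classify_5csrtt_trial, classify_5cswm_trial  # noqa: F401  (re-export)

__all__ = [
    "FiveCSRTTParams",
    "FiveCSWMParams",
    "HabituationParams",
    "OptoSchedule",
    "build_5csrtt",
    "build_habituation",
    "build_5cswm",
    "make_challenge",
    "attach_opto_schedule",
    "params_meta",
    "classify_5csrtt_trial",
    "classify_5cswm_trial",
]

HOLES = tuple(range(1, N_HOLES + 1))


def _positive(name: str, value) -> None:
    if value is None or value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class FiveCSRTTParams:
    """Baseline 5-CSRTT stage-5 parameters: 2 s SD, 5 s ITI, 2 s LH,
    5 s time-out, 20 µl reward, 30-min sessions.

    ``iti_ms`` may be a sequence, in which case each trial's ITI is drawn
    uniformly from it with the task's seeded generator (variable-ITI
    challenge).
    """

    sd_ms: int = 2000
    iti_ms: Union[int, Sequence[int]] = 5000
    lh_ms: int = 2000
    timeout_ms: int = 5000
    reward_ul: float = 20.0
    houselight_during_task: bool = True
    houselight_during_timeout: bool = False
    session_ms: int = 30 * 60 * 1000
    pump: PumpCalibration = field(default_factory=PumpCalibration)

    def __post_init__(self):
        _positive("sd_ms", self.sd_ms)
        _positive("lh_ms", self.lh_ms)
        _positive("timeout_ms", self.timeout_ms)
        _positive("reward_ul", self.reward_ul)
        _positive("session_ms", self.session_ms)
        itis = self.iti_ms if isinstance(self.iti_ms, (list, tuple)) else [self.iti_ms]
        if not itis:
            raise ValueError("iti_ms set must be non-empty")
        for v in itis:
            _positive("iti_ms", v)


@dataclass(frozen=True)
class FiveCSWMParams:
    """Baseline (stage-5) working-memory parameters: 10 s maximum SP stimulus,
    5 s maximum CP stimulus, 2 s delay after SP-reward collection, 10/60 µl
    SP/CP rewards, 5 s time-out."""

    sp_sd_ms: int = 10000
    cp_sd_ms: int = 5000
    delay_ms: int = 2000
    sp_reward_ul: float = 10.0
    cp_reward_ul: float = 60.0
    timeout_ms: int = 5000
    iti_ms: int = 5000
    houselight_during_task: bool = False
    houselight_during_timeout: bool = True
    session_ms: int = 30 * 60 * 1000
    pump: PumpCalibration = field(default_factory=PumpCalibration)

    def __post_init__(self):
        for name in ("sp_sd_ms", "cp_sd_ms", "delay_ms", "timeout_ms", "iti_ms",
                     "sp_reward_ul", "cp_reward_ul", "session_ms"):
            _positive(name, getattr(self, name))


@dataclass(frozen=True)
class HabituationParams:
    """Simplified operant cycle: every 5-choice poke is rewarded (40 µl)."""

    reward_ul: float = 40.0
    session_ms: int = 30 * 60 * 1000
    pump: PumpCalibration = field(default_factory=PumpCalibration)

    def __post_init__(self):
        _positive("reward_ul", self.reward_ul)
        _positive("session_ms", self.session_ms)


@dataclass(frozen=True)
class OptoSchedule:
    """A TTL pulse anchored to a task event, e.g. the first 4 s of each ITI
    (``anchor='iti_onset'``) or the first 2 s of reward collection
    (``anchor='reward_collection'``)."""

    anchor: str  # 'iti_onset' | 'reward_collection'
    pulse_duration_ms: int
    onset_offset_ms: int = 0
    ttl_channel: int = 1

    def __post_init__(self):
        if self.anchor not in ("iti_onset", "reward_collection"):
            raise ValueError(f"unknown opto anchor {self.anchor!r}")
        _positive("pulse_duration_ms", self.pulse_duration_ms)
        if self.onset_offset_ms < 0:
            raise ValueError("onset_offset_ms must be >= 0")
        if not 1 <= self.ttl_channel <= N_TTL:
            raise ValueError(f"ttl_channel {self.ttl_channel} out of range 1..{N_TTL}")

    @property
    def anchor_event(self) -> Optional[str]:
        # reward_collection is fired explicitly by the reward-wait handlers
        return "iti_start" if self.anchor == "iti_onset" else None


def _fire_collection_anchors(ctx) -> None:
    for sched in ctx.machine.opto_schedules:
        if sched.anchor == "reward_collection":
            ctx._schedule_opto(sched)


# ---------------------------------------------------------------------------
# 5-CSRTT


def build_5csrtt(params: Optional[FiveCSRTTParams] = None) -> StateMachine:
    """Build the 5-CSRTT operant cycle as a state machine."""
    p = params or FiveCSRTTParams()
    m = StateMachine("5csrtt", p, "iti")

    def session_start(ctx, _):
        ctx.houselight(p.houselight_during_task)
        ctx.goto("iti")

    def iti_enter(ctx, _):
        ctx.emit("iti_start")
        iti = p.iti_ms
        if isinstance(iti, (list, tuple)):
            iti = int(iti[int(ctx.rng.integers(0, len(iti)))])
        ctx.set_timer("iti_end", iti)

    def iti_poke(ctx, act):
        ctx.end_trial("premature")
        ctx.goto("timeout")

    def stim_enter(ctx, _):
        target = int(ctx.rng.integers(1, N_HOLES + 1))
        ctx.vars["target"] = target
        ctx.hole_light(target, True)
        ctx.set_timer("sd_end", p.sd_ms)

    def correct(ctx):
        ctx.hole_light(ctx.vars["target"], False)
        ctx.end_trial("correct")
        ctx.receptacle_light(True)
        ctx.reward(p.reward_ul)
        ctx.goto("reward_wait")

    def incorrect(ctx):
        ctx.hole_light(ctx.vars["target"], False)
        ctx.end_trial("incorrect")
        ctx.goto("timeout")

    def stim_poke(ctx, act):
        correct(ctx) if act.hole == ctx.vars["target"] else incorrect(ctx)

    def sd_end(ctx, _):
        ctx.hole_light(ctx.vars["target"], False)
        ctx.goto("limited_hold")

    def lh_enter(ctx, _):
        ctx.vars["lh_deadline"] = ctx.now + p.lh_ms
        ctx.set_timer("lh_end", p.lh_ms)

    def lh_poke(ctx, act):
        if ctx.now >= ctx.vars["lh_deadline"]:
            return  # half-open window: boundary poke is not scored
        correct(ctx) if act.hole == ctx.vars["target"] else incorrect(ctx)

    def lh_end(ctx, _):
        ctx.end_trial("omission")
        ctx.goto("timeout")

    def rw_entry(ctx, _):
        ctx.receptacle_light(False)
        _fire_collection_anchors(ctx)
        ctx.goto("collecting")

    def collect_exit(ctx, _):
        ctx.goto("iti")  # receptacle exit initiates the next ITI

    def to_enter(ctx, _):
        ctx.emit("timeout_start")
        ctx.houselight(p.houselight_during_timeout)
        ctx.set_timer("to_end", p.timeout_ms)

    def to_end(ctx, _):
        ctx.emit("timeout_end")
        ctx.houselight(p.houselight_during_task)
        ctx.goto("iti")

    m.on_session_start = session_start
    m.state("iti", iti_enter)
    m.on("iti", "poke", iti_poke)
    m.on("iti", "iti_end", lambda ctx, _: ctx.goto("stimulus"))
    m.ignores("iti", "receptacle_entry", "receptacle_exit")
    m.state("stimulus", stim_enter)
    m.on("stimulus", "poke", stim_poke)
    m.on("stimulus", "sd_end", sd_end)
    m.ignores("stimulus", "receptacle_entry", "receptacle_exit")
    m.state("limited_hold", lh_enter)
    m.on("limited_hold", "poke", lh_poke)
    m.on("limited_hold", "lh_end", lh_end)
    m.ignores("limited_hold", "receptacle_entry", "receptacle_exit")
    m.state("reward_wait")
    m.on("reward_wait", "receptacle_entry", rw_entry)
    m.ignores("reward_wait", "poke", "receptacle_exit")
    m.state("collecting")
    m.on("collecting", "receptacle_exit", collect_exit)
    m.ignores("collecting", "poke", "receptacle_entry")
    m.state("timeout", to_enter)
    m.on("timeout", "to_end", to_end)
    m.ignores("timeout", "poke", "receptacle_entry", "receptacle_exit")
    return m


# ---------------------------------------------------------------------------
# Habituation


def build_habituation(params: Optional[HabituationParams] = None) -> StateMachine:
    """All five holes lit for the whole session; any 5-choice poke earns the
    reward at the illuminated receptacle (even before a prior reward is
    collected — pokes are never penalised during habituation)."""
    p = params or HabituationParams()
    m = StateMachine("habituation", p, "active")

    def session_start(ctx, _):
        ctx.houselight(True)
        for h in HOLES:
            ctx.hole_light(h, True)
        ctx.goto("active")

    def poke(ctx, act):
        ctx.receptacle_light(True)
        ctx.reward(p.reward_ul)

    m.on_session_start = session_start
    m.state("active")
    m.on("active", "poke", poke)
    m.on("active", "receptacle_entry", lambda ctx, _: ctx.receptacle_light(False))
    m.ignores("active", "receptacle_exit")
    return m


# ---------------------------------------------------------------------------
# 5-CSWM (delayed matching to position)


def build_5cswm(params: Optional[FiveCSWMParams] = None) -> StateMachine:
    """Build the working-memory (DMTP) trial cycle.

    ITI pokes are logged but not scored (the task defines errors only within
    the SP and CP).  Any non-matching CP poke — distractor or unlit hole — is
    a non-match error.  The distractor is drawn uniformly from the four
    non-sample holes with the task's seeded generator.
    """
    p = params or FiveCSWMParams()
    m = StateMachine("5cswm", p, "iti")

    def session_start(ctx, _):
        ctx.houselight(p.houselight_during_task)
        ctx.goto("iti")

    def iti_enter(ctx, _):
        ctx.emit("iti_start")
        ctx.set_timer("iti_end", p.iti_ms)

    def sp_enter(ctx, _):
        ctx.emit("sp_start")
        target = int(ctx.rng.integers(1, N_HOLES + 1))
        ctx.vars["target"] = target
        ctx.hole_light(target, True)
        ctx.set_timer("sp_sd_end", p.sp_sd_ms)

    def sp_poke(ctx, act):
        target = ctx.vars["target"]
        ctx.hole_light(target, False)
        if act.hole == target:
            ctx.receptacle_light(True)
            ctx.reward(p.sp_reward_ul)
            ctx.goto("sp_reward_wait")
        else:
            ctx.end_trial("sp_incorrect")
            ctx.goto("timeout")

    def sp_sd_end(ctx, _):
        ctx.hole_light(ctx.vars["target"], False)
        ctx.end_trial("sp_omission")
        ctx.goto("timeout")

    def sp_rw_entry(ctx, _):
        ctx.receptacle_light(False)
        _fire_collection_anchors(ctx)
        ctx.goto("sp_collecting")

    def delay_enter(ctx, _):
        ctx.emit("delay_start")
        ctx.set_timer("delay_end", p.delay_ms)

    def cp_enter(ctx, _):
        ctx.emit("cp_start")
        target = ctx.vars["target"]
        others = [h for h in HOLES if h != target]
        distractor = others[int(ctx.rng.integers(0, len(others)))]
        if distractor == target:  # unreachable by construction
            raise EngineFault("CP distractor equals sample hole")
        ctx.vars["distractor"] = distractor
        for h in sorted((target, distractor)):
            ctx.hole_light(h, True)
        ctx.set_timer("cp_sd_end", p.cp_sd_ms)

    def cp_lights_off(ctx):
        ctx.hole_light(ctx.vars["target"], False)
        ctx.hole_light(ctx.vars["distractor"], False)

    def cp_poke(ctx, act):
        cp_lights_off(ctx)
        if act.hole == ctx.vars["target"]:
            ctx.end_trial("cp_match")
            ctx.receptacle_light(True)
            ctx.reward(p.cp_reward_ul)
            ctx.goto("cp_reward_wait")
        else:
            ctx.end_trial("cp_nonmatch")
            ctx.goto("timeout")

    def cp_sd_end(ctx, _):
        cp_lights_off(ctx)
        ctx.end_trial("cp_omission")
        ctx.goto("timeout")

    def cp_rw_entry(ctx, _):
        ctx.receptacle_light(False)
        _fire_collection_anchors(ctx)
        ctx.goto("cp_collecting")

    def to_enter(ctx, _):
        ctx.emit("timeout_start")
        ctx.houselight(p.houselight_during_timeout)
        ctx.set_timer("to_end", p.timeout_ms)

    def to_end(ctx, _):
        ctx.emit("timeout_end")
        ctx.houselight(p.houselight_during_task)
        ctx.goto("iti")

    m.on_session_start = session_start
    m.state("iti", iti_enter)
    m.on("iti", "iti_end", lambda ctx, _: ctx.goto("sp_stim"))
    m.ignores("iti", "poke", "receptacle_entry", "receptacle_exit")
    m.state("sp_stim", sp_enter)
    m.on("sp_stim", "poke", sp_poke)
    m.on("sp_stim", "sp_sd_end", sp_sd_end)
    m.ignores("sp_stim", "receptacle_entry", "receptacle_exit")
    m.state("sp_reward_wait")
    m.on("sp_reward_wait", "receptacle_entry", sp_rw_entry)
    m.ignores("sp_reward_wait", "poke", "receptacle_exit")
    m.state("sp_collecting")
    m.on("sp_collecting", "receptacle_exit", lambda ctx, _: ctx.goto("delay"))
    m.ignores("sp_collecting", "poke", "receptacle_entry")
    m.state("delay", delay_enter)
    m.on("delay", "delay_end", lambda ctx, _: ctx.goto("cp_stim"))
    m.ignores("delay", "poke", "receptacle_entry", "receptacle_exit")
    m.state("cp_stim", cp_enter)
    m.on("cp_stim", "poke", cp_poke)
    m.on("cp_stim", "cp_sd_end", cp_sd_end)
    m.ignores("cp_stim", "receptacle_entry", "receptacle_exit")
    m.state("cp_reward_wait")
    m.on("cp_reward_wait", "receptacle_entry", cp_rw_entry)
    m.ignores("cp_reward_wait", "poke", "receptacle_exit")
    m.state("cp_collecting")
    m.on("cp_collecting", "receptacle_exit", lambda ctx, _: ctx.goto("iti"))
    m.ignores("cp_collecting", "poke", "receptacle_entry")
    m.state("timeout", to_enter)
    m.on("timeout", "to_end", to_end)
    m.ignores("timeout", "poke", "receptacle_entry", "receptacle_exit")
    return m


# ---------------------------------------------------------------------------
# Challenges and opto


DEFAULT_VARIABLE_ITI_SET = (5000, 7500, 12500)  # configurable placeholder


def make_challenge(base: FiveCSRTTParams, kind: str,
                   magnitude=None) -> FiveCSRTTParams:
    """Derive a challenge parameter set from a baseline.

    * ``attention`` — shorten the SD (default 800 ms from the 2 s baseline);
    * ``fixed_iti`` — lengthen every ITI to ``magnitude`` ms;
    * ``variable_iti`` — draw each trial's ITI uniformly from a set
      (default ``DEFAULT_VARIABLE_ITI_SET``).
    """
    if kind == "attention":
        return replace(base, sd_ms=int(magnitude) if magnitude else 800)
    if kind == "fixed_iti":
        if magnitude is None:
            raise ValueError("fixed_iti challenge needs a magnitude (ms)")
        return replace(base, iti_ms=int(magnitude))
    if kind == "variable_iti":
        itis = tuple(int(v) for v in (magnitude or DEFAULT_VARIABLE_ITI_SET))
        return replace(base, iti_ms=itis)
    raise ValueError(f"unknown challenge kind {kind!r}")


def attach_opto_schedule(machine: StateMachine, schedule: OptoSchedule) -> StateMachine:
    """Attach a TTL pulse schedule to a built task machine (in place).

    Each occurrence of the anchor event emits TTL-high at
    ``anchor + onset_offset`` and TTL-low ``pulse_duration`` later.
    """
    if schedule.anchor == "reward_collection":
        has_anchor = any(k[1] == "receptacle_entry" and k[0].endswith("reward_wait")
                         for k in machine.handlers)
        if not has_anchor and machine.name != "5csrtt":
            raise ValueError(
                f"task {machine.name!r} has no reward-collection anchor")
    machine.opto_schedules.append(schedule)
    return machine
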