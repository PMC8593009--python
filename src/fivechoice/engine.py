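"""Discrete-event runtime for simulated operant-box sessions.

The engine executes a :class:`StateMachine` (built by :mod:`fivechoice.tasks`)
against a subject policy (:mod:`fivechoice.agents`) on a millisecond virtual
clock, logging every event — nose-pokes, receptacle crossings, light and TTL
transitions, rewards — into an :class:`~fivechoice.events.EventLog`.

Determinism is by construction: the clock is integer ms with no wall-clock
dependence; at equal timestamps subject-input events are processed before
timer expiries, and simultaneous timers fire in alphabetical order of timer
name; all randomness flows through two seeded generators (task and agent
streams spawned from one seed).  The same (task, agent, seed, duration)
therefore reproduces a byte-identical log.

Virtual devices: five stimulus (hole) lights, the receptacle light, the house
light, a stepper-motor reward pump and four TTL output lines.  Lights and TTL
lines are modelled as logged level changes; the pump converts commanded
microliter volumes to motor steps through a :class:`PumpCalibration`.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .events import EventLog

__all__ = [
    "EngineFault",
    "PumpCalibration",
    "DeviceState",
    "StateMachine",
    "Engine",
    "run_session",
    "volume_to_steps",
]

N_HOLES = 5
N_TTL = 4


class EngineFault(RuntimeError):
    """Task-definition or runtime contract violation inside the engine."""


_PARAM_META_KEYS = ("sd_ms", "iti_ms", "lh_ms", "timeout_ms", "reward_ul",
                    "sp_sd_ms", "cp_sd_ms", "delay_ms", "sp_reward_ul",
                    "cp_reward_ul")


def params_meta(params) -> dict:
    """Task-parameter fields embedded in a log's metadata header (so that
    offline classification can reconstruct the response windows)."""
    out = {}
    for key in _PARAM_META_KEYS:
        if hasattr(params, key):
            v = getattr(params, key)
            out[key] = "|".join(str(x) for x in v) if isinstance(v, (list, tuple)) else v
    return out


@dataclass(frozen=True)
class PumpCalibration:
    """Mapping from liquid volume to stepper-motor steps.

    The default 0.5 µl/step is a configurable placeholder; real pumps are
    bench-calibrated per unit.
    """

    microliters_per_step: float = 0.5

    def __post_init__(self):
        if self.microliters_per_step <= 0:
            raise ValueError("microliters_per_step must be positive")

    def steps(self, volume_ul: float) -> int:
        return volume_to_steps(volume_ul, self)


def volume_to_steps(volume_ul: float, cal: PumpCalibration) -> int:
    """Nearest-step coding of a commanded volume (half rounds up).

    The dispensed volume ``steps * microliters_per_step`` differs from the
    commanded one by at most half a step's volume.
    """
    if volume_ul < 0:
        raise ValueError(f"negative volume {volume_ul}")
    return int(math.floor(volume_ul / cal.microliters_per_step + 0.5))


@dataclass
class DeviceState:
    """Levels of all virtual box outputs."""

    hole_lights: set = field(default_factory=set)      # lit hole indices 1..5
    receptacle_light: bool = False
    house_light: bool = False
    ttl_lines: set = field(default_factory=set)        # high channel indices 1..4


Handler = Callable[["Engine", object], None]


class StateMachine:
    """Declarative finite-state task definition.

    ``handlers`` maps ``(state, event_key)`` to a callable; ``event_key`` is a
    subject input name (``poke``, ``receptacle_entry``, ``receptacle_exit``)
    or a timer name.  Every reachable pair must have a handler or be listed in
    ``ignore`` — anything else is an engine fault naming the pair.  Timers are
    cancelled on state exit unless declared persistent.
    """

    def __init__(self, name: str, params, initial_state: str):
        self.name = name
        self.params = params
        self.initial_state = initial_state
        self.handlers: dict[tuple[str, str], Handler] = {}
        self.on_enter: dict[str, Handler] = {}
        self.ignore: set[tuple[str, str]] = set()
        self.on_session_start: Optional[Handler] = None
        self.opto_schedules: list = []   # attached by tasks.attach_opto_schedule

    def state(self, name: str, on_enter: Optional[Handler] = None) -> None:
        if on_enter is not None:
            self.on_enter[name] = on_enter

    def on(self, state: str, event_key: str, handler: Handler) -> None:
        self.handlers[(state, event_key)] = handler

    def ignores(self, state: str, *event_keys: str) -> None:
        for k in event_keys:
            self.ignore.add((state, k))


_INPUT_NAMES = {"poke", "receptacle_entry", "receptacle_exit"}


class Engine:
    """Executes one session; also serves as the handler context (``ctx``)."""

    def __init__(self, machine: StateMachine, agent, seed: int,
                 duration_ms: int, max_trials: Optional[int] = None,
                 pump: Optional[PumpCalibration] = None, meta: Optional[dict] = None):
        if duration_ms <= 0:
            raise ValueError("duration must be positive")
        self.machine = machine
        self.agent = agent
        self.duration = int(duration_ms)
        self.max_trials = max_trials
        self.pump = pump or getattr(machine.params, "pump", None) or PumpCalibration()
        self.now = 0
        self.state: Optional[str] = None
        self.devices = DeviceState()
        self.log = EventLog(meta=dict(meta or {}))
        self.log.meta.setdefault("paradigm", machine.name)
        self.log.meta.setdefault("seed", seed)
        self.log.meta.setdefault("duration_ms", self.duration)
        for k, v in params_meta(machine.params).items():
            self.log.meta.setdefault(k, v)
        ss = np.random.SeedSequence(seed)
        task_ss, agent_ss = ss.spawn(2)
        self.rng = np.random.default_rng(task_ss)
        self._agent_rng = np.random.default_rng(agent_ss)
        # timers: name -> (abs_time, persistent, generation)
        self._timers: dict[str, tuple[int, bool, int]] = {}
        self._timer_heap: list[tuple[int, str, int]] = []
        self._gen = 0
        self._pending: list = []          # agent actions, kept time-sorted
        self._notify_from = 0             # index into log for agent notification
        self.trial_count = 0
        self.vars: dict = {}              # machine scratch (target hole, deadlines)
        self._finished = False

    # ---- ctx API used by task handlers -----------------------------------

    def emit(self, name: str, payload=None) -> None:
        self.log.append(self.now, name, payload)
        for sched in self.machine.opto_schedules:
            if sched.anchor_event == name:
                self._schedule_opto(sched)

    def goto(self, state: str) -> None:
        # state exit cancels non-persistent timers
        for tname, (t, persistent, gen) in list(self._timers.items()):
            if not persistent:
                del self._timers[tname]
        self.state = state
        enter = self.machine.on_enter.get(state)
        if enter is not None:
            enter(self, None)

    def set_timer(self, name: str, delay_ms: int, persistent: bool = False) -> None:
        if delay_ms < 0:
            raise EngineFault(f"negative timer delay for {name!r}: {delay_ms}")
        self._gen += 1
        t = self.now + int(delay_ms)
        self._timers[name] = (t, persistent, self._gen)
        heapq.heappush(self._timer_heap, (t, name, self._gen))

    def cancel_timer(self, name: str) -> None:
        self._timers.pop(name, None)

    def end_trial(self, response_class: str) -> None:
        self.emit("trial_end", response_class)
        self.trial_count += 1

    # device commands: log only genuine level changes

    def hole_light(self, hole: int, on: bool) -> None:
        if on and hole not in self.devices.hole_lights:
            self.devices.hole_lights.add(hole)
            self.emit("hole_light_on", hole)
        elif not on and hole in self.devices.hole_lights:
            self.devices.hole_lights.remove(hole)
            self.emit("hole_light_off", hole)

    def houselight(self, on: bool) -> None:
        if on != self.devices.house_light:
            self.devices.house_light = on
            self.emit("houselight_on" if on else "houselight_off")

    def receptacle_light(self, on: bool) -> None:
        if on != self.devices.receptacle_light:
            self.devices.receptacle_light = on
            self.emit("receptacle_light_on" if on else "receptacle_light_off")

    def ttl(self, channel: int, high: bool) -> None:
        if not 1 <= channel <= N_TTL:
            raise EngineFault(f"TTL channel {channel} out of range 1..{N_TTL}")
        if high and channel not in self.devices.ttl_lines:
            self.devices.ttl_lines.add(channel)
            self.emit("ttl_high", channel)
        elif not high and channel in self.devices.ttl_lines:
            self.devices.ttl_lines.remove(channel)
            self.emit("ttl_low", channel)

    def reward(self, volume_ul: float) -> None:
        steps = volume_to_steps(volume_ul, self.pump)
        self.emit("reward", f"vol_ul={volume_ul};steps={steps}")

    # ---- opto -------------------------------------------------------------

    def _schedule_opto(self, sched) -> None:
        k = len([t for t in self._timers if t.startswith("zopto_")])
        on_name = f"zopto_on_{sched.ttl_channel}_{self._gen}_{k}"
        off_name = f"zopto_off_{sched.ttl_channel}_{self._gen}_{k}"
        self.set_timer(on_name, sched.onset_offset_ms, persistent=True)
        self.set_timer(off_name, sched.onset_offset_ms + sched.pulse_duration_ms,
                       persistent=True)

    def _opto_timer(self, name: str) -> bool:
        if name.startswith("zopto_on_"):
            self.ttl(int(name.split("_")[2]), True)
            return True
        if name.startswith("zopto_off_"):
            self.ttl(int(name.split("_")[2]), False)
            return True
        return False

    # ---- main loop --------------------------------------------------------

    def _dispatch(self, event_key: str, event) -> None:
        key = (self.state, event_key)
        handler = self.machine.handlers.get(key)
        if handler is not None:
            handler(self, event)
        elif key in self.machine.ignore or (self.state, "*") in self.machine.ignore:
            pass
        else:
            raise EngineFault(
                f"unhandled (state={self.state!r}, event={event_key!r}) pair "
                f"in task {self.machine.name!r}"
            )

    def _notify_agent(self) -> None:
        new = self.log.events[self._notify_from:]
        self._notify_from = len(self.log.events)
        for rec in new:
            actions = self.agent.observe(rec, self)
            if actions is not None:
                for a in actions:
                    if a.time < self.now:
                        raise EngineFault(
                            f"agent scheduled action in the past ({a.time} < {self.now})"
                        )
                self._pending = sorted(actions, key=lambda a: a.time)

    def _next_timer(self):
        while self._timer_heap:
            t, name, gen = self._timer_heap[0]
            live = self._timers.get(name)
            if live is None or live[2] != gen:
                heapq.heappop(self._timer_heap)
                continue
            return t, name
        return None

    def run(self) -> EventLog:
        if self._finished:
            raise RuntimeError("engine already ran")
        self.emit("session_start", self.machine.name)
        if self.machine.on_session_start is not None:
            self.machine.on_session_start(self, None)
        else:
            self.goto(self.machine.initial_state)
        self.agent.reset(self._agent_rng, self)
        self._notify_agent()
        guard = 0
        while True:
            guard += 1
            if guard > 50_000_000:
                raise EngineFault("event budget exceeded; runaway task?")
            nt = self._next_timer()
            na = self._pending[0] if self._pending else None
            if nt is None and na is None:
                break
            # inputs win ties with timers
            take_action = na is not None and (nt is None or na.time <= nt[0])
            t = na.time if take_action else nt[0]
            if t > self.duration:
                break
            if self.max_trials is not None and self.trial_count >= self.max_trials:
                break
            if t < self.now:
                raise EngineFault(f"event from the past: {t} < {self.now}")
            self.now = int(t)
            if take_action:
                act = self._pending.pop(0)
                if act.action == "poke":
                    self.emit("poke", act.hole)
                    self._dispatch("poke", act)
                elif act.action in ("receptacle_entry", "receptacle_exit"):
                    self.emit(act.action)
                    self._dispatch(act.action, act)
                else:
                    raise EngineFault(f"unknown agent action {act.action!r}")
            else:
                _, name = nt
                del self._timers[name]
                heapq.heappop(self._timer_heap)
                if not self._opto_timer(name):
                    self._dispatch(name, None)
            self._notify_agent()
        # session end: turn every output off (conservation), log session_end
        if self.max_trials is None or self.trial_count < self.max_trials:
            self.now = self.duration
        for hole in sorted(self.devices.hole_lights):
            self.hole_light(hole, False)
        self.receptacle_light(False)
        self.houselight(False)
        for ch in sorted(self.devices.ttl_lines):
            self.ttl(ch, False)
        self.emit("session_end")
        self._finished = True
        return self.log


def run_session(machine: StateMachine, agent, seed: int, duration_ms: int,
                max_trials: Optional[int] = None,
                pump: Optional[PumpCalibration] = None,
                meta: Optional[dict] = None) -> EventLog:
    """Run one complete session and return its time-sorted event log.

    ``max_trials`` optionally stops the session once that many trials have
    been classified (used for fixed-trial-count simulations); otherwise the
    session ends exactly at ``duration_ms``.
    """
    return Engine(machine, agent, seed, duration_ms, max_trials=max_trials,
                  pump=pump, meta=meta).run()
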