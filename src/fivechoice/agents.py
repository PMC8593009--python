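"""Virtual subjects that drive the task engine.

Two policies are provided: a :class:`StochasticAgent` whose behaviour is
governed by a handful of interpretable rates and latency distributions (used
for parameter-recovery and chance-level checks), and a :class:`ScriptedAgent`
that replays a fixed action list verbatim for exact, hand-checkable traces.

The stochastic model, per trial:

* during the ITI the first premature poke time is exponential with rate
  ``premature_hazard_per_s`` (a poke is emitted only if it falls before the
  stimulus appears);
* on stimulus onset the subject responds with probability ``p_respond``; the
  responded hole is the cued one with probability
  ``p_correct_given_response``, otherwise uniform over the other four holes;
* response and reward-collection latencies are lognormal in ms, the response
  latency truncated (by resampling) to the legal response window so that
  ``p_respond`` keeps its meaning as the omission complement;
* in the working-memory choice phase the choice set is the two lit holes:
  the sample hole is chosen with ``p_match_given_response`` (default: fall
  back to ``p_correct_given_response``), else the distractor.

Each agent owns one RNG stream, spawned from the session seed independently
of the task's own stream, so task randomness (cue-hole sequences) and
behaviour are separately reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = ["AgentParams", "ScriptedAction", "ScriptedAgent", "StochasticAgent"]


@dataclass(frozen=True)
class ScriptedAction:
    time: int
    action: str                 # 'poke' | 'receptacle_entry' | 'receptacle_exit'
    hole: Optional[int] = None

    def __post_init__(self):
        if self.action not in ("poke", "receptacle_entry", "receptacle_exit"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "poke" and not 1 <= (self.hole or 0) <= 5:
            raise ValueError(f"poke needs a hole in 1..5, got {self.hole}")


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of the stochastic subject.

    Defaults emulate a well-trained mouse on the baseline attention task:
    roughly 80 % accuracy, a quarter of trials omitted, a low premature rate,
    sub-second response latencies — yielding on the order of 160 trials in a
    30-min session.
    """

    p_respond: float = 0.72
    p_correct_given_response: float = 0.8
    premature_hazard_per_s: float = 0.02
    response_latency_log_mu: float = math.log(850.0)   # ms
    response_latency_log_sigma: float = 0.35
    reward_latency_log_mu: float = math.log(1200.0)    # ms
    reward_latency_log_sigma: float = 0.30
    receptacle_dwell_ms: int = 1500
    p_match_given_response: Optional[float] = None

    def __post_init__(self):
        for name in ("p_respond", "p_correct_given_response"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_match_given_response is not None and not (
                0.0 <= self.p_match_given_response <= 1.0):
            raise ValueError("p_match_given_response must be in [0, 1]")
        if self.premature_hazard_per_s < 0:
            raise ValueError("premature_hazard_per_s must be >= 0")
        for name in ("response_latency_log_sigma", "reward_latency_log_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.receptacle_dwell_ms <= 0:
            raise ValueError("receptacle_dwell_ms must be positive")


class ScriptedAgent:
    """Replays a fixed, strictly time-ordered action list regardless of task
    state.  An empty script produces an all-omission session."""

    def __init__(self, script: Sequence[ScriptedAction]):
        self.script = list(script)
        for a, b in zip(self.script, self.script[1:]):
            if b.time <= a.time:
                raise ValueError(
                    f"script times must be strictly increasing ({a.time} -> {b.time})")
        self._armed = False

    def reset(self, rng, view) -> None:
        self._armed = True

    def observe(self, event, view):
        if self._armed and event.name == "session_start":
            self._armed = False
            return list(self.script)
        return None


class StochasticAgent:
    """Event-driven stochastic policy (see module docstring for the model)."""

    def __init__(self, params: Optional[AgentParams] = None):
        self.p = params or AgentParams()
        self.rng = None

    def reset(self, rng, view) -> None:
        self.rng = rng

    # -- samplers ----------------------------------------------------------

    def _lognormal_ms(self, mu: float, sigma: float, upper: Optional[int] = None) -> int:
        for _ in range(1000):
            v = int(round(float(self.rng.lognormal(mu, sigma))))
            v = max(v, 1)
            if upper is None or v < upper:
                return v
        return max(1, (upper or 2) - 1)

    def _response_window_ms(self, view) -> int:
        p = view.machine.params
        if view.machine.name == "5csrtt":
            return p.sd_ms + p.lh_ms
        if view.state == "sp_stim":
            return p.sp_sd_ms
        return p.cp_sd_ms

    def _choose_hole(self, target: int, alternatives: Sequence[int], p_target: float) -> int:
        if float(self.rng.random()) < p_target:
            return target
        return int(alternatives[int(self.rng.integers(0, len(alternatives)))])

    # -- policy ------------------------------------------------------------

    def observe(self, event, view):
        name = event.name
        paradigm = view.machine.name
        if paradigm == "habituation":
            if name in ("session_start", "receptacle_exit"):
                hole = int(self.rng.integers(1, 6))
                t = view.now + self._lognormal_ms(self.p.response_latency_log_mu,
                                                  self.p.response_latency_log_sigma)
                return [ScriptedAction(t, "poke", hole)]
            if name == "reward":
                return self._collect(view)
            return None

        if name == "iti_start" and paradigm == "5csrtt":
            lam = self.p.premature_hazard_per_s
            if lam > 0:
                dt_ms = int(round(float(self.rng.exponential(1.0 / lam)) * 1000.0))
                hole = int(self.rng.integers(1, 6))
                return [ScriptedAction(view.now + max(dt_ms, 1), "poke", hole)]
            return []

        if (name == "hole_light_on" and view.state == "stimulus") or name == "sp_start":
            if float(self.rng.random()) >= self.p.p_respond:
                return []  # omission; also clears any stale premature poke
            target = view.vars["target"]
            others = [h for h in range(1, 6) if h != target]
            hole = self._choose_hole(target, others, self.p.p_correct_given_response)
            latency = self._lognormal_ms(self.p.response_latency_log_mu,
                                         self.p.response_latency_log_sigma,
                                         upper=self._response_window_ms(view))
            return [ScriptedAction(view.now + latency, "poke", hole)]

        if name == "cp_start":
            if float(self.rng.random()) >= self.p.p_respond:
                return []
            target, distractor = view.vars["target"], view.vars["distractor"]
            p_match = (self.p.p_match_given_response
                       if self.p.p_match_given_response is not None
                       else self.p.p_correct_given_response)
            hole = self._choose_hole(target, [distractor], p_match)
            latency = self._lognormal_ms(self.p.response_latency_log_mu,
                                         self.p.response_latency_log_sigma,
                                         upper=self._response_window_ms(view))
            return [ScriptedAction(view.now + latency, "poke", hole)]

        if name == "reward":
            return self._collect(view)
        return None

    def _collect(self, view):
        entry = view.now + self._lognormal_ms(self.p.reward_latency_log_mu,
                                              self.p.reward_latency_log_sigma)
        exit_ = entry + self.p.receptacle_dwell_ms
        return [ScriptedAction(entry, "receptacle_entry"),
                ScriptedAction(exit_, "receptacle_exit")]
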