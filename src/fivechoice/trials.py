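"""Trial segmentation and response classification from raw event logs.

Classification here is derived purely from the raw device/behaviour events
(stimulus-light transitions, pokes, receptacle crossings, time-out markers)
and never reads the engine's own ``trial_end`` labels — so an engine log can
be checked against this independent reading of the task rules, and externally
recorded logs can be classified the same way.

A trial spans one ``iti_start`` to the next (or to session end); reward
collection after a correct response therefore belongs to the trial that
earned it.  The final trial is flagged incomplete (and excluded from counts)
when the session ends before it reaches a classification.

Attention-task response windows are half-open ``[stimulus onset, onset+SD+LH)``
— a poke at exactly the limited-hold end is not scored.  SD and LH are read
from the log metadata (engine logs embed them); for external logs lacking
them the classifier falls back to event ordering (a poke logged before the
trial's time-out marker is scored), which differs only for a poke landing on
the LH boundary millisecond.

Latency definitions: *response latency* is stimulus onset → correct poke;
*reward latency* is correct poke → receptacle entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .events import EventLog, EventRecord

__all__ = [
    "Trial",
    "segment_trials",
    "classify_5csrtt_trial",
    "classify_5cswm_trial",
]

CSRTT_CLASSES = ("correct", "incorrect", "premature", "omission")
CSWM_CLASSES = ("sp_incorrect", "sp_omission", "cp_match", "cp_nonmatch",
                "cp_omission")


@dataclass
class Trial:
    """One segmented trial with its classification and latencies."""

    index: int
    start_ms: int
    events: list = field(default_factory=list)
    cls: Optional[str] = None
    complete: bool = True
    stim_onset_ms: Optional[int] = None
    target_hole: Optional[int] = None
    response_hole: Optional[int] = None
    response_latency_ms: Optional[float] = None
    reward_latency_ms: Optional[float] = None
    # 5-CSWM phase detail
    sp_onset_ms: Optional[int] = None
    cp_onset_ms: Optional[int] = None
    sp_latency_ms: Optional[float] = None
    cp_latency_ms: Optional[float] = None

    @property
    def bin_time_ms(self) -> Optional[int]:
        """Time used for session-time binning: stimulus onset, or for
        premature trials (which never see a stimulus) the classifying poke."""
        if self.stim_onset_ms is not None:
            return self.stim_onset_ms
        for e in self.events:
            if e.name == "poke":
                return e.time
        return self.start_ms


class TrialParseError(ValueError):
    pass


def _first_idx(events, name, start: int = 0) -> Optional[int]:
    for i in range(start, len(events)):
        if events[i].name == name:
            return i
    return None


def classify_5csrtt_trial(trial_events: list[EventRecord],
                          sd_ms: Optional[int] = None,
                          lh_ms: Optional[int] = None) -> Trial:
    """Classify one 5-CSRTT trial slice from its raw events.

    Rules: a 5-choice poke before stimulus onset is *premature*; the first
    scored poke in the response window is *correct* if it hits the cued hole,
    else *incorrect*; no scored poke followed by a time-out is an *omission*.
    A slice with no classifying evidence is flagged incomplete.
    """
    if not trial_events or trial_events[0].name != "iti_start":
        raise TrialParseError("trial slice must begin with iti_start")
    t = Trial(index=-1, start_ms=trial_events[0].time, events=list(trial_events))
    stim_idx = _first_idx(trial_events, "hole_light_on")
    if stim_idx is not None:
        stim = trial_events[stim_idx]
        t.stim_onset_ms = stim.time
        t.target_hole = int(stim.payload)
        window_end = (stim.time + sd_ms + lh_ms
                      if sd_ms is not None and lh_ms is not None else None)
        to_idx = _first_idx(trial_events, "timeout_start", stim_idx)
    for i, e in enumerate(trial_events):
        if e.name != "poke":
            continue
        if stim_idx is None or i < stim_idx:
            t.cls = "premature"
            t.response_hole = int(e.payload)
            return t
        if window_end is not None:
            scored = e.time < window_end
        else:  # external log without SD/LH: rely on event ordering
            scored = to_idx is None or i < to_idx
        if not scored:
            break  # late/time-out poke: not a response
        t.response_hole = int(e.payload)
        if t.response_hole == t.target_hole:
            t.cls = "correct"
            t.response_latency_ms = e.time - stim.time
            entry_idx = _first_idx(trial_events, "receptacle_entry", i)
            if entry_idx is not None:
                t.reward_latency_ms = trial_events[entry_idx].time - e.time
        else:
            t.cls = "incorrect"
        return t
    if stim_idx is not None and to_idx is not None:
        t.cls = "omission"
        return t
    t.complete = False
    return t


def classify_5cswm_trial(trial_events: list[EventRecord]) -> Trial:
    """Classify one working-memory (DMTP) trial slice.

    The choice phase never occurs unless the sample phase was answered
    correctly; SP errors/omissions abort the trial.  Any non-matching CP poke
    (distractor or unlit hole) is a non-match error.  The task has no
    limited hold, so scoring follows event order: pokes logged before the
    phase's time-out marker are responses.
    """
    if not trial_events or trial_events[0].name != "iti_start":
        raise TrialParseError("trial slice must begin with iti_start")
    t = Trial(index=-1, start_ms=trial_events[0].time, events=list(trial_events))
    sp_idx = _first_idx(trial_events, "sp_start")
    if sp_idx is None:
        t.complete = False
        return t
    sp_stim_idx = _first_idx(trial_events, "hole_light_on", sp_idx)
    if sp_stim_idx is None:
        t.complete = False
        return t
    sp_stim = trial_events[sp_stim_idx]
    t.sp_onset_ms = t.stim_onset_ms = sp_stim.time
    t.target_hole = int(sp_stim.payload)
    cp_idx = _first_idx(trial_events, "cp_start")
    to_idx = _first_idx(trial_events, "timeout_start", sp_stim_idx)
    sp_end_idx = cp_idx if cp_idx is not None else to_idx

    sp_poke_idx = None
    for i in range(sp_stim_idx, sp_end_idx if sp_end_idx is not None
                   else len(trial_events)):
        if trial_events[i].name == "poke":
            sp_poke_idx = i
            break
    if sp_poke_idx is not None:
        sp_poke = trial_events[sp_poke_idx]
        t.response_hole = int(sp_poke.payload)
        if t.response_hole != t.target_hole:
            t.cls = "sp_incorrect"
            return t
        t.sp_latency_ms = t.response_latency_ms = sp_poke.time - sp_stim.time
        entry_idx = _first_idx(trial_events, "receptacle_entry", sp_poke_idx)
        if entry_idx is not None:
            t.reward_latency_ms = trial_events[entry_idx].time - sp_poke.time
    else:
        if sp_end_idx is not None and cp_idx is None:
            t.cls = "sp_omission"
            return t
        t.complete = False
        return t
    # SP answered correctly: look for the choice phase
    if cp_idx is None:
        t.complete = False
        return t
    cp_stim_idx = _first_idx(trial_events, "hole_light_on", cp_idx)
    if cp_stim_idx is None:
        t.complete = False
        return t
    cp_stim = trial_events[cp_stim_idx]
    t.cp_onset_ms = cp_stim.time
    cp_to_idx = _first_idx(trial_events, "timeout_start", cp_stim_idx)
    for i in range(cp_stim_idx, cp_to_idx if cp_to_idx is not None
                   else len(trial_events)):
        e = trial_events[i]
        if e.name == "poke":
            t.cp_latency_ms = e.time - cp_stim.time
            t.cls = "cp_match" if int(e.payload) == t.target_hole else "cp_nonmatch"
            return t
    if cp_to_idx is not None:
        t.cls = "cp_omission"
        return t
    t.complete = False
    return t


def _meta_int(log: EventLog, key: str) -> Optional[int]:
    v = log.meta.get(key)
    if v is None or (isinstance(v, str) and ("|" in v or v == "")):
        return None
    try:
        return int(float(v))
    except (TypeError, ValueError):
        return None


def segment_trials(log: EventLog, paradigm: Optional[str] = None) -> list[Trial]:
    """Split a session log at ``iti_start`` events and classify each slice.

    Returns only trials that reached a classification; a truncated final
    trial is dropped (it carries ``complete=False`` internally).  Habituation
    sessions have no trial structure and yield an empty list — rewards are
    counted directly from the log.
    """
    paradigm = paradigm or str(log.meta.get("paradigm", ""))
    if paradigm == "habituation":
        return []
    if paradigm == "5csrtt":
        sd, lh = _meta_int(log, "sd_ms"), _meta_int(log, "lh_ms")
        classify = lambda ev: classify_5csrtt_trial(ev, sd, lh)  # noqa: E731
    elif paradigm == "5cswm":
        classify = classify_5cswm_trial
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    starts = [i for i, e in enumerate(log.events) if e.name == "iti_start"]
    trials: list[Trial] = []
    for k, i in enumerate(starts):
        j = starts[k + 1] if k + 1 < len(starts) else len(log.events)
        t = classify(log.events[i:j])
        if t.cls is None or not t.complete:
            continue
        t.index = len(trials)
        trials.append(t)
    return trials
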