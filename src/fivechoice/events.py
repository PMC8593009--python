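"""Canonical event-log data model and CSV interchange.

Every behavioural and device event in a session is one timestamped
:class:`EventRecord`; a session is an :class:`EventLog`.  Times are integer
milliseconds from session start on the behavioural clock (logs mapped onto an
acquisition-system clock carry float times and are marked ``aligned`` in their
metadata).  The event vocabulary is closed and versioned so that externally
produced logs can be validated before analysis.

The on-disk format is a plain UTF-8 CSV with ``#``-prefixed metadata header
lines followed by a ``time_ms,event,payload`` header row.  Write→read is the
identity.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

__all__ = [
    "VOCABULARY",
    "VOCABULARY_VERSION",
    "EventRecord",
    "EventLog",
    "LogFormatError",
    "SessionSummary",
    "read_event_csv",
    "write_event_csv",
    "read_summary_csv",
    "write_summary_csv",
]

VOCABULARY_VERSION = "1"

#: Closed event vocabulary (version 1).  Payload conventions:
#: ``poke`` / ``hole_light_*`` → hole index "1".."5"; ``ttl_*`` → channel
#: index; ``reward`` → "vol_ul=<float>;steps=<int>"; ``trial_end`` → response
#: class; ``session_start`` → paradigm name.
VOCABULARY = frozenset(
    {
        "session_start",
        "session_end",
        "iti_start",
        "hole_light_on",
        "hole_light_off",
        "poke",
        "receptacle_entry",
        "receptacle_exit",
        "reward",
        "timeout_start",
        "timeout_end",
        "houselight_on",
        "houselight_off",
        "receptacle_light_on",
        "receptacle_light_off",
        "ttl_high",
        "ttl_low",
        "sp_start",
        "delay_start",
        "cp_start",
        "trial_end",
        "note",
    }
)


class LogFormatError(ValueError):
    """Raised when an event CSV violates the documented dialect."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class EventRecord:
    """One timestamped event.

    ``time`` is integer ms on the behavioural clock; logs that have been
    mapped onto an acquisition clock may carry floats.
    """

    time: Union[int, float]
    name: str
    payload: Optional[str] = None

    def payload_dict(self) -> dict:
        """Parse a ``key=value;key=value`` payload into a dict."""
        if not self.payload or "=" not in self.payload:
            return {}
        out = {}
        for part in self.payload.split(";"):
            k, _, v = part.partition("=")
            out[k] = v
        return out


@dataclass
class EventLog:
    """A time-sorted sequence of events plus session metadata."""

    events: list[EventRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def append(self, time: Union[int, float], name: str, payload=None) -> EventRecord:
        if name not in VOCABULARY:
            raise ValueError(f"event name {name!r} not in vocabulary v{VOCABULARY_VERSION}")
        if self.events and time < self.events[-1].time:
            raise ValueError(
                f"non-monotone event time {time} after {self.events[-1].time}"
            )
        rec = EventRecord(time, name, None if payload is None else str(payload))
        self.events.append(rec)
        return rec

    def filter(self, *names: str) -> list[EventRecord]:
        want = set(names)
        return [e for e in self.events if e.name in want]

    @property
    def aligned(self) -> bool:
        return str(self.meta.get("aligned", "0")) == "1"

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# fivechoice-event-log v{VOCABULARY_VERSION}\n")
        for key in sorted(self.meta):
            buf.write(f"# {key}={self.meta[key]}\n")
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["time_ms", "event", "payload"])
        for e in self.events:
            t = e.time if not isinstance(e.time, float) else repr(e.time)
            writer.writerow([t, e.name, "" if e.payload is None else e.payload])
        return buf.getvalue()

    def sha256(self) -> str:
        return hashlib.sha256(self.to_csv_text().encode()).hexdigest()


def write_event_csv(log: EventLog, path: Union[str, Path]) -> None:
    """Write ``log`` to ``path`` in the documented CSV dialect."""
    Path(path).write_text(log.to_csv_text(), encoding="utf-8")


def _parse_time(text: str, aligned: bool, lineno: int):
    try:
        if aligned:
            return float(text)
        return int(text)
    except ValueError:
        raise LogFormatError(
            f"non-{'numeric' if aligned else 'integer'} time {text!r}", lineno
        ) from None


def read_event_csv(source: Union[str, Path]) -> EventLog:
    """Read an event CSV, validating times, ordering and the vocabulary.

    Raises :class:`LogFormatError` with the offending 1-based line number for
    unknown event names, non-integer times (on a behavioural-clock log) and
    non-monotone timestamps.
    """
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    meta: dict = {}
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            content = line[1:].strip()
            if "=" in content:
                k, _, v = content.partition("=")
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    if body_start >= len(lines) or lines[body_start].split(",")[0] != "time_ms":
        raise LogFormatError("missing 'time_ms,event,payload' header row", body_start + 1)
    log = EventLog(meta=meta)
    aligned = log.aligned
    prev = None
    for offset, row in enumerate(csv.reader(lines[body_start + 1 :])):
        lineno = body_start + 2 + offset
        if not row:
            continue
        if len(row) != 3:
            raise LogFormatError(f"expected 3 columns, got {len(row)}", lineno)
        t = _parse_time(row[0], aligned, lineno)
        if t < 0:
            raise LogFormatError(f"negative time {t}", lineno)
        if prev is not None and t < prev:
            raise LogFormatError(f"decreasing time {t} after {prev}", lineno)
        if row[1] not in VOCABULARY:
            raise LogFormatError(f"unknown event name {row[1]!r}", lineno)
        log.events.append(EventRecord(t, row[1], row[2] or None))
        prev = t
    return log


# ---------------------------------------------------------------------------
# Session summaries


@dataclass
class SessionSummary:
    """Counts and derived performance metrics for one session.

    Metrics with an undefined denominator are ``None`` (written as empty CSV
    fields), never 0 or 100: a silent zero would bias stage-progression
    decisions.

    5-CSRTT metrics: ``accuracy`` = 100·correct/(correct+incorrect),
    ``pct_omissions`` = 100·omissions/trials, ``pct_premature`` =
    100·prematures/trials.  For the working-memory task the analogous sample-
    and choice-phase metrics are filled instead.
    """

    paradigm: str = ""
    stage: str = ""
    duration_ms: int = 0
    trials: int = 0
    correct: int = 0
    incorrect: int = 0
    premature: int = 0
    omission: int = 0
    rewards: int = 0
    total_reward_ul: float = 0.0
    accuracy: Optional[float] = None
    pct_omissions: Optional[float] = None
    pct_premature: Optional[float] = None
    mean_response_latency_ms: Optional[float] = None
    mean_reward_latency_ms: Optional[float] = None
    # 5-CSWM phase-resolved fields
    sp_correct: Optional[int] = None
    sp_incorrect: Optional[int] = None
    sp_omission: Optional[int] = None
    cp_match: Optional[int] = None
    cp_nonmatch: Optional[int] = None
    cp_omission: Optional[int] = None
    sp_accuracy: Optional[float] = None
    sp_pct_omissions: Optional[float] = None
    cp_accuracy: Optional[float] = None
    cp_pct_omissions: Optional[float] = None
    seed: Optional[int] = None
    config_hash: Optional[str] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_SUMMARY_COLUMNS = [f.name for f in fields(SessionSummary)]
_INT_FIELDS = {
    "duration_ms", "trials", "correct", "incorrect", "premature", "omission",
    "rewards", "sp_correct", "sp_incorrect", "sp_omission", "cp_match",
    "cp_nonmatch", "cp_omission", "seed",
}


def write_summary_csv(summaries: Iterable[SessionSummary], path: Union[str, Path]) -> None:
    """One row per session, stable column order, full float precision."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one summary")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_SUMMARY_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for s in summaries:
            row = {
                k: ("" if v is None else (repr(v) if isinstance(v, float) else v))
                for k, v in s.as_dict().items()
            }
            writer.writerow(row)


def read_summary_csv(path: Union[str, Path]) -> list[SessionSummary]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            kwargs = {}
            for k, v in row.items():
                if k not in _SUMMARY_COLUMNS:
                    raise LogFormatError(f"unknown summary column {k!r}")
                if v == "" or v is None:
                    kwargs[k] = None if k not in (
                        "paradigm", "stage") else ""
                    if k in ("duration_ms", "trials", "correct", "incorrect",
                             "premature", "omission", "rewards"):
                        kwargs[k] = 0
                    if k == "total_reward_ul":
                        kwargs[k] = 0.0
                elif k in _INT_FIELDS:
                    kwargs[k] = int(v)
                elif k in ("paradigm", "stage", "config_hash"):
                    kwargs[k] = v
                else:
                    kwargs[k] = float(v)
            out.append(SessionSummary(**kwargs))
    return out
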