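"""Alignment of behavioural timestamps with an acquisition-system clock.

TTL pulses emitted by the task are recorded as timestamps by the acquisition
system (electrophysiology or imaging).  The two clocks are related by an
affine model ``received ≈ offset + drift · emitted`` — over a 30-min session
crystal-oscillator drift is far below 1 % and curvature is negligible, so a
single linear fit suffices.  After fitting, every behavioural event time can
be mapped onto the acquisition timeline for offline analysis.

Pulse matching tolerates dropped pulses: a coarse offset is first estimated
by cross-correlating the two trains (histogram of pairwise time differences),
then pulses are paired greedily to the nearest candidate within a tolerance.

An acquisition-clock simulator with controllable offset, drift, timestamp
jitter and pulse-drop rate provides ground truth for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .events import EventLog, EventRecord

__all__ = [
    "PulseTrain",
    "ClockModel",
    "ClockSyncError",
    "match_pulses",
    "fit_clock_mapping",
    "map_timestamps",
    "simulate_acquisition_clock",
    "pulse_train_from_log",
    "read_pulse_csv",
    "write_pulse_csv",
]

DRIFT_SANITY_BOUND = 0.01  # |drift - 1| beyond this means a bad match/fit


class ClockSyncError(ValueError):
    pass


@dataclass(frozen=True)
class PulseTrain:
    """Strictly increasing pulse timestamps (ms) on one clock."""

    times: np.ndarray
    clock_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", arr)
        if arr.ndim != 1:
            raise ValueError("times must be 1-D")
        if arr.size >= 2 and not np.all(np.diff(arr) > 0):
            raise ValueError("pulse times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ClockModel:
    """Affine mapping behavioural → acquisition time, with fit diagnostics."""

    offset_ms: float
    drift: float
    residual_sd_ms: float = 0.0
    offset_se_ms: float = float("nan")
    drift_se: float = float("nan")
    n_pulses: int = 0

    def __post_init__(self):
        if abs(self.drift - 1.0) >= DRIFT_SANITY_BOUND:
            raise ClockSyncError(
                f"drift {self.drift} violates sanity bound "
                f"|drift-1| < {DRIFT_SANITY_BOUND}; check the pulse matching")

    def map(self, t):
        return self.offset_ms + self.drift * np.asarray(t, dtype=float)

    def invert(self, t):
        return (np.asarray(t, dtype=float) - self.offset_ms) / self.drift


def match_pulses(emitted: PulseTrain, received: PulseTrain,
                 tolerance_ms: Optional[float] = None,
                 max_offset_ms: float = 10_000.0):
    """Pair received pulses with emitted ones despite drops.

    Returns ``(pairs, unmatched_emitted, unmatched_received)`` where pairs is
    a list of ``(i_emitted, j_received)``.  Coarse offset: the peak of a
    histogram (cross-correlation) of pairwise received-emitted differences
    within ``±max_offset_ms``, refined by the median difference near the
    peak; then greedy nearest-neighbour assignment within ``tolerance_ms``
    (default: 45 % of the smallest emitted inter-pulse interval).
    """
    e, r = emitted.times, received.times
    if e.size == 0 or r.size == 0:
        raise ClockSyncError("empty pulse train")
    if tolerance_ms is None:
        tolerance_ms = 0.45 * float(np.min(np.diff(e))) if e.size >= 2 else max_offset_ms
    # coarse offset via histogram of pairwise differences
    diffs = (r[:, None] - e[None, :]).ravel()
    diffs = diffs[np.abs(diffs) <= max_offset_ms]
    if diffs.size == 0:
        raise ClockSyncError(f"no pulse pairs within ±{max_offset_ms} ms")
    bin_w = max(tolerance_ms / 2.0, 1.0)
    edges = np.arange(-max_offset_ms - bin_w, max_offset_ms + 2 * bin_w, bin_w)
    hist, _ = np.histogram(diffs, bins=edges)
    peak = int(np.argmax(hist))
    lo, hi = edges[max(peak - 1, 0)], edges[min(peak + 2, len(edges) - 1)]
    offset0 = float(np.median(diffs[(diffs >= lo) & (diffs <= hi)]))
    # greedy nearest-neighbour under the coarse offset
    pairs = []
    used = np.zeros(e.size, dtype=bool)
    idx = np.searchsorted(e, r - offset0)
    for j, rj in enumerate(r):
        cands = [i for i in (idx[j] - 1, idx[j]) if 0 <= i < e.size and not used[i]]
        if not cands:
            continue
        i_best = min(cands, key=lambda i: abs(rj - offset0 - e[i]))
        if abs(rj - offset0 - e[i_best]) <= tolerance_ms:
            used[i_best] = True
            pairs.append((int(i_best), int(j)))
    matched_j = {j for _, j in pairs}
    unmatched_e = [i for i in range(e.size) if not used[i]]
    unmatched_r = [j for j in range(r.size) if j not in matched_j]
    return pairs, unmatched_e, unmatched_r


def fit_clock_mapping(emitted: PulseTrain, received: PulseTrain,
                      tolerance_ms: Optional[float] = None,
                      max_unmatched_frac: float = 0.2) -> ClockModel:
    """Least-squares affine fit ``received ≈ offset + drift · emitted``.

    Pulses are matched first (tolerating drops); at least two matched pairs
    are required, and more than ``max_unmatched_frac`` unmatched *received*
    pulses is an error (it indicates the trains do not correspond).
    """
    if len(emitted) < 2 or len(received) < 2:
        raise ClockSyncError("need at least two pulses in each train to fit")
    pairs, unmatched_e, unmatched_r = match_pulses(emitted, received, tolerance_ms)
    if len(pairs) < 2:
        raise ClockSyncError("fewer than two matched pulse pairs")
    if len(unmatched_r) > max_unmatched_frac * len(received):
        raise ClockSyncError(
            f"{len(unmatched_r)} received pulses unmatched (indices "
            f"{unmatched_r[:10]}{'...' if len(unmatched_r) > 10 else ''}); "
            f"emitted unmatched: {len(unmatched_e)}")
    ei = emitted.times[[i for i, _ in pairs]]
    rj = received.times[[j for _, j in pairs]]
    if np.ptp(ei) == 0:
        raise ClockSyncError("degenerate emitted train (zero time span)")
    res = stats.linregress(ei, rj)
    residuals = rj - (res.intercept + res.slope * ei)
    ddof = 2 if len(pairs) > 2 else 0
    residual_sd = float(np.sqrt(np.sum(residuals**2) / max(len(pairs) - ddof, 1)))
    return ClockModel(
        offset_ms=float(res.intercept),
        drift=float(res.slope),
        residual_sd_ms=residual_sd,
        offset_se_ms=float(res.intercept_stderr),
        drift_se=float(res.stderr),
        n_pulses=len(pairs),
    )


def map_timestamps(log: EventLog, model: ClockModel) -> EventLog:
    """Map every event time onto the acquisition timeline.

    The returned log carries float times and is marked ``aligned`` in its
    metadata; event order is preserved (the mapping is strictly monotone).
    """
    out = EventLog(meta=dict(log.meta))
    out.meta["aligned"] = "1"
    out.meta["clock_offset_ms"] = repr(model.offset_ms)
    out.meta["clock_drift"] = repr(model.drift)
    out.events = [EventRecord(float(model.map(e.time)), e.name, e.payload)
                  for e in log.events]
    return out


def simulate_acquisition_clock(true_times: Sequence[float], offset_ms: float = 0.0,
                               drift: float = 1.0, jitter_sd_ms: float = 0.0,
                               drop_rate: float = 0.0, seed: int = 0,
                               clock_id: str = "acquisition") -> PulseTrain:
    """Simulate how an acquisition system would timestamp emitted pulses:
    affine transform plus Gaussian timestamp jitter, with each pulse dropped
    independently at ``drop_rate``."""
    if not 0.0 <= drop_rate < 1.0:
        raise ValueError("drop_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    t = np.asarray(true_times, dtype=float)
    received = offset_ms + drift * t
    if jitter_sd_ms > 0:
        received = received + rng.normal(0.0, jitter_sd_ms, size=t.size)
    if drop_rate > 0:
        received = received[rng.random(t.size) >= drop_rate]
    received = np.sort(received)
    # guard against jitter-induced ties (strict monotonicity required)
    for k in range(1, received.size):
        if received[k] <= received[k - 1]:
            received[k] = received[k - 1] + 1e-6
    return PulseTrain(received, clock_id)


def pulse_train_from_log(log: EventLog, channel: int = 1,
                         clock_id: str = "behaviour") -> PulseTrain:
    """Extract the TTL rising-edge times of one channel from a session log."""
    times = [e.time for e in log.events
             if e.name == "ttl_high" and int(e.payload) == channel]
    return PulseTrain(np.asarray(times, dtype=float), clock_id)


def write_pulse_csv(train: PulseTrain, path: Union[str, Path]) -> None:
    lines = [f"# clock_id={train.clock_id}", "time_ms"]
    lines += [repr(float(t)) for t in train.times]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pulse_csv(path: Union[str, Path]) -> PulseTrain:
    clock_id = ""
    times = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            if k.strip() == "clock_id":
                clock_id = v.strip()
            continue
        if line == "time_ms":
            continue
        try:
            times.append(float(line))
        except ValueError:
            raise ClockSyncError(f"line {lineno}: bad pulse time {line!r}") from None
    return PulseTrain(np.asarray(times, dtype=float), clock_id)
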