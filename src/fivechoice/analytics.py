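"""Session performance indicators and comparisons.

The three attention-task indicators follow the standard definitions:

* ``accuracy``     = 100 · correct / (correct + incorrect)
* ``%omissions``   = 100 · omissions / trials
* ``%premature``   = 100 · prematures / trials

with *trials* the number of initiated trials that reached a classification
(premature trials count).  Undefined metrics (zero denominator) are ``None``,
never 0 or 100.  The working-memory task reports the analogous sample-phase
metrics plus the choice-phase matching accuracy over trials that reached the
choice phase.

Also here: 3-min time-binned performance curves, per-class latency summaries
and the Pearson chi-square comparison of response-class shares between two
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .events import EventLog, SessionSummary
from .trials import Trial, segment_trials

__all__ = [
    "compute_5csrtt_metrics",
    "compute_5cswm_metrics",
    "summarize_session",
    "BinnedMetrics",
    "time_binned_metrics",
    "ShareTestResult",
    "response_share_test",
    "latency_summary",
]


def _pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def _mean(values: Sequence[float]) -> Optional[float]:
    values = [v for v in values if v is not None]
    return float(np.mean(values)) if values else None


def compute_5csrtt_metrics(trials: Sequence[Trial]) -> SessionSummary:
    """Counts and the three percentage indicators for classified 5-CSRTT
    trials; mean response and reward latencies over correct trials."""
    s = SessionSummary(paradigm="5csrtt")
    s.trials = len(trials)
    for t in trials:
        if t.cls not in ("correct", "incorrect", "premature", "omission"):
            raise ValueError(f"not a 5-CSRTT trial class: {t.cls!r}")
    s.correct = sum(t.cls == "correct" for t in trials)
    s.incorrect = sum(t.cls == "incorrect" for t in trials)
    s.premature = sum(t.cls == "premature" for t in trials)
    s.omission = sum(t.cls == "omission" for t in trials)
    s.accuracy = _pct(s.correct, s.correct + s.incorrect)
    s.pct_omissions = _pct(s.omission, s.trials)
    s.pct_premature = _pct(s.premature, s.trials)
    corrects = [t for t in trials if t.cls == "correct"]
    s.mean_response_latency_ms = _mean([t.response_latency_ms for t in corrects])
    s.mean_reward_latency_ms = _mean([t.reward_latency_ms for t in corrects])
    s.rewards = s.correct
    return s


def compute_5cswm_metrics(trials: Sequence[Trial]) -> SessionSummary:
    """Phase-resolved metrics for the working-memory task.

    Sample-phase formulas mirror the attention task (SP-correct trials are
    those that reached the choice phase); choice-phase accuracy is
    100·match/(match+non-match) over CP-reaching trials, and CP omissions are
    relative to CP-reaching trials.  An SP failure contributes to the SP
    denominators only.
    """
    s = SessionSummary(paradigm="5cswm")
    s.trials = len(trials)
    counts = {c: 0 for c in ("sp_incorrect", "sp_omission", "cp_match",
                             "cp_nonmatch", "cp_omission")}
    for t in trials:
        if t.cls not in counts:
            raise ValueError(f"not a 5-CSWM trial class: {t.cls!r}")
        counts[t.cls] += 1
    sp_correct = counts["cp_match"] + counts["cp_nonmatch"] + counts["cp_omission"]
    s.sp_correct = sp_correct
    s.sp_incorrect = counts["sp_incorrect"]
    s.sp_omission = counts["sp_omission"]
    s.cp_match = counts["cp_match"]
    s.cp_nonmatch = counts["cp_nonmatch"]
    s.cp_omission = counts["cp_omission"]
    s.sp_accuracy = _pct(sp_correct, sp_correct + s.sp_incorrect)
    s.sp_pct_omissions = _pct(s.sp_omission, s.trials)
    s.cp_accuracy = _pct(s.cp_match, s.cp_match + s.cp_nonmatch)
    s.cp_pct_omissions = _pct(s.cp_omission, sp_correct)
    sp_resp = [t for t in trials if t.sp_latency_ms is not None]
    s.mean_response_latency_ms = _mean([t.sp_latency_ms for t in sp_resp])
    s.mean_reward_latency_ms = _mean([t.reward_latency_ms for t in sp_resp])
    s.rewards = sp_correct + s.cp_match
    return s


def summarize_session(log: EventLog, trials: Optional[Sequence[Trial]] = None
                      ) -> SessionSummary:
    """Full summary of one session log: classified-trial metrics plus reward
    counts/volumes and session metadata read from the log itself."""
    paradigm = str(log.meta.get("paradigm", ""))
    if trials is None:
        trials = segment_trials(log)
    if paradigm == "5csrtt":
        s = compute_5csrtt_metrics(trials)
    elif paradigm == "5cswm":
        s = compute_5cswm_metrics(trials)
    elif paradigm == "habituation":
        s = SessionSummary(paradigm="habituation")
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    rewards = log.filter("reward")
    s.rewards = len(rewards)
    s.total_reward_ul = float(sum(float(e.payload_dict().get("vol_ul", 0))
                                  for e in rewards))
    s.duration_ms = int(log.meta.get("duration_ms", 0) or 0)
    s.stage = str(log.meta.get("stage", ""))
    if "seed" in log.meta:
        s.seed = int(log.meta["seed"])
    s.config_hash = log.meta.get("config_hash")
    return s


@dataclass
class BinnedMetrics:
    """Per-time-bin trial counts and performance across a session (default
    3-min bins).  Trials are binned by stimulus onset; premature trials by
    their classifying poke.  Empty bins carry ``None`` metrics."""

    bin_width_ms: int
    edges_ms: list = field(default_factory=list)       # len = n_bins + 1
    trial_counts: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)
    pct_omissions: list = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.trial_counts)


def time_binned_metrics(trials: Sequence[Trial], duration_ms: int,
                        bin_width_ms: int = 180_000) -> BinnedMetrics:
    """Bin classified trials over the session and recompute accuracy and
    %omissions per bin with the session-level formulas."""
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    n_bins = int(np.ceil(duration_ms / bin_width_ms))
    bm = BinnedMetrics(bin_width_ms=bin_width_ms,
                       edges_ms=[i * bin_width_ms for i in range(n_bins + 1)])
    binned: list[list[Trial]] = [[] for _ in range(n_bins)]
    for t in trials:
        b = min(t.bin_time_ms // bin_width_ms, n_bins - 1)
        binned[int(b)].append(t)
    for group in binned:
        c = sum(t.cls == "correct" for t in group)
        i = sum(t.cls == "incorrect" for t in group)
        o = sum(t.cls == "omission" for t in group)
        bm.trial_counts.append(len(group))
        bm.accuracy.append(_pct(c, c + i))
        bm.pct_omissions.append(_pct(o, len(group)))
    return bm


@dataclass(frozen=True)
class ShareTestResult:
    statistic: float
    df: int
    p_value: float
    pooled_categories: tuple = ()


def response_share_test(counts_a: Sequence[int], counts_b: Sequence[int],
                        labels: Sequence[str] = ("correct", "incorrect",
                                                 "premature", "omission")
                        ) -> ShareTestResult:
    """Pearson chi-square comparing the shares of the four response classes
    between two conditions (2×4 table, df = 3).

    Categories empty in both conditions are pooled out (df reduced and the
    pooled labels reported).  Identical tables give statistic 0, p = 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if not (np.allclose(a, np.round(a)) and np.allclose(b, np.round(b))):
        raise ValueError("counts must be integers")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both conditions need at least one response")
    keep = (a + b) > 0
    pooled = tuple(lbl for lbl, k in zip(labels, keep) if not k)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("fewer than two non-empty categories; no test possible")
    table = np.vstack([a, b])
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ShareTestResult(float(stat), int(df), float(p), pooled)


def latency_summary(trials: Sequence[Trial], which: str = "response",
                    hist_edges_ms: Optional[Sequence[float]] = None) -> dict:
    """Per-response-class latency quantiles and histogram.

    ``which`` selects ``response`` or ``reward`` latencies; classes without
    latencies (omissions, prematures) are absent from the result.
    """
    attr = {"response": "response_latency_ms", "reward": "reward_latency_ms"}[which]
    if hist_edges_ms is None:
        hist_edges_ms = np.arange(0.0, 5001.0, 250.0)
    edges = np.asarray(hist_edges_ms, dtype=float)
    out: dict = {}
    by_class: dict[str, list[float]] = {}
    for t in trials:
        v = getattr(t, attr)
        if v is not None:
            by_class.setdefault(t.cls, []).append(float(v))
    for cls, values in sorted(by_class.items()):
        arr = np.asarray(values)
        counts, _ = np.histogram(arr, bins=edges)
        out[cls] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "q25": float(np.percentile(arr, 25)),
            "q75": float(np.percentile(arr, 75)),
            "hist_counts": counts.tolist(),
            "hist_edges_ms": edges.tolist(),
        }
    return out
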