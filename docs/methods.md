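# Methods

## Simulation model

The engine is a deterministic discrete-event simulator on an integer
millisecond clock starting at 0 at the session-start event; there is no
wall-clock dependence. A task is a finite-state machine: named states, a
handler for every reachable (state, event) pair (anything else is an engine
fault naming the pair), named timers that are cancelled on state exit unless
declared persistent, and virtual devices — five stimulus-hole lights, the
receptacle light, the house light, a stepper-motor pump and four TTL output
lines — whose level changes are logged as events. Subjects interact through
three input kinds: `poke` (hole 1–5), `receptacle_entry`, `receptacle_exit`.

**Determinism.** At equal timestamps, subject inputs are processed before
timer expiries; simultaneous timers fire in alphabetical order of timer
name. All randomness flows through two generator streams spawned from the
single session seed — one for the task (cue holes, variable ITIs,
distractors), one for the agent — so cue sequences are invariant under
changes to agent parameters and vice versa. The same (task, agent, seed,
duration) reproduces a byte-identical log; tests assert hash equality.

**Boundary conventions.** Response windows are half-open `[start, end)`:
a poke at exactly the end of the stimulus duration is still scored (it
coincides with the start of the limited hold), while a poke at exactly the
limited-hold end is not scored and the trial becomes an omission. Because
inputs win ties globally, the limited-hold handler enforces this with an
explicit deadline check. A poke at exactly the ITI end is premature. Pokes
during time-outs, reward collection, the working-memory delay and (in the
working-memory task) the ITI are logged — the log records every event — but
have no task consequence.

**Pump.** Reward volumes are coded as stepper-motor steps,
`steps = round(volume / µl_per_step)` with half rounding up, so the
dispensed volume differs from the commanded one by at most half a step. The
default calibration of 0.5 µl/step is a configurable placeholder; real pumps
are bench-calibrated per unit.

## Task parameters (defaults)

| parameter | attention task | working-memory task |
|---|---|---|
| stimulus duration | 2000 ms (SD) | SP ≤ 10000 ms, CP ≤ 5000 ms |
| inter-trial interval | 5000 ms | 5000 ms |
| limited hold | 2000 ms | — (windows are the maximum SDs) |
| time-out | 5000 ms | 5000 ms |
| reward | 20 µl | SP 10 µl, CP 60 µl |
| delay (after SP collection) | — | 2000 ms |
| house light | on; off in time-out | off; on in time-out |
| session | 30 min | 30 min |

Habituation: all five holes lit for the whole session, every poke rewarded
with 40 µl. The working-memory task's ITI length is not a protocol constant
we could source, so it defaults to the attention-task value (5 s) and is
configurable. Challenge protocols derive from the baseline: *attention*
shortens SD to 800 ms; *fixed ITI* sets a longer ITI; *variable ITI* draws
each trial's ITI uniformly from a configurable set (default 5/7.5/12.5 s —
a placeholder, as published variable-ITI sets differ between labs).

Training stages are data, not code: a plan is a list of (parameters,
criteria) pairs. The only hard protocol constant is the habituation
advancement rule — at least 30 rewards in each of two consecutive sessions.
The shipped stage 1–5 ramp (SD 8→4→2 s, ITI 2→5 s) and criteria (accuracy
≥ 80 %, %omissions ≤ 50 %, ≥ 30 correct, 2 consecutive sessions) are
editable placeholders; per-lab criterion tables should replace them.
Transitions depend only on the trailing `consecutive`-session block, and a
metric a criterion needs but a summary lacks raises an error naming the
metric rather than silently failing the check.

## Stochastic subject

The virtual subject is intentionally simple — a stationary policy with
interpretable parameters, not a learning model:

- `p_respond` (default 0.72): probability of responding on a cued trial;
  its complement is the omission rate among non-premature trials.
- `p_correct_given_response` (0.8): probability the responded hole is the
  cued one; otherwise uniform over the other four holes. Setting it to 0.2
  therefore makes the choice uniform over all five holes — the chance-level
  condition.
- `premature_hazard_per_s` (0.02): constant hazard of a premature poke
  during the ITI; the premature fraction over many trials is
  1 − exp(−λ·ITI).
- Response latency: lognormal, median 850 ms, σ_log 0.35, truncated by
  resampling to the legal response window (truncation rather than censoring
  keeps `p_respond` equal to the realised response rate). Reward latency:
  lognormal, median 1200 ms, σ_log 0.30; receptacle dwell 1500 ms.
- In the working-memory choice phase the choice set is the two lit holes:
  the sample hole with `p_match_given_response` (default: falls back to
  `p_correct_given_response`), else the distractor.

These defaults were chosen once to land in the range a well-trained mouse
produces on the baseline attention task (on the order of 160 trials per
30-min session, accuracy near 80 %, a quarter of trials omitted) and are not
tuned thereafter. The latency family is a modelling choice; no distribution
is implied by the protocol.

What the simulated data does *not* emulate: learning and within-session
fatigue (rates are stationary), satiety (a habituation subject will happily
collect hundreds of rewards), perseverative response structure, sound
distraction, and any biological effect of stimulation — opto schedules only
produce the TTL trains. Passing tests therefore validate the *machinery*
(task logic, logging, metrics, scheduling, alignment) under known ground
truth, not any claim about animal behaviour.

## Event logs and metrics

Logs are UTF-8 CSV: `#`-prefixed metadata headers (paradigm, seed, duration,
task parameters, config hash, vocabulary version) and `time_ms,event,payload`
rows drawn from a closed, versioned vocabulary; write→read is the identity
and the parser reports unknown names, non-integer or decreasing times with
the offending line number.

Trials span one `iti_start` to the next; reward collection belongs to the
trial that earned it, and a final trial truncated before classification is
excluded from counts. Classification is recomputed from the raw device and
behaviour events — never from the engine's own `trial_end` labels — which
lets the suite cross-check the engine against an independent reading of the
rules, and classifies externally recorded logs the same way. The attention
task's response window needs SD and LH, which engine logs embed in their
metadata; for logs lacking them the classifier falls back to event ordering,
which differs only for a poke on the exact limited-hold boundary
millisecond.

Undefined metrics (e.g. accuracy with no responses) are explicit missing
values, never 0 or 100 — a silent extreme would bias stage decisions.
Percentages are kept at full float precision; rounding is presentation-only.
Time-binned curves (default 3-min bins) assign trials by stimulus onset;
premature trials, which never see a stimulus, are assigned by their
classifying poke so the bins still partition the session. The
response-share comparison between two conditions is a Pearson chi-square on
the 2×4 class table (df 3; categories empty in both conditions are pooled
out and reported).

## Clock alignment

Behavioural and acquisition clocks are related by an affine model
`received ≈ offset + drift · emitted`; over a 30-min session oscillator
drift is orders of magnitude below the 1 % sanity bound enforced on fits,
and curvature is negligible, so no piecewise model is attempted. Matching
tolerates dropped pulses: a coarse offset is estimated from the peak of a
histogram of pairwise received−emitted differences (a cross-correlation of
the two trains), refined by the median near the peak, followed by greedy
nearest-neighbour pairing within a tolerance (default 45 % of the smallest
emitted inter-pulse interval). Too many unmatched received pulses is an
error rather than a silent bad fit. The fit is ordinary least squares with
standard errors and residual SD reported; mapped logs carry float times and
an `aligned` metadata flag (the integer-ms invariant applies to
behavioural-clock logs only).

## Problem sizes used in the checks

Statistical checks run at sizes where the 99 % confidence intervals are
decisive yet cheap: 10,000 trials for the chance-level accuracy check, 2,000
trials for parameter recovery, 100 pulses for clock recovery, 50 randomized
short sessions for the metric-formula oracle. These sizes are the package's
own convention and complete in seconds.
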