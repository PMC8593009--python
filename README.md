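# fivechoice

A software-only 5-choice operant box: discrete-event task engines for the
standard nose-poke paradigms used in rodent cognitive neuroscience —
habituation, the **5-choice serial reaction time task** (5-CSRTT, sustained
attention and impulsivity) and the **5-choice spatial working memory task**
(5-CSWM, delayed matching to position) — driven by simulated subjects, with
millisecond event logging, the standard performance metrics, criterion-based
training-stage scheduling, optogenetic TTL pulse scheduling and offline clock
alignment with electrophysiology acquisition systems.

It is aimed at people who build, test or analyse operant behavioural
pipelines: everything a physical box would produce (event logs, session
summaries, TTL trains) is generated in simulation, deterministically from a
seed, so analysis code, stage-progression rules and alignment procedures can
be validated end-to-end without animals or hardware.

## The tasks and their metrics

In the 5-CSRTT operant cycle, an inter-trial interval (ITI, baseline 5 s) —
initiated by the subject leaving the reward receptacle or by the end of a
time-out — is followed by the illumination of one of five holes for the
stimulus duration (SD, baseline 2 s), plus a limited hold (LH, 2 s) after
light-off. Poking the cued hole during SD or LH is a *correct* response,
rewarded with 20 µl milk; poking during the ITI is *premature*, poking an
uncued hole *incorrect*, and not poking an *omission* — each of those
triggers a 5 s time-out with the house light switched off. Sessions last
30 min. Performance is summarised by

- accuracy = 100 · correct / (correct + incorrect)  (sustained attention;
  chance level 20 %),
- %omissions = 100 · omissions / trials  (task participation),
- %premature = 100 · prematures / trials  (motor impulsivity),

plus response latency (stimulus onset → correct poke) and reward latency
(correct poke → receptacle entry).

The 5-CSWM task is a delayed-matching-to-position assay: a sample phase
(one lit hole, ≤ 10 s; correct poke earns 10 µl), a 2 s delay after the
sample reward is collected, then a choice phase (sample hole + one
distractor lit, ≤ 5 s) where re-poking the sample hole earns 60 µl. Errors
or omissions in either phase abort the trial into a time-out; house-light
polarity is inverted relative to the attention task.

Virtual subjects are either **scripted** (exact, hand-checkable action
traces) or **stochastic**, parameterised by interpretable rates: response
probability, probability of choosing the cued hole given a response, an
exponential premature-poke hazard during the ITI, and lognormal response and
reward latencies.

## Worked example

```yaml
# baseline.yaml
paradigm: 5csrtt
seed: 42
duration_min: 30
agent:
  p_respond: 0.72
  p_correct_given_response: 0.8
  premature_hazard_per_s: 0.02
out_dir: session01
```

```
$ fivechoice run baseline.yaml
defaults filled: challenge, opto, params, script, stage
paradigm=5csrtt seed=42 events=1607 trials=177 rewards=87
wrote session01/events.csv and session01/summary.csv

$ fivechoice analyze session01/events.csv --out re.csv --binned binned.csv
trials=177 accuracy=74.35897435897436 pct_omissions=23.728813559322035 pct_premature=10.169491525423728
wrote re.csv
```

The simulated subject initiated 177 trials in 30 min and collected 87
rewards; accuracy 74.4 % means 74.4 % of its responses hit the cued hole
(the agent's hit probability is 0.8, and a finite session scatters around
it), 23.7 % of trials were omitted (response probability 0.72), and 10.2 %
of trials ended with a premature poke (hazard 0.02 s⁻¹ over a 5 s ITI gives
an expected 1 − e^(−0.1) ≈ 9.5 %). `--binned` writes the same metrics in
3-min intervals across the session:

```
bin_start_ms,bin_end_ms,trials,accuracy,pct_omissions
0,180000,19,86.66666666666667,15.789473684210526
180000,360000,17,80.0,29.41176470588235
...
```

Re-running with the same seed reproduces every file byte-for-byte. Other
commands: `fivechoice cohort` (n seeded subjects plus an aggregate table),
`fivechoice align` (map an event log onto an acquisition-system clock fitted
from TTL pulse trains), `fivechoice schedule` (apply a stage-progression
criterion to a session history). The same functionality is available as a
library — see `fivechoice.tasks`, `fivechoice.agents`,
`fivechoice.analytics`, `fivechoice.scheduler`, `fivechoice.sync`.

## Documentation

`docs/methods.md` describes the simulation model, its assumptions and
numerical conventions (time base, tie-breaks, boundary inclusivity), the
stochastic-subject parameters and what the simulated data can and cannot
stand in for.
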