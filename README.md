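# eyeblink

Trace scoring, cohort simulation and the full statistical battery for
Pavlovian **delay eyeblink conditioning** in head-fixed mice, plus the
accompanying motor-task analyses (ErasmusLadder, accelerating rotarod,
balance beam, grip strength).

## Who this is for

Labs running eyeblink conditioning record eyelid-position time series at a
fixed frame rate: 20 daily sessions of 240 trials (20 blocks of 1 CS-only,
1 US-only and 10 paired trials), with a conditional stimulus (LED) leading a
corneal air puff by an interstimulus interval (ISI) of 250 ms in the first
training phase and 500 ms in the second. This package turns those raw traces
into conditioned-response (CR) outcomes and fits the multilevel models that
repeated-measures behavioral designs require — and it ships a synthetic-data
generator with known ground truth, so every stage of the analysis can be
validated by parameter recovery instead of faith.

## What it computes

**Scoring** (`preprocess`, `cr_metrics`). Each 2000 ms trial snippet is
filtered forward and backward with a 4th-order Butterworth low-pass at 50 Hz
(zero phase, so latencies are unbiased), aligned by the median of its 500 ms
pre-CS baseline, and flagged invalid when pre-CS activity exceeds 7× the
interquartile range. Traces are normalized so a full blink equals 1 NEC
(normalized eye closure): the divisor is the peak of the session's averaged
unconditioned response (UR) over the post-US window. On valid CS-only trials
a CR is an eyelid movement with

* peak amplitude > 0.1 NEC,
* onset latency in [50, 500] ms and peak latency in [100, 1000] ms after CS
  onset (closed intervals),

and a CR is *perfectly timed* when its peak falls within ±50 ms of the
(omitted) US onset. Session summaries report the CR proportion, NEC at 250
and 500 ms after CS onset, mean onset/peak latencies and the perfectly-timed
proportion.

**Statistics** (`stats_models`). One model family per outcome type, each
with training day (categorical), genotype and their interaction as fixed
effects and per-mouse random effects:

| outcome | model | omnibus test |
|---|---|---|
| trial-level CR presence | mixed binomial logistic (Laplace ML) | Wald χ² |
| NEC amplitudes, latencies | linear mixed model (ML) | likelihood ratio |
| proportions in (0,1) | mixed beta regression (logit link) | likelihood ratio |
| censored latency to fall | Cox PH with log-normal per-mouse frailty | Wald χ² |

Two random structures are compared by likelihood-ratio test (random
intercepts per mouse vs. intercepts plus day-level effects); per-day
genotype contrasts are Holm-adjusted. `power_sample_size` performs the
noncentral-*t* sample-size iteration for a two-sample design. The binomial
mixed GLM reproduces lme4's `glmer` to ~4 decimals on matched data (see
`tests/test_stats.py`).

**Motor battery** (`motor_tasks`). The ladder's correct-step proportion is
two-part distributed: "clean sweeps" (all steps correct) are analyzed as a
mixed logistic model over all trials, and the remaining mixed trials as a
mixed beta regression after Smithson–Verkuilen boundary compression.
Rotarod latencies are right-censored at 300 s (the 80 RPM sub-experiment is
excluded) and go to the Cox frailty model. Beam crossing times and grip
forces are modeled on the log scale, with grip means back-translated to
newton.

## Worked example

```bash
python examples/power_analysis.py
```

```
required mice per group: 17
power at n=17: 0.807
power at n=16: 0.781 (just below 80%)
```

A 0.2 NEC group difference at SD 0.2 (standardized effect d = 1) needs 17
mice per group for 80% power at two-sided α = 0.05 — 16 falls just short.

```bash
python examples/simulate_and_score.py
```

```
simulated 1728 trials (4 mice x 6 days)
valid CS-only trials scored: 144; invalid trials: 42

mean CR proportion per day and genotype ...
day       NF1_HET     WT
1           0.250  0.333
...
mean peak latency (ms after CS onset) on CR trials ...
4           237.0  210.0
5           365.0  325.0
6           439.0  428.0
```

The CR proportion grows with training, and after the ISI switch (day 4 in
this shortened schedule) the mean CR peak latency migrates from ~250 ms
toward the new 500 ms US onset — the adaptive-timing signature the scoring
is designed to expose. `examples/fit_acquisition_models.py` and
`examples/motor_battery.py` run the statistical battery on simulated
cohorts; a thin CLI (`eyeblink simulate|score|motor|run`) wraps the same
functions for shell use.

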