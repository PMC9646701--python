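# Methods

This note documents the models and procedures the package implements, the
defaults it chooses where the procedure leaves room, and what the synthetic
data can and cannot establish.

## Trace scoring

**Pipeline order.** Each trial is processed filter → baseline-align →
validity flag → normalize. Filtering precedes the validity check so that
above-band sensor spikes (which the 50 Hz low-pass removes anyway) cannot
disqualify a trial.

**Filter.** Butterworth low-pass, cutoff 50 Hz, order 4, applied forward and
backward (`scipy.signal.filtfilt`), giving zero phase (no latency bias) and
an effective order of 8. Only the cutoff is dictated by the procedure; order
4 is this package's choice, standard for 300 fps eyelid data. Inputs must be
longer than the filter's padding (3×(order+1) samples) and the cutoff below
Nyquist.

**Baseline.** The median of the 500 ms pre-CS window is subtracted. The
median rather than the mean keeps an isolated pre-CS blink from shifting the
baseline; alignment is idempotent.

**Validity.** A trial is invalid when max |pre − median(pre)| > 7 × IQR(pre),
with the IQR computed on the trial's own pre-CS samples (a session-pooled
IQR is a plausible alternative reading; the within-trial version is the
default and the rule is config-exposed via `k`). Degenerate baselines are
resolved with a relative flatness tolerance: deviations at or below
1e-5 × max|trace| count as zero, so a numerically-silent baseline is valid
and a zero-IQR baseline with real activity is invalid. The rule is invariant
to positive rescaling of the trace.

**Normalization.** The session factor is the maximum of the sample-wise
average of all *valid US-containing* trials (US-only and paired by default;
`ur_source="us_only"` restricts it), taken over the window from US impact to
trace end so that CRs in paired trials cannot inflate the factor. Sessions
with no valid US trial, or a non-positive factor (no reflexive closure), are
unusable and reported, never silently dropped. NEC output is invariant to
session-wide positive rescaling of the raw signal.

**CR detection.** On valid CS-only trials: the peak is the earliest maximal
sample in the 1000 ms window after CS onset; the onset is the start of the
contiguous run of samples ≥ 0.02 NEC containing the peak, required to last
≥ 10 ms (threshold and sustain are parameters — "onset" has no universal
definition, this is the package's operationalization). A CR requires peak
amplitude > 0.1 NEC, onset in [50, 500] ms, peak in [100, 1000] ms; all
interval checks are closed, so boundary samples count as inside. NEC at 250
and 500 ms and the CR proportion are computed over valid CS-only trials
(including CR-absent ones); latency means over CR-present trials only.
"Perfectly timed" means the peak lies within ±50 ms of the omitted US onset,
closed interval.

## Synthetic cohorts

The generator emulates the paradigm: 240-trial sessions in 20 blocks of
1 CS-only + 1 US-only + 10 paired (seeded per-block permutation), ten days
at ISI 250 ms then ten at 500 ms, traces of 2000 ms at 300 fps with a 500 ms
pre-CS baseline. The air puff is triggered `isi − delay` ms after CS onset
(default delay 14 ms → 236 ms for the short ISI) and impacts at the ISI.

Per-trial traces are additive in raw units: Gaussian baseline noise (SD
0.05 vs a UR gain of 4.0), an optional pre-CS artifact bump (probability
0.02), a raised-cosine CR bump on CS-containing trials, and a stereotyped UR
(smooth ~25 ms rise, 250 ms exponential decay) on US-containing trials, with
a soft saturation cap at 1.05 × the UR gain representing full closure.
Acquisition follows a saturating law p(d) = p_max(1 − e^(−k_g d)) per
genotype (defaults: p_max 0.9, k_WT 0.30, k_NF1 0.45 — the mutant learns
slightly faster, matching the qualitative direction of the study system);
amplitude follows the same law toward 0.6 NEC; at the ISI switch both
restart from 0.8 × their phase-1 end value. CR peak-time means adapt
exponentially (rate 0.6/day) from 180 ms toward the current US onset with
50 ms jitter. These dynamics parameters are invented plumbing chosen to look
like realistic acquisition; they are not fitted to any dataset.

**Ground truth.** Every trial records whether a CR was emitted and, for
emitted CRs, the onset/peak/amplitude of the *band-limited* clean component
— i.e. the CR bump passed through the same 50 Hz zero-phase filter and
normalized by the session's clean-component factor — scanned with the
scoring definitions (independently coded). Ground truth is defined in this
observable space because the filter itself is part of the measurement: the
analytic bump support starts where the amplitude is exactly zero, which no
threshold detector can or should report. With noise and artifacts disabled,
the scoring path reproduces this table exactly at sample resolution; that
recovery is asserted in the acceptance suite.

**What the simulator does not model.** The adaptive inter-trial-interval
gating (trials are emitted as independent snippets — ITI policy affects
acquisition rate, not scoring correctness), eyelid mechanics, camera noise
beyond white Gaussian, within-session learning, and extinction dynamics.
Passing recovery tests therefore demonstrates correctness of the scoring
arithmetic, not robustness to every artifact real video produces.

**Motor tables.** Ladder: 5 days × 42 runs; each trial is a clean sweep with
probability ~0.16 (logit-linear in day) or draws its correct-step proportion
from a beta law (mean 0.75, precision 12). Rotarod: 4 days × 4 trials,
log-normal latencies improving by 0.25 log-units/day, right-censored at
300 s, plus 80 RPM rows on later days/trials that preparation must discard.
Beam: two crossings per width, log-time width effect −0.5. Grip: 4 days × 2
pulls, log-normal around 90 N. All tables share per-mouse random intercepts
(SD 0.25 on the log/logit scale) and carry no genotype effect by default.

## Statistical battery

All models are fitted by maximum likelihood (not REML), so likelihood-ratio
comparisons between fixed-effects structures are valid.

* **Binomial logistic** (trial-level 0/1): mixed GLM via the Laplace
  approximation — the same approximation lme4's `glmer` uses at nAGQ = 1,
  and the implementation matches `glmer` to ~4 decimals on matched data
  (frozen cross-check in the test suite). A per-session binomial-counts
  aggregation is available and gives the same inference. Omnibus tests are
  Wald χ² per term, with the fixed-effects covariance conditioned on the
  variance estimates (as `glmer`'s `vcov` does).
* **Gaussian LMM** (amplitudes, latencies, log-times/forces): statsmodels
  `MixedLM` with ML; omnibus tests are likelihood ratios from drop-term
  refits (marginal, type-III-style, under treatment coding). Per-day
  contrasts use *t* CIs with mouse-level degrees of freedom
  (n_mice − n_groups).
* **Beta regression** (proportions strictly inside (0,1)): logit-link
  mean-precision beta GLMM via the same Laplace engine; LR omnibus tests.
  Inputs on the boundary raise an error pointing to the Smithson–Verkuilen
  compression y′ = (y(n−1)+0.5)/n, which the ladder analysis applies to
  mixed trials (which can legitimately contain 0).
* **Cox frailty** (censored latencies): Breslow partial likelihood with a
  per-mouse normal random effect on the log hazard, maximized jointly over
  (β, b) with the frailty variance profiled by the Laplace-approximate
  integrated partial likelihood — the approach of the coxme package. With
  the frailty variance forced to zero the fit matches lifelines'
  `CoxPHFitter` to 1e-6 (tested). Day is the only time-varying covariate;
  richer random structures than a shared frailty are out of scope.

**Random-structure selection.** Candidates are (a) random intercepts per
mouse, and (b) intercepts plus day-level random effects per mouse with one
shared variance. Structure (b) realizes "random slopes per time point" with
a diagonal covariance; a fully unstructured day covariance is generally
unidentifiable at 20 mice × 10 days, so the diagonal form is the default and
the chosen structure is recorded in every `FitResult`. The LR test selects
(b) when p < 0.05, with fallback to (a) on non-convergence (recorded as a
warning).

**Multiplicity.** Per-day genotype contrasts within a phase form one Holm
family (step-down: sort ascending, multiply by m − rank + 1, enforce
monotonicity, cap at 1). Significance is 0.05 after correction.

**Power.** `power_sample_size` returns the smallest equal n such that the
two-sample two-sided t-test at effect d = δ/σ reaches the target power,
iterating the noncentral-t distribution; it agrees with statsmodels'
`TTestIndPower` (tested) and returns 17 per group at d = 1, 80% power,
α = 0.05.

## Numerical choices

* Inner mode searches use clipped Newton steps (|step| ≤ 3, |b| ≤ 30) since
  the beta log-likelihood is not globally concave in the random effects.
* Variance parameters are optimized on the log scale with bounds
  (log σ ∈ [−8, 3], log φ ∈ [−3, 12]) so degenerate data (e.g. an outcome
  with no variation) terminates at a boundary instead of diverging.
* The LMM falls back across optimizers (lbfgs → powell → nm) when a
  boundary variance makes the Hessian singular.
* Likelihood-ratio statistics that come out marginally negative (within
  1e-5 of the loglik scale) are clamped to zero: independently-optimized
  nested fits can disagree at that level on flat likelihoods (e.g. a
  constant outcome driving the beta precision to its bound) without either
  fit being wrong; larger violations still raise an error.
* Ties at the CR peak: the earliest maximal sample wins. Sample-to-ms
  conversion is index/fps × 1000; `nec_at` uses the nearest sample.
* CSV round-trips use shortest-round-trip float formatting on write and
  `float_precision="round_trip"` on read, so datasets survive the EBC-CSV
  formats bit-exactly.

## Calibration problem sizes

The acceptance suite checks each family's omnibus genotype test under its
own null at sizes chosen to be both asymptotically honest and quick on one
CPU: logistic 10 mice/group × 3 days × 12 trials; LMM 16/group × 4 days;
beta 8/group × 3 days × 5 proportions; Cox 14/group × 3 days × 4 latencies
(~14% censored); 200 replicates each, acceptance band 0.025–0.10. The
anchored LMM recovery uses 21 + 20 mice × 10 days with a 0.18 genotype
difference and day-6 group SDs of 0.17/0.26, asserting the day-6 contrast
lands in [0.06, 0.29] in ≥ 80% of 200 replicates.

## Known limitations

* The Laplace approximation can bias variance components slightly downward
  with few observations per cluster; adaptive quadrature is not implemented.
* Wald tests in the Cox frailty model condition on the profiled frailty
  variance; with genotype purely between-mouse and few mice they can run
  mildly anticonservative (the calibration test bounds this empirically).
* The beta GLMM treats the precision φ as homogeneous across cells.
* The trigger-time helper implements the subtraction rule isi − delay;
  consumers who need a different hardware constant pass their own delay.
* Supplementary/real datasets are ingested via the EBC-CSV loader with a
  column-mapping step left to the caller; no binary acquisition formats are
  parsed.
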