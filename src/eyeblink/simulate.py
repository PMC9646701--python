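"""Synthetic eyeblink-conditioning cohorts and motor-task tables.

The simulator emulates the delay eyeblink-conditioning paradigm used for
head-fixed mice: 20 daily sessions of 240 trials in 20 blocks (1 CS-only,
1 US-only, 10 paired per block, semi-randomly ordered), a 250 ms
interstimulus interval (ISI) for days 1-10 and 500 ms for days 11-20, a
stereotyped reflexive blink (UR) to the air puff, and conditioned responses
(CRs) whose probability, amplitude and peak timing evolve over training.
Eyelid position is emitted in raw arbitrary units (larger = more closed) at
a fixed sampling rate; a ground-truth table of the emitted CR events is
retained so that downstream scoring can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import lowpass_zero_phase

GENOTYPES = ("WT", "NF1_HET")
TRIAL_TYPES = ("CS_ONLY", "US_ONLY", "PAIRED")

#: block composition: 1 CS-only, 1 US-only, 10 paired trials
BLOCK = ("CS_ONLY", "US_ONLY") + ("PAIRED",) * 10


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic eyeblink cohort.

    Durations are in milliseconds, the UR gain and noise SD in raw signal
    units, CR amplitudes in normalized eye closure (NEC, fraction of a full
    blink). Defaults reproduce the standard paradigm: 300 fps video, 2000 ms
    snippets with a 500 ms pre-CS baseline, ten 250 ms-ISI days followed by
    ten 500 ms-ISI days.
    """

    n_per_genotype: int = 4
    fps: float = 300.0
    trace_ms: float = 2000.0
    pre_cs_ms: float = 500.0
    days_phase1: int = 10
    days_phase2: int = 10
    isi_phase1_ms: float = 250.0
    isi_phase2_ms: float = 500.0
    delivery_delay_ms: float = 14.0
    n_blocks: int = 20
    # acquisition dynamics (per-genotype learning-rate constants, 1/day)
    learn_rate_by_genotype: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.30, "NF1_HET": 0.45}
    )
    p_max: float = 0.90
    amp_max: float = 0.60
    carry_over: float = 0.8
    amp_jitter_sd: float = 0.10
    # CR timing: peak-time mean starts early and adapts toward the US onset
    timing_start_ms: float = 180.0
    timing_adapt_rate: float = 0.6
    timing_sd_ms: float = 50.0
    cr_rise_min_ms: float = 80.0
    cr_rise_max_ms: float = 160.0
    # UR kinematics and signal scale
    ur_gain: float = 4.0
    ur_rise_ms: float = 25.0
    ur_decay_ms: float = 250.0
    noise_sd: float = 0.05
    artifact_prob: float = 0.02
    artifact_amp: float = 2.0
    seed: int = 0
    # thresholds mirrored by the scoring stage (used for ground truth)
    onset_threshold: float = 0.02
    sustain_ms: float = 10.0

    def __post_init__(self) -> None:
        for name in ("fps", "trace_ms", "pre_cs_ms", "isi_phase1_ms", "isi_phase2_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        for name in ("artifact_prob", "carry_over"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_per_genotype < 1:
            raise ValueError("n_per_genotype must be >= 1")
        for g in GENOTYPES:
            if g not in self.learn_rate_by_genotype:
                raise ValueError(f"missing learning rate for genotype {g!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fps * self.trace_ms / 1000.0))

    @property
    def cs_onset_index(self) -> int:
        return int(round(self.fps * self.pre_cs_ms / 1000.0))

    @property
    def n_days(self) -> int:
        return self.days_phase1 + self.days_phase2

    def phase(self, day: int) -> str:
        if not 1 <= day <= self.n_days:
            raise ValueError(f"day {day} outside schedule 1..{self.n_days}")
        return "ISI250" if day <= self.days_phase1 else "ISI500"

    def isi_ms(self, day: int) -> float:
        return self.isi_phase1_ms if self.phase(day) == "ISI250" else self.isi_phase2_ms


@dataclass
class TrialRecord:
    """One trial's raw eyelid trace plus its metadata."""

    mouse_id: str
    genotype: str
    day: int
    phase: str
    block: int
    trial: int
    trial_type: str
    isi_ms: float
    fps: float
    cs_onset_index: int
    us_onset_index: int | None
    samples: np.ndarray

    @property
    def has_us(self) -> bool:
        return self.trial_type in ("US_ONLY", "PAIRED")

    @property
    def has_cs(self) -> bool:
        return self.trial_type in ("CS_ONLY", "PAIRED")


def make_schedule(n_blocks: int, seed) -> list[str]:
    """Trial-type order for one session: per 12-trial block a seeded random
    permutation of 1 CS-only + 1 US-only + 10 paired trials."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for _ in range(n_blocks):
        block = list(BLOCK)
        out.extend(np.array(block)[rng.permutation(len(block))])
    return out


def us_trigger_time(isi_ms: float, delivery_delay_ms: float) -> float:
    """Trigger time of the air puff after CS onset (ms), compensating the
    fixed delivery delay so the puff hits the cornea at the nominal ISI."""
    if delivery_delay_ms < 0:
        raise ValueError("delivery_delay_ms must be >= 0")
    if delivery_delay_ms >= isi_ms:
        raise ValueError("delivery delay must be smaller than the ISI")
    return isi_ms - delivery_delay_ms


def _phase_local_day(day: int, params: SimParams) -> tuple[int, bool]:
    """(1-based local day within phase, is_phase2)."""
    if day <= params.days_phase1:
        return day, False
    return day - params.days_phase1, True


def _saturating(day: int, k: float, ceiling: float, params: SimParams) -> float:
    """Saturating acquisition law ceiling*(1-exp(-k*d)); after the ISI switch
    the curve restarts from carry_over x its end-of-phase-1 value."""
    d, phase2 = _phase_local_day(day, params)
    if not phase2:
        return ceiling * (1.0 - np.exp(-k * d))
    start = params.carry_over * ceiling * (1.0 - np.exp(-k * params.days_phase1))
    # effective day offset so the phase-2 curve passes through `start` at d=0
    frac = min(start / ceiling, 1.0 - 1e-12)
    d0 = -np.log(1.0 - frac) / k if k > 0 else 0.0
    return ceiling * (1.0 - np.exp(-k * (d + d0)))


def cr_probability(day: int, genotype: str, params: SimParams) -> float:
    """Probability that a CS-containing trial on `day` contains a CR."""
    if genotype not in params.learn_rate_by_genotype:
        raise ValueError(f"unknown genotype {genotype!r}")
    k = params.learn_rate_by_genotype[genotype]
    return float(_saturating(day, k, params.p_max, params))


def cr_amplitude(day: int, genotype: str, params: SimParams) -> float:
    """Mean CR peak amplitude (NEC) on `day`."""
    k = params.learn_rate_by_genotype[genotype]
    return float(_saturating(day, k, params.amp_max, params))


def cr_peak_mean_ms(day: int, params: SimParams) -> float:
    """Mean CR peak latency: adapts exponentially toward the current US
    onset; phase 2 starts from the phase-1 end value (timing carries over)."""
    d, phase2 = _phase_local_day(day, params)
    r = params.timing_adapt_rate
    if not phase2:
        start, target = params.timing_start_ms, params.isi_phase1_ms
    else:
        start = params.isi_phase1_ms + (
            params.timing_start_ms - params.isi_phase1_ms
        ) * np.exp(-r * (params.days_phase1 - 1))
        target = params.isi_phase2_ms
    return float(target + (start - target) * np.exp(-r * (d - 1)))


def _hann_bump(n: int, fps: float, onset_ms: float, width_ms: float, amp: float) -> np.ndarray:
    """Raised-cosine bump with compact support [onset, onset+width], peak at
    onset + width/2."""
    t = np.arange(n) / fps * 1000.0
    x = (t - onset_ms) / width_ms
    out = np.where((x >= 0) & (x <= 1), 0.5 * amp * (1.0 - np.cos(2 * np.pi * x)), 0.0)
    return out


def _ur_template(params: SimParams, n: int, us_index: int) -> np.ndarray:
    """Stereotyped UR: smooth rise over ~ur_rise_ms to ur_gain, exponential
    decay with time constant ur_decay_ms, starting at the US impact sample."""
    t = np.arange(n - us_index) / params.fps * 1000.0
    shape = (1.0 - np.exp(-((t / params.ur_rise_ms) ** 2))) * np.exp(-t / params.ur_decay_ms)
    shape = shape / shape.max()
    out = np.zeros(n)
    out[us_index:] = params.ur_gain * shape
    return out


def _soft_cap(x: np.ndarray, gain: float) -> np.ndarray:
    """Soft saturation above the full-blink level: identity up to `gain`,
    smooth compression toward 1.05*gain above it."""
    cap = 1.05 * gain
    over = x > gain
    out = x.copy()
    out[over] = gain + (cap - gain) * np.tanh((x[over] - gain) / (cap - gain))
    return out


def _scan_threshold_onset(nec: np.ndarray, peak_idx: int, cs_idx: int,
                          threshold: float, sustain_n: int) -> int | None:
    """Start of the contiguous >=threshold run containing the peak (None if
    the run is shorter than sustain_n samples)."""
    if nec[peak_idx] < threshold:
        return None
    i = peak_idx
    while i > cs_idx and nec[i - 1] >= threshold:
        i -= 1
    j = peak_idx
    while j + 1 < len(nec) and nec[j + 1] >= threshold:
        j += 1
    if j - i + 1 < sustain_n:
        return None
    return i


_FACTOR_MEMO: dict[tuple, float] = {}


def clean_session_factor(params: SimParams, isi_ms: float) -> float:
    """Normalization factor of a noise-free session: peak of the band-limited
    UR template in the post-US window (identical URs average to themselves)."""
    key = (params.fps, params.trace_ms, params.pre_cs_ms, params.ur_gain,
           params.ur_rise_ms, params.ur_decay_ms, isi_ms)
    if key in _FACTOR_MEMO:
        return _FACTOR_MEMO[key]
    n = params.n_samples
    us_idx = params.cs_onset_index + int(round(params.fps * isi_ms / 1000.0))
    ur = _ur_template(params, n, us_idx)
    filt = lowpass_zero_phase(ur, params.fps)
    _FACTOR_MEMO[key] = float(filt[us_idx:].max())
    return _FACTOR_MEMO[key]


def simulate_trial(meta: TrialRecord, params: SimParams, rng: np.random.Generator,
                   *, truth: dict | None = None) -> TrialRecord:
    """Fill `meta.samples` with a simulated raw eyelid trace.

    The trace is additive: Gaussian baseline noise, an optional pre-CS blink
    artifact, a raised-cosine CR bump on CS-containing trials (present with
    the day's CR probability), and the stereotyped UR on US-containing
    trials, soft-capped at full closure. When a dict is passed as `truth` it
    is filled with the emitted ground truth (CR presence per the scoring
    criteria, band-limited onset/peak samples, amplitude, artifact flag).
    """
    n = params.n_samples
    cs_idx = meta.cs_onset_index
    trace = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)

    artifact = False
    if params.artifact_prob > 0 and rng.random() < params.artifact_prob:
        artifact = True
        center = rng.uniform(100.0, params.pre_cs_ms - 100.0)
        trace += _hann_bump(n, params.fps, center - 50.0, 100.0, params.artifact_amp)

    cr_emitted = False
    cr_component = np.zeros(n)
    amp = peak_ms = onset_support_ms = np.nan
    if meta.has_cs:
        p = cr_probability(meta.day, meta.genotype, params)
        if rng.random() < p:
            cr_emitted = True
            amp = cr_amplitude(meta.day, meta.genotype, params)
            if params.amp_jitter_sd > 0:
                amp *= float(np.exp(rng.normal(0.0, params.amp_jitter_sd)))
            amp = min(amp, 0.95)
            peak_ms = float(np.clip(
                rng.normal(cr_peak_mean_ms(meta.day, params), params.timing_sd_ms),
                120.0, 950.0))
            rise = rng.uniform(params.cr_rise_min_ms, params.cr_rise_max_ms)
            # keep the bump's support inside the post-CS region (>= 55 ms)
            rise = min(rise, peak_ms - 55.0)
            onset_support_ms = peak_ms - rise
            cr_component = _hann_bump(
                n, params.fps, params.pre_cs_ms + onset_support_ms, 2 * rise, amp)

    ur = _ur_template(params, n, meta.us_onset_index) if meta.has_us else 0.0
    raw = trace + cr_component * params.ur_gain + ur
    raw = _soft_cap(raw, params.ur_gain)
    meta.samples = raw

    if truth is not None:
        truth.update(
            mouse_id=meta.mouse_id, genotype=meta.genotype, day=meta.day,
            phase=meta.phase, block=meta.block, trial=meta.trial,
            trial_type=meta.trial_type, isi_ms=meta.isi_ms,
            artifact=artifact, cr_emitted=cr_emitted,
            cr_amp=amp, cr_peak_support_ms=peak_ms,
            cr_onset_support_ms=onset_support_ms,
            cr_present=False, onset_ms=np.nan, peak_ms=np.nan, peak_nec=np.nan,
        )
    return meta


def _truth_scan(truth: dict, params: SimParams, factor: float) -> None:
    """Finalize one trial's ground truth: scan the band-limited clean CR
    component, normalized by the session truth factor, with the scoring
    definitions (amplitude > 0.1 NEC, onset in [50, 500], peak in
    [100, 1000] ms, sustained 0.02-NEC crossing)."""
    if not truth["cr_emitted"]:
        return
    n = params.n_samples
    cs_idx = params.cs_onset_index
    peak_ms = truth["cr_peak_support_ms"]
    onset_support = truth["cr_onset_support_ms"]
    comp = _hann_bump(n, params.fps, params.pre_cs_ms + onset_support,
                      2 * (peak_ms - onset_support), truth["cr_amp"])
    nec = lowpass_zero_phase(comp * params.ur_gain, params.fps) / factor
    win_end = min(cs_idx + int(round(params.fps * 1.0)), n - 1)  # 1000 ms window
    seg = nec[: win_end + 1].copy()
    seg[: cs_idx + 1] = -np.inf
    pk = int(np.argmax(seg))
    sustain_n = int(round(params.sustain_ms * params.fps / 1000.0))
    onset_idx = _scan_threshold_onset(
        nec, pk, cs_idx, params.onset_threshold, sustain_n)
    pk_ms = (pk - cs_idx) / params.fps * 1000.0
    on_ms = None if onset_idx is None else (onset_idx - cs_idx) / params.fps * 1000.0
    peak_nec = float(nec[pk])
    is_cr = (
        peak_nec > 0.1
        and on_ms is not None and 50.0 <= on_ms <= 500.0
        and 100.0 <= pk_ms <= 1000.0
    )
    truth.update(
        cr_present=bool(is_cr),
        onset_ms=np.nan if on_ms is None else on_ms,
        peak_ms=pk_ms, peak_nec=peak_nec,
    )


def _truth_session_factor(session_truth: list[dict], params: SimParams,
                          isi_ms: float) -> float:
    """Noise-free normalization factor of one simulated session: average the
    clean components (CR bump + UR, soft-capped) of its US-containing
    trials, filter, baseline-align, and take the post-US maximum. Mirrors
    the definitional rule independently of the scoring implementation."""
    n = params.n_samples
    us_idx = params.cs_onset_index + int(round(params.fps * isi_ms / 1000.0))
    ur = _ur_template(params, n, us_idx)
    total = np.zeros(n)
    count = 0
    for tr in session_truth:
        if tr["trial_type"] == "CS_ONLY":
            continue
        comp = ur.copy()
        if tr["cr_emitted"]:
            onset_support = tr["cr_onset_support_ms"]
            comp = comp + params.ur_gain * _hann_bump(
                n, params.fps, params.pre_cs_ms + onset_support,
                2 * (tr["cr_peak_support_ms"] - onset_support), tr["cr_amp"])
        total += _soft_cap(comp, params.ur_gain)
        count += 1
    avg = lowpass_zero_phase(total / count, params.fps)
    pre = avg[params.cs_onset_index - int(round(params.fps * params.pre_cs_ms
                                                / 1000.0)): params.cs_onset_index]
    avg = avg - np.median(pre)
    return float(avg[us_idx:].max())


def _mouse_ids(params: SimParams) -> list[tuple[str, str]]:
    out = []
    for g in GENOTYPES:
        for i in range(params.n_per_genotype):
            out.append((f"{g}_{i + 1:02d}", g))
    return out


def simulate_session(mouse_id: str, genotype: str, day: int, params: SimParams,
                     rng: np.random.Generator,
                     truth_rows: list[dict] | None = None) -> list[TrialRecord]:
    """One mouse-day session: scheduled trial types, simulated traces."""
    schedule = make_schedule(params.n_blocks, rng)
    isi = params.isi_ms(day)
    us_idx = params.cs_onset_index + int(round(params.fps * isi / 1000.0))
    trials = []
    session_truth: list[dict] = []
    for t, ttype in enumerate(schedule, start=1):
        meta = TrialRecord(
            mouse_id=mouse_id, genotype=genotype, day=day, phase=params.phase(day),
            block=(t - 1) // len(BLOCK) + 1, trial=t, trial_type=ttype,
            isi_ms=isi, fps=params.fps, cs_onset_index=params.cs_onset_index,
            us_onset_index=us_idx if ttype != "CS_ONLY" else None,
            samples=np.empty(0),
        )
        truth: dict | None = {} if truth_rows is not None else None
        simulate_trial(meta, params, rng, truth=truth)
        if truth is not None:
            session_truth.append(truth)
        trials.append(meta)
    if truth_rows is not None:
        factor = _truth_session_factor(session_truth, params, isi)
        for tr in session_truth:
            _truth_scan(tr, params, factor)
        truth_rows.extend(session_truth)
    return trials


def simulate_cohort(params: SimParams) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Full cohort: n_per_genotype mice per genotype x all training days.

    Returns the trial records and the ground-truth table (one row per trial,
    keyed by mouse/day/trial). Each mouse gets its own child RNG stream
    spawned from the root seed, so cohorts are reproducible and insensitive
    to mouse ordering.
    """
    root = np.random.SeedSequence(params.seed)
    mice = _mouse_ids(params)
    streams = root.spawn(len(mice))
    trials: list[TrialRecord] = []
    truth_rows: list[dict] = []
    for (mouse, genotype), ss in zip(mice, streams):
        rng = np.random.default_rng(ss)
        for day in range(1, params.n_days + 1):
            trials.extend(
                simulate_session(mouse, genotype, day, params, rng, truth_rows))
    return trials, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# motor-task tables


@dataclass(frozen=True)
class MotorParams:
    """Generating parameters of the four motor-task tables.

    Defaults emulate the published task structures: 5 x 42 ladder runs with a
    two-part (clean sweep vs mixed) step-proportion law, 4 x 4 rotarod trials
    right-censored at 300 s (plus an excluded 80 RPM sub-experiment), two
    crossing times per beam width, and 4 x 2 grip-force pulls around 90 N.
    """

    n_per_genotype: int = 8
    # ladder
    ladder_days: int = 5
    ladder_trials: int = 42
    clean_sweep_p: float = 0.16
    ladder_mu: float = 0.75          # mean correct-step proportion, mixed trials
    ladder_phi: float = 12.0         # beta precision
    ladder_day_slope: float = 0.15   # logit/day improvement in clean-sweep odds
    # rotarod
    rotarod_days: int = 4
    rotarod_trials: int = 4
    rotarod_log_mean: float = np.log(150.0)
    rotarod_log_day_slope: float = 0.25
    rotarod_log_sd: float = 0.45
    rotarod_cap_s: float = 300.0
    include_80rpm: bool = True
    # beam
    beam_log_mean_6mm: float = np.log(8.0)
    beam_width_effect: float = -0.5  # log-time difference 12 mm vs 6 mm
    beam_log_sd: float = 0.25
    # grip
    grip_days: int = 4
    grip_reps: int = 2
    grip_log_mean: float = np.log(90.0)
    grip_log_sd: float = 0.12
    # shared per-mouse random-intercept SDs (log/logit scale)
    mouse_sd: float = 0.25
    seed: int = 0


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_motor_tables(params: MotorParams | None = None,
                          rng: np.random.Generator | None = None
                          ) -> dict[str, pd.DataFrame]:
    """Ladder, rotarod, beam and grip tables with per-mouse random effects."""
    params = params or MotorParams()
    rng = rng or np.random.default_rng(params.seed)
    mice = [(f"{g}_{i + 1:02d}", g)
            for g in GENOTYPES for i in range(params.n_per_genotype)]

    ladder_rows, rot_rows, beam_rows, grip_rows = [], [], [], []
    for mouse, geno in mice:
        u_lad, u_rot, u_beam, u_grip = rng.normal(0.0, params.mouse_sd, 4)
        # ladder: two-part law per trial
        for day in range(1, params.ladder_days + 1):
            if params.clean_sweep_p >= 1.0:
                p_clean = 1.0
            else:
                logit_clean = (np.log(params.clean_sweep_p / (1 - params.clean_sweep_p))
                               + params.ladder_day_slope * (day - 1) + u_lad)
                p_clean = _invlogit(logit_clean)
            mu = _invlogit(np.log(params.ladder_mu / (1 - params.ladder_mu)) + u_lad)
            a, b = mu * params.ladder_phi, (1 - mu) * params.ladder_phi
            for trial in range(1, params.ladder_trials + 1):
                if rng.random() < p_clean:
                    prop = 1.0
                else:
                    prop = float(np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6))
                ladder_rows.append(dict(mouse=mouse, genotype=geno, day=day,
                                        trial=trial, prop_correct=prop))
        # rotarod: lognormal latency improving over days, censored at the cap
        for day in range(1, params.rotarod_days + 1):
            for trial in range(1, params.rotarod_trials + 1):
                lat = float(np.exp(rng.normal(
                    params.rotarod_log_mean
                    + params.rotarod_log_day_slope * (day - 1) + u_rot,
                    params.rotarod_log_sd)))
                censored = lat >= params.rotarod_cap_s
                rot_rows.append(dict(
                    mouse=mouse, genotype=geno, day=day, trial=trial,
                    rpm_condition=40,
                    latency_s=min(lat, params.rotarod_cap_s), censored=censored))
                # excluded sub-experiment: higher speed on later trials/days
                if (params.include_80rpm and day >= 3 and trial >= 3):
                    lat80 = float(np.exp(rng.normal(
                        params.rotarod_log_mean - 0.5 + u_rot, params.rotarod_log_sd)))
                    rot_rows.append(dict(
                        mouse=mouse, genotype=geno, day=day, trial=trial,
                        rpm_condition=80,
                        latency_s=min(lat80, params.rotarod_cap_s),
                        censored=lat80 >= params.rotarod_cap_s))
        # beam: two crossings per width, day-3 measurement only
        for width in (6, 12):
            for rep in (1, 2):
                logt = rng.normal(
                    params.beam_log_mean_6mm
                    + (params.beam_width_effect if width == 12 else 0.0) + u_beam,
                    params.beam_log_sd)
                beam_rows.append(dict(mouse=mouse, genotype=geno, width_mm=width,
                                      rep=rep, time_s=float(np.exp(logt))))
        # grip: two pulls per day
        for day in range(1, params.grip_days + 1):
            for rep in range(1, params.grip_reps + 1):
                logf = rng.normal(params.grip_log_mean + u_grip, params.grip_log_sd)
                grip_rows.append(dict(mouse=mouse, genotype=geno, day=day,
                                      rep=rep, force_n=float(np.exp(logf))))

    return {
        "ladder": pd.DataFrame(ladder_rows),
        "rotarod": pd.DataFrame(rot_rows),
        "beam": pd.DataFrame(beam_rows),
        "grip": pd.DataFrame(grip_rows),
    }
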