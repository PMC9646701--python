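"""Raw eyelid traces -> valid, baseline-aligned, UR-normalized NEC traces.

Scoring of conditioned eyeblinks requires traces on a common scale: 0 for the
fully open eye at baseline, 1 for a full blink. Each trial is low-pass
filtered (zero-phase Butterworth, 50 Hz), its 500 ms pre-CS baseline median
is subtracted, trials with large pre-CS activity (> 7x the interquartile
range) are flagged invalid, and every trace is divided by the session's
normalization factor: the peak of the averaged unconditioned response (UR)
across the session's valid US-containing trials.

Processing order is filter -> align -> validity -> normalize, so that
above-band sensor spikes cannot trigger the validity exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

DEFAULT_CUTOFF_HZ = 50.0
DEFAULT_ORDER = 4
DEFAULT_IQR_K = 7.0


@dataclass
class NormalizedTrial:
    """A filtered, aligned, UR-normalized trial in NEC units."""

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
    nec: np.ndarray
    valid: bool
    norm_factor: float
    baseline_offset: float

    @property
    def is_cs_only(self) -> bool:
        return self.trial_type == "CS_ONLY"


class SessionUnusableError(ValueError):
    """Session has no valid US-containing trials or no reflexive closure."""


def lowpass_zero_phase(samples: np.ndarray, fps: float,
                       cutoff: float = DEFAULT_CUTOFF_HZ,
                       order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    DC gain is 1 and the output has the input's length. Applying the filter
    forward and in reverse cancels the phase response, so symmetric features
    keep their position (no latency bias in onset/peak estimates).
    """
    samples = np.asarray(samples, dtype=float)
    if cutoff >= fps / 2.0:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {fps / 2.0} Hz")
    if samples.ndim != 1:
        raise ValueError("expected a 1-D series")
    b, a = signal.butter(order, cutoff, btype="low", fs=fps)
    padlen = 3 * max(len(a), len(b))
    if len(samples) <= padlen:
        raise ValueError(f"series of length {len(samples)} too short to filter "
                         f"(need > {padlen} samples)")
    return signal.filtfilt(b, a, samples)


def pre_cs_window(cs_onset_index: int, fps: float, pre_cs_ms: float = 500.0
                  ) -> slice:
    n_pre = int(round(fps * pre_cs_ms / 1000.0))
    if cs_onset_index < n_pre:
        raise ValueError(
            f"only {cs_onset_index} samples before CS onset, need {n_pre}")
    return slice(cs_onset_index - n_pre, cs_onset_index)


def baseline_align(samples: np.ndarray, cs_onset_index: int, fps: float,
                   pre_cs_ms: float = 500.0) -> tuple[np.ndarray, float]:
    """Subtract the median of the pre-CS baseline window.

    The median (rather than the mean) keeps isolated pre-CS blinks from
    shifting the baseline. Returns (aligned series, offset subtracted).
    """
    samples = np.asarray(samples, dtype=float)
    win = pre_cs_window(cs_onset_index, fps, pre_cs_ms)
    offset = float(np.median(samples[win]))
    return samples - offset, offset


def trial_validity(aligned: np.ndarray, cs_onset_index: int, fps: float,
                   k: float = DEFAULT_IQR_K, pre_cs_ms: float = 500.0) -> bool:
    """Validity flag: pre-CS activity must stay within k x IQR of the median.

    The IQR is computed on the trial's own pre-CS samples. A trial is invalid
    iff max |pre - median(pre)| > k * IQR(pre); a flat baseline (zero IQR and
    zero deviation) is valid. Flatness is judged against a small tolerance
    relative to the trace's overall scale (1e-5 x max |aligned|), so that
    numerically-negligible filter residue on an otherwise silent baseline
    does not trip the rule.
    """
    aligned = np.asarray(aligned, dtype=float)
    pre = aligned[pre_cs_window(cs_onset_index, fps, pre_cs_ms)]
    med = np.median(pre)
    dev = np.max(np.abs(pre - med))
    q75, q25 = np.percentile(pre, [75, 25])
    iqr = q75 - q25
    eps = 1e-5 * np.max(np.abs(aligned), initial=0.0)
    if dev <= eps:
        return True
    if iqr <= eps:
        return False
    return not dev > k * iqr


def session_ur_factor(trials, *, pre_cs_ms: float = 500.0,
                      cutoff: float = DEFAULT_CUTOFF_HZ,
                      order: int = DEFAULT_ORDER,
                      k: float = DEFAULT_IQR_K,
                      ur_source: str = "all_us") -> float:
    """Session normalization factor from the averaged unconditioned response.

    Filters and baseline-aligns every valid US-containing trial, averages
    them sample-wise, and returns the maximum of the average over the window
    from US impact to trace end (so CRs in paired trials cannot inflate the
    factor). `ur_source` selects which trials contribute: "all_us" (US-only
    and paired, the default) or "us_only".
    """
    if ur_source not in ("all_us", "us_only"):
        raise ValueError("ur_source must be 'all_us' or 'us_only'")
    wanted = ("US_ONLY",) if ur_source == "us_only" else ("US_ONLY", "PAIRED")
    stack, us_indices = [], []
    for t in trials:
        if t.trial_type not in wanted or t.us_onset_index is None:
            continue
        filt = lowpass_zero_phase(t.samples, t.fps, cutoff, order)
        aligned, _ = baseline_align(filt, t.cs_onset_index, t.fps, pre_cs_ms)
        if not trial_validity(aligned, t.cs_onset_index, t.fps, k, pre_cs_ms):
            continue
        stack.append(aligned)
        us_indices.append(t.us_onset_index)
    if not stack:
        raise SessionUnusableError("no valid US-containing trials in session")
    avg = np.mean(stack, axis=0)
    factor = float(avg[min(us_indices):].max())
    if factor <= 0:
        raise SessionUnusableError(
            "no reflexive eyelid closure after US delivery (factor <= 0)")
    return factor


def normalize_session(trials, *, pre_cs_ms: float = 500.0,
                      cutoff: float = DEFAULT_CUTOFF_HZ,
                      order: int = DEFAULT_ORDER,
                      k: float = DEFAULT_IQR_K,
                      ur_source: str = "all_us") -> list[NormalizedTrial]:
    """Filter, align, flag and normalize every trial of one session.

    Invalid trials are flagged but still normalized (they stay available for
    QC); downstream scoring excludes them. Raises SessionUnusableError when
    the session has no usable UR.
    """
    factor = session_ur_factor(trials, pre_cs_ms=pre_cs_ms, cutoff=cutoff,
                               order=order, k=k, ur_source=ur_source)
    out = []
    for t in trials:
        filt = lowpass_zero_phase(t.samples, t.fps, cutoff, order)
        aligned, offset = baseline_align(filt, t.cs_onset_index, t.fps, pre_cs_ms)
        valid = trial_validity(aligned, t.cs_onset_index, t.fps, k, pre_cs_ms)
        out.append(NormalizedTrial(
            mouse_id=t.mouse_id, genotype=t.genotype, day=t.day, phase=t.phase,
            block=t.block, trial=t.trial, trial_type=t.trial_type,
            isi_ms=t.isi_ms, fps=t.fps, cs_onset_index=t.cs_onset_index,
            us_onset_index=t.us_onset_index, nec=aligned / factor, valid=valid,
            norm_factor=factor, baseline_offset=offset))
    return out
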