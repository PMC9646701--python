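"""Conditioned-response detection and per-session eyeblink outcomes.

A conditioned response (CR) is an eyelid movement larger than 0.1 NEC whose
onset latency falls in [50, 500] ms and whose peak latency falls in
[100, 1000] ms after CS onset (closed intervals; boundary samples count).
Conditioned behavior is scored on valid CS-only trials, which show the full
kinetic profile of the CR without the UR riding on top of it.

Session outcomes: the CR proportion, the mean NEC at 250 and at 500 ms after
CS onset (over valid CS-only trials, CR-present or not), mean onset/peak
latencies (CR-present trials only), and the proportion of "perfectly timed"
CRs, whose peak falls within +/-50 ms of the omitted US onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NormalizedTrial

AMP_THRESHOLD = 0.1
ONSET_WINDOW_MS = (50.0, 500.0)
PEAK_WINDOW_MS = (100.0, 1000.0)
PERFECT_HALF_WINDOW_MS = 50.0


@dataclass
class CRResult:
    mouse_id: str
    genotype: str
    day: int
    phase: str
    trial: int
    isi_ms: float
    is_cr: bool
    onset_ms: float   # nan when no CR
    peak_ms: float
    peak_nec: float
    perfectly_timed: bool


def detect_cr(trial: NormalizedTrial, *, onset_threshold: float = 0.02,
              sustain_ms: float = 10.0, amp_threshold: float = AMP_THRESHOLD,
              onset_window_ms=ONSET_WINDOW_MS,
              peak_window_ms=PEAK_WINDOW_MS) -> CRResult:
    """Score one valid CS-only trial for a CR.

    The peak is the earliest maximal sample of the NEC trace in the 1000 ms
    window after CS onset. The onset is the start of the contiguous run of
    samples >= onset_threshold that contains the peak, required to last at
    least sustain_ms. A CR is present iff the peak amplitude exceeds
    amp_threshold and both latencies fall inside their windows (closed).
    Latencies are reported at sample resolution, in ms after CS onset.
    """
    if not trial.valid:
        raise ValueError("detect_cr requires a valid trial")
    if not trial.is_cs_only:
        raise ValueError("detect_cr scores CS-only trials only")
    nec = np.asarray(trial.nec, dtype=float)
    fps, cs = trial.fps, trial.cs_onset_index
    win_end = min(cs + int(round(fps * peak_window_ms[1] / 1000.0)), len(nec) - 1)
    seg = nec[cs + 1: win_end + 1]
    if seg.size == 0:
        raise ValueError("trace ends before the CR peak window")
    peak_idx = cs + 1 + int(np.argmax(seg))  # argmax takes the earliest tie
    peak_nec = float(nec[peak_idx])
    peak_ms = (peak_idx - cs) / fps * 1000.0

    onset_ms = np.nan
    if nec[peak_idx] >= onset_threshold:
        i = peak_idx
        while i > cs and nec[i - 1] >= onset_threshold:
            i -= 1
        j = peak_idx
        while j + 1 < len(nec) and nec[j + 1] >= onset_threshold:
            j += 1
        sustain_n = int(round(sustain_ms * fps / 1000.0))
        if j - i + 1 >= sustain_n:
            onset_ms = (i - cs) / fps * 1000.0

    is_cr = bool(
        peak_nec > amp_threshold
        and np.isfinite(onset_ms)
        and onset_window_ms[0] <= onset_ms <= onset_window_ms[1]
        and peak_window_ms[0] <= peak_ms <= peak_window_ms[1]
    )
    return CRResult(
        mouse_id=trial.mouse_id, genotype=trial.genotype, day=trial.day,
        phase=trial.phase, trial=trial.trial, isi_ms=trial.isi_ms,
        is_cr=is_cr,
        onset_ms=onset_ms if is_cr else np.nan,
        peak_ms=peak_ms if is_cr else np.nan,
        peak_nec=peak_nec,
        perfectly_timed=is_cr and perfectly_timed(peak_ms, trial.isi_ms),
    )


def perfectly_timed(peak_ms: float, isi_ms: float,
                    half_window_ms: float = PERFECT_HALF_WINDOW_MS) -> bool:
    """True iff the CR peak falls within +/- half_window_ms of the omitted
    US onset (closed interval)."""
    return isi_ms - half_window_ms <= peak_ms <= isi_ms + half_window_ms


def nec_at(nec: np.ndarray, t_ms: float, fps: float, cs_onset_index: int) -> float:
    """NEC value at t_ms after CS onset (nearest sample)."""
    idx = int(round(cs_onset_index + t_ms * fps / 1000.0))
    nec = np.asarray(nec, dtype=float)
    if not 0 <= idx < len(nec):
        raise ValueError(f"t={t_ms} ms falls outside the trace")
    return float(nec[idx])


def summarize_session(trials: list[NormalizedTrial],
                      results: list[CRResult] | None = None,
                      include_paired_nec: bool = False,
                      **detect_kwargs) -> dict:
    """Per-mouse-per-day summary over valid CS-only trials.

    When `results` is omitted, detect_cr is run on every valid CS-only trial.
    With zero valid CS-only trials a summary row is still emitted (metrics
    NaN, n_cs_only_valid = 0) so exclusions stay visible downstream.
    `include_paired_nec` additionally averages valid paired trials into the
    NEC-at-time metrics where the time point falls strictly before their US
    impact (their post-US samples are UR-contaminated and never used).
    """
    if not trials:
        raise ValueError("empty session")
    head = trials[0]
    cs_only = [t for t in trials if t.is_cs_only]
    valid = [t for t in cs_only if t.valid]
    n_invalid = sum(1 for t in trials if not t.valid)
    if results is None:
        results = [detect_cr(t, **detect_kwargs) for t in valid]
    elif len(results) != len(valid):
        raise ValueError("results must match the valid CS-only trials")

    out = dict(
        mouse_id=head.mouse_id, genotype=head.genotype, day=head.day,
        phase=head.phase, isi_ms=head.isi_ms,
        n_cs_only_valid=len(valid), n_invalid=n_invalid,
        cr_proportion=np.nan, nec_250=np.nan, nec_500=np.nan,
        mean_onset_ms=np.nan, mean_peak_ms=np.nan, perfect_proportion=np.nan,
    )
    if not valid:
        return out
    out["cr_proportion"] = sum(r.is_cr for r in results) / len(valid)

    def nec_pool(t_ms):
        pool = list(valid)
        if include_paired_nec:
            pool += [t for t in trials
                     if t.trial_type == "PAIRED" and t.valid
                     and t_ms < t.isi_ms]
        return float(np.mean(
            [nec_at(t.nec, t_ms, t.fps, t.cs_onset_index) for t in pool]))

    out["nec_250"] = nec_pool(250.0)
    out["nec_500"] = nec_pool(500.0)
    crs = [r for r in results if r.is_cr]
    if crs:
        out["mean_onset_ms"] = float(np.mean([r.onset_ms for r in crs]))
        out["mean_peak_ms"] = float(np.mean([r.peak_ms for r in crs]))
    out["perfect_proportion"] = sum(r.perfectly_timed for r in results) / len(valid)
    return out


_METRICS = ("cr_proportion", "nec_250", "nec_500",
            "mean_onset_ms", "mean_peak_ms", "perfect_proportion")


def aggregate_cohort(summaries: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-day-per-genotype table: mean, SD, median and quartiles of
    each session metric across mice (one row per day x genotype)."""
    if len(summaries) == 0:
        raise ValueError("no session summaries to aggregate")
    rows = []
    for (day, geno), grp in summaries.groupby(["day", "genotype"], sort=True):
        row = dict(day=day, genotype=geno, n_mice=grp["mouse_id"].nunique())
        for m in _METRICS:
            vals = grp[m].dropna().to_numpy()
            if vals.size == 0:
                row.update({f"{m}_mean": np.nan, f"{m}_sd": np.nan,
                            f"{m}_median": np.nan, f"{m}_q25": np.nan,
                            f"{m}_q75": np.nan})
                continue
            row[f"{m}_mean"] = float(np.mean(vals))
            # SD across mice; undefined (NaN) for a single mouse
            row[f"{m}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            row[f"{m}_median"] = float(med)
            row[f"{m}_q25"] = float(q25)
            row[f"{m}_q75"] = float(q75)
        rows.append(row)
    return pd.DataFrame(rows)


def score_cohort(trials, preprocess_kwargs: dict | None = None, **detect_kwargs):
    """Normalize and score a cohort of TrialRecords.

    Groups trials into (mouse, day) sessions, normalizes each, runs CR
    detection on valid CS-only trials and summarizes. Returns (per-trial CR
    table, per-session summary table, QC table). Sessions without a usable UR
    are skipped and reported in the QC table with reason "no_ur".
    """
    from .preprocess import SessionUnusableError, normalize_session

    preprocess_kwargs = preprocess_kwargs or {}
    sessions: dict[tuple, list] = {}
    for t in trials:
        sessions.setdefault((t.mouse_id, t.day), []).append(t)

    cr_rows, summary_rows, qc_rows = [], [], []
    for (mouse, day), sess in sorted(sessions.items()):
        try:
            normed = normalize_session(sess, **preprocess_kwargs)
        except SessionUnusableError as exc:
            qc_rows.append(dict(mouse_id=mouse, day=day, usable=False,
                                reason=str(exc), norm_factor=np.nan,
                                n_valid=0, n_invalid=len(sess)))
            continue
        valid_cs = [t for t in normed if t.is_cs_only and t.valid]
        results = [detect_cr(t, **detect_kwargs) for t in valid_cs]
        cr_rows.extend(r.__dict__ for r in results)
        summary_rows.append(summarize_session(normed, results))
        qc_rows.append(dict(
            mouse_id=mouse, day=day, usable=True, reason="",
            norm_factor=normed[0].norm_factor,
            n_valid=sum(t.valid for t in normed),
            n_invalid=sum(not t.valid for t in normed)))
    return (pd.DataFrame(cr_rows), pd.DataFrame(summary_rows),
            pd.DataFrame(qc_rows))
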