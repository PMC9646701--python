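"""Brute-force definitional reimplementations used as independent oracles.

Each function applies the scoring definitions by direct scan over plain
Python loops, sharing no code with the package implementation.
"""

import numpy as np


def brute_detect(nec, fps, cs_idx, onset_threshold=0.02, sustain_ms=10.0,
                 amp_threshold=0.1):
    """Definitional CR scan: earliest argmax in (cs, cs+1000 ms], onset =
    start of the sustained >= threshold run containing the peak, closed
    latency windows [50, 500] and [100, 1000] ms."""
    nec = list(nec)
    win_end = min(cs_idx + int(round(fps * 1.0)), len(nec) - 1)
    peak_idx, peak_val = None, -np.inf
    for i in range(cs_idx + 1, win_end + 1):
        if nec[i] > peak_val:
            peak_idx, peak_val = i, nec[i]
    peak_ms = (peak_idx - cs_idx) / fps * 1000.0
    onset_ms = None
    if peak_val >= onset_threshold:
        i = peak_idx
        while i > cs_idx and nec[i - 1] >= onset_threshold:
            i -= 1
        j = peak_idx
        while j + 1 < len(nec) and nec[j + 1] >= onset_threshold:
            j += 1
        if (j - i + 1) >= int(round(sustain_ms * fps / 1000.0)):
            onset_ms = (i - cs_idx) / fps * 1000.0
    is_cr = (peak_val > amp_threshold and onset_ms is not None
             and 50.0 <= onset_ms <= 500.0 and 100.0 <= peak_ms <= 1000.0)
    return is_cr, onset_ms, peak_ms, peak_val


def brute_validity(aligned, pre_n, k=7.0):
    """Definitional pre-CS activity rule on an aligned trace whose pre-CS
    window is the first pre_n samples."""
    pre = sorted(aligned[:pre_n])
    n = len(pre)
    med = np.median(pre)
    dev = max(abs(v - med) for v in aligned[:pre_n])
    q75 = np.percentile(pre, 75)
    q25 = np.percentile(pre, 25)
    iqr = q75 - q25
    eps = 1e-5 * max(abs(v) for v in aligned) if len(aligned) else 0.0
    if dev <= eps:
        return True
    if iqr <= eps:
        return False
    return dev <= k * iqr


def brute_ur_factor(traces, us_indices):
    """Average the given aligned US-trial traces sample-wise and return the
    max over the window starting at the earliest US impact index."""
    n = len(traces[0])
    avg = [sum(tr[i] for tr in traces) / len(traces) for i in range(n)]
    start = min(us_indices)
    return max(avg[start:])
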