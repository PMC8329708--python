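"""Threshold-based and template-matching spike detection.

Detection runs on the locally normalized differential signal. A robust
estimate of the noise standard deviation, ``n = MAD(x) * 1.4826``, sets the
threshold ``Thr = 4 * n``; spikes are negative-going troughs (local minima
below ``-Thr``). A second, template-matching pass computes the sliding
Pearson correlation of each unit's median spike shape with the signal and
repeats the detection on the correlation trace, recovering spikes whose
shape is intact but whose amplitude dipped below the threshold during noisy
episodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SpikeEvent",
    "MAD_TO_SD",
    "WAVEFORM_LEN",
    "robust_noise",
    "detection_threshold",
    "detect_spikes",
    "extract_waveforms",
    "median_template",
    "sliding_pearson",
    "template_matching_detect",
    "match_events",
    "detection_f1",
]

#: Consistency constant relating the MAD to the standard deviation of a
#: Gaussian: 1 / PHI^-1(0.75).
MAD_TO_SD = 1.4826

#: Waveform window: 1.44 ms at 20 kHz is 28.8 samples, rounded up to the odd
#: 29 so the trough sits exactly at the center (14 + trough + 14).
WAVEFORM_LEN = 29

#: Minimum separation between detected troughs, as a fraction of the window.
MIN_SEPARATION_S = 0.00035


@dataclass
class SpikeEvent:
    """A detected spike."""

    t_s: float
    sample_index: int
    trough_amplitude: float  # signal value at the trough, normalized units
    waveform: np.ndarray | None = None  # WAVEFORM_LEN samples, trough-centered
    origin: str = "threshold"  # "threshold" | "template"


def robust_noise(x: np.ndarray) -> float:
    """Robust noise standard deviation: ``median(|x - median(x)|) * 1.4826``."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.median(np.abs(x - np.median(x))) * MAD_TO_SD)


def detection_threshold(x: np.ndarray, multiplier: float = 4.0) -> float:
    """Detection threshold ``Thr = multiplier * robust_noise(x)``."""
    return multiplier * robust_noise(x)


def detect_spikes(
    x: np.ndarray,
    sample_rate_hz: float = 20_000.0,
    multiplier: float = 4.0,
    min_separation_s: float = MIN_SEPARATION_S,
    positive_peaks: bool = False,
) -> list:
    """Threshold detection of negative troughs.

    Candidates are local minima of ``x`` below ``-Thr`` with
    ``Thr = multiplier * robust_noise(x)``; troughs closer than
    ``min_separation_s`` keep only the deeper one. ``positive_peaks`` flips
    the sign convention for positive-going units.
    """
    x = np.asarray(x, dtype=float)
    if positive_peaks:
        x = -x
    thr = detection_threshold(x, multiplier)
    if thr == 0:
        raise ValueError("degenerate signal: robust noise estimate is zero")
    distance = max(int(round(min_separation_s * sample_rate_hz)), 1)
    idx, _ = find_peaks(-x, height=thr, distance=distance)
    sign = -1.0 if positive_peaks else 1.0
    return [
        SpikeEvent(
            t_s=i / sample_rate_hz,
            sample_index=int(i),
            trough_amplitude=sign * float(x[i]),
            origin="threshold",
        )
        for i in idx
    ]


def extract_waveforms(
    x: np.ndarray, events: list, window_len: int = WAVEFORM_LEN
) -> tuple:
    """Attach trough-centered waveforms to events.

    Events too close to either edge for a full window are dropped; returns
    ``(kept_events, n_dropped)``.
    """
    x = np.asarray(x, dtype=float)
    half = window_len // 2
    kept = []
    dropped = 0
    for ev in events:
        i = ev.sample_index
        if i - half < 0 or i + half + 1 > len(x):
            dropped += 1
            continue
        ev.waveform = x[i - half : i + half + 1].copy()
        kept.append(ev)
    return kept, dropped


def median_template(waveforms) -> np.ndarray:
    """Per-sample median spike shape over a set of waveforms."""
    wf = np.asarray(waveforms, dtype=float)
    if wf.ndim != 2 or wf.shape[0] < 1:
        raise ValueError("need at least one waveform")
    return np.median(wf, axis=0)


def sliding_pearson(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson correlation of the template with every window of the signal.

    Output ``c`` has length ``len(x) - len(template) + 1``; ``c[i]``
    correlates ``template`` with ``x[i : i + len(template)]``. Zero-variance
    windows yield 0.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(template, dtype=float)
    m = len(w)
    if m < 2 or len(x) < m:
        raise ValueError("template must fit inside the signal")
    wc = w - w.mean()
    w_ss = float(np.dot(wc, wc))
    if w_ss == 0:
        return np.zeros(len(x) - m + 1)
    num = np.correlate(x, wc, mode="valid")  # sum x_w * wc (means drop out)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = csum[m:] - csum[:-m]
    s2 = csum2[m:] - csum2[:-m]
    var = np.maximum(s2 - s1 * s1 / m, 0.0)
    denom = np.sqrt(var * w_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    return np.clip(c, -1.0, 1.0)


def template_matching_detect(
    x: np.ndarray,
    template: np.ndarray,
    existing_events: list,
    sample_rate_hz: float = 20_000.0,
    multiplier: float = 4.0,
    dedup_s: float = 0.002,
    min_separation_s: float = MIN_SEPARATION_S,
) -> list:
    """Re-detect spikes on the sliding-correlation trace.

    The detection recipe is applied to the correlation coefficient: its own
    robust-noise threshold, then local maxima (Pearson correlation peaks
    positively at true matches). Matches within ``dedup_s`` of an existing
    event are discarded, so the returned events are disjoint from — and
    never remove — the threshold-stage events.
    """
    c = sliding_pearson(x, template)
    thr = detection_threshold(c, multiplier)
    distance = max(int(round(min_separation_s * sample_rate_hz)), 1)
    idx, _ = find_peaks(c, height=thr, distance=distance)
    half = len(template) // 2
    centers = idx + half  # alignment start -> trough position
    existing = np.sort([ev.sample_index for ev in existing_events])
    dedup = dedup_s * sample_rate_hz
    new_events = []
    for i in centers:
        if len(existing):
            j = np.searchsorted(existing, i)
            near = min(
                abs(i - existing[j - 1]) if j > 0 else np.inf,
                abs(existing[j] - i) if j < len(existing) else np.inf,
            )
            if near <= dedup:
                continue
        new_events.append(
            SpikeEvent(
                t_s=i / sample_rate_hz,
                sample_index=int(i),
                trough_amplitude=float(np.asarray(x, dtype=float)[i]),
                origin="template",
            )
        )
    return new_events


# --------------------------------------------------------------------------
# evaluation against ground truth
# --------------------------------------------------------------------------


def match_events(
    detected_times: np.ndarray, true_times: np.ndarray, tol_s: float = 0.001
) -> np.ndarray:
    """Greedy one-to-one matching of detected to true spike times.

    Returns an integer array over detected times: the index of the matched
    true spike, or -1. Each true spike is matched at most once; ties go to
    the nearest pair first.
    """
    detected_times = np.asarray(detected_times, dtype=float)
    true_times = np.asarray(true_times, dtype=float)
    assignment = np.full(len(detected_times), -1, dtype=int)
    if len(detected_times) == 0 or len(true_times) == 0:
        return assignment
    pairs = []
    j = np.searchsorted(true_times, detected_times)
    for d_i, (t_d, jj) in enumerate(zip(detected_times, j)):
        for cand in (jj - 1, jj):
            if 0 <= cand < len(true_times):
                dt = abs(true_times[cand] - t_d)
                if dt <= tol_s:
                    pairs.append((dt, d_i, cand))
    used_d, used_t = set(), set()
    for dt, d_i, t_i in sorted(pairs):
        if d_i in used_d or t_i in used_t:
            continue
        assignment[d_i] = t_i
        used_d.add(d_i)
        used_t.add(t_i)
    return assignment


def detection_f1(
    detected_times: np.ndarray, true_times: np.ndarray, tol_s: float = 0.001
) -> dict:
    """Precision, recall and F1 of detected vs. true spike times."""
    assignment = match_events(detected_times, true_times, tol_s)
    tp = int(np.sum(assignment >= 0))
    n_det, n_true = len(np.asarray(detected_times)), len(np.asarray(true_times))
    precision = tp / n_det if n_det else 0.0
    recall = tp / n_true if n_true else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp}
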