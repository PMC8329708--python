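"""Spike-rate binning, repetition autocorrelation, and rate/yaw correlation.

Spike trains are binned on a fixed 100 ms grid. Two analyses link rates to
flight behavior: (1) the Pearson correlation of the rate vector of a single
trefoil repetition with every equal-length window of the whole flight's rate
series, which peaks at the start of every repetition if activity is locked
to the repeated trajectory; (2) the lagged Pearson correlation between spike
rate and yaw speed (|yaw rate|), whose peak lag estimates the latency of the
neural response to turning. A 3 s rolling mean is provided for
visualization; all correlations use the raw 100 ms rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import TelemetryTrack

__all__ = [
    "RateSeries",
    "CrossCorrResult",
    "RepetitionSegmentation",
    "bin_rates",
    "smooth_rates",
    "bin_yaw_speed",
    "segment_repetitions",
    "sliding_autocorrelation",
    "lagged_crosscorr",
]

DEFAULT_BIN_S = 0.1


@dataclass
class RateSeries:
    """Binned spike rates on a fixed grid of half-open bins."""

    start_t_s: float
    bin_width_s: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def rates(self) -> np.ndarray:
        """Rates in Hz: counts / bin width."""
        return self.counts / self.bin_width_s

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_centers(self) -> np.ndarray:
        return self.start_t_s + (np.arange(self.n_bins) + 0.5) * self.bin_width_s


@dataclass
class CrossCorrResult:
    """Lagged correlation between two series on a common grid."""

    lags_s: np.ndarray
    r_at_lag: np.ndarray
    peak_lag_s: float
    peak_r: float


@dataclass
class RepetitionSegmentation:
    """Repetition intervals [start_s, end_s) on the telemetry clock."""

    intervals: list
    entry_times_s: np.ndarray

    def __len__(self) -> int:
        return len(self.intervals)


def bin_rates(
    spike_times: np.ndarray,
    t0: float,
    t1: float,
    bin_width_s: float = DEFAULT_BIN_S,
) -> RateSeries:
    """Bin spike times into half-open bins [t0 + i*w, t0 + (i+1)*w).

    Counts are conserved: every spike in [t0, t1) lands in exactly one bin.
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    spike_times = np.asarray(spike_times, dtype=float)
    n_bins = int(np.ceil((t1 - t0) / bin_width_s - 1e-12))
    sel = (spike_times >= t0) & (spike_times < t1)
    idx = np.floor((spike_times[sel] - t0) / bin_width_s).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return RateSeries(start_t_s=t0, bin_width_s=bin_width_s, counts=counts)


def smooth_rates(series: RateSeries, window_s: float = 3.0) -> np.ndarray:
    """Centered rolling mean of the rates (visualization only).

    The window is truncated at the edges, so the interior mean is preserved
    and no padding bias is introduced.
    """
    if window_s < series.bin_width_s:
        raise ValueError("window must be at least one bin wide")
    win = int(round(window_s / series.bin_width_s))
    rates = series.rates.astype(float)
    csum = np.concatenate([[0.0], np.cumsum(rates)])
    n = len(rates)
    half_l = (win - 1) // 2
    half_r = win // 2
    i = np.arange(n)
    lo = np.maximum(i - half_l, 0)
    hi = np.minimum(i + half_r + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def bin_yaw_speed(
    telemetry: TelemetryTrack,
    t0: float,
    t1: float,
    bin_width_s: float = DEFAULT_BIN_S,
    signed: bool = False,
) -> np.ndarray:
    """Yaw rate resampled to the rate grid by per-bin averaging.

    By default the yaw-rate magnitude |yaw rate| is used (turning speed
    regardless of direction); ``signed=True`` keeps the sign.
    """
    n_bins = int(np.ceil((t1 - t0) / bin_width_s - 1e-12))
    yr = telemetry.yaw_rate_rad_s if signed else np.abs(telemetry.yaw_rate_rad_s)
    sel = (telemetry.t_s >= t0) & (telemetry.t_s < t1)
    idx = np.floor((telemetry.t_s[sel] - t0) / bin_width_s).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=yr[sel], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    out = np.full(n_bins, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if np.any(~nz):  # sparse telemetry: fill gaps by interpolation
        centers = (np.arange(n_bins) + 0.5) * bin_width_s + t0
        out[~nz] = np.interp(centers[~nz], centers[nz], out[nz])
    return out


def segment_repetitions(
    telemetry: TelemetryTrack,
    start_region: tuple,
    min_gap_s: float = 10.0,
    bearing_rad: float | None = None,
    bearing_tol_rad: float = 0.01,
) -> RepetitionSegmentation:
    """Split a flight into repetitions of the repeated trajectory.

    A repetition starts when the copter is inside the circular start region
    ``(x, y, radius)`` *and* its heading aligns (within ``bearing_tol_rad``)
    with the initial bearing — i.e., it has finished turning at the corner
    and set off on the first leg again. Successive starts closer than
    ``min_gap_s`` are merged. The default bearing is the heading at the
    first in-region sample. The flight before the first start and after the
    final return to the region (closest approach to the region center during
    the last visit) is excluded as take-off/landing.

    The bearing tolerance should be smaller than the per-sample heading
    change during the corner turn, so each detected start is accurate to a
    couple of telemetry samples; with 100 Hz telemetry and ordinary turn
    rates the 0.01 rad default satisfies this.
    """
    cx, cy, radius = start_region
    if radius <= 0:
        raise ValueError("start region radius must be positive")
    dist = np.hypot(telemetry.x_m - cx, telemetry.y_m - cy)
    inside = dist <= radius
    if not np.any(inside):
        return RepetitionSegmentation(intervals=[], entry_times_s=np.empty(0))
    if bearing_rad is None:
        bearing_rad = float(telemetry.yaw_rad[np.nonzero(inside)[0][0]])
    ang = np.abs(
        np.mod(telemetry.yaw_rad - bearing_rad + np.pi, 2 * np.pi) - np.pi
    )
    cond = inside & (ang <= bearing_tol_rad)
    edges = np.nonzero(cond & ~np.concatenate([[False], cond[:-1]]))[0]
    starts = []
    for e in edges:
        if not starts or telemetry.t_s[e] - starts[-1][1] >= min_gap_s:
            starts.append((e, telemetry.t_s[e]))
    if not starts:
        return RepetitionSegmentation(intervals=[], entry_times_s=np.empty(0))
    entry_times = np.array([t for _, t in starts])
    intervals = [
        (entry_times[i], entry_times[i + 1]) for i in range(len(entry_times) - 1)
    ]
    # final repetition: close at the return to the region after the last start
    last_idx = starts[-1][0]
    after = np.nonzero(~inside & (np.arange(len(inside)) > last_idx))[0]
    if len(after):
        revisit = np.nonzero(inside & (np.arange(len(inside)) > after[0]))[0]
        if len(revisit):
            j0 = revisit[0]
            j1 = j0
            while j1 + 1 < len(inside) and inside[j1 + 1]:
                j1 += 1
            closest = j0 + int(np.argmin(dist[j0 : j1 + 1]))
            end_t = float(telemetry.t_s[closest])
        else:
            end_t = float(telemetry.t_s[-1])
    else:
        end_t = float(telemetry.t_s[-1])
    # an "entry" at the very end of the flight is the closing crossing of the
    # last repetition, not the start of a new one: require a real duration
    if end_t - entry_times[-1] >= min_gap_s:
        intervals.append((float(entry_times[-1]), end_t))
    return RepetitionSegmentation(intervals=intervals, entry_times_s=entry_times)


def sliding_autocorrelation(
    rate_series: RateSeries, template_interval: tuple
) -> tuple:
    """Correlate one repetition's rate vector against the whole series.

    ``template_interval`` is ``(start_s, end_s)`` on the series' clock; the
    rate bins covered by it form the template, which is slid across the full
    series. Returns ``(offsets_s, r)`` where ``offsets_s[i]`` is the start
    time of window ``i`` and ``r[i]`` its Pearson correlation with the
    template (0 where a window has zero variance).
    """
    t_start, t_end = template_interval
    w = rate_series.bin_width_s
    i0 = int(round((t_start - rate_series.start_t_s) / w))
    i1 = int(round((t_end - rate_series.start_t_s) / w))
    i0, i1 = max(i0, 0), min(i1, rate_series.n_bins)
    template = rate_series.rates[i0:i1]
    if len(template) < 2:
        raise ValueError("template interval too short")
    if len(template) > rate_series.n_bins:
        raise ValueError("template longer than the series")
    from .detection import sliding_pearson  # same statistic, reused

    r = sliding_pearson(rate_series.rates, template)
    offsets = rate_series.start_t_s + np.arange(len(r)) * w
    return offsets, r


def lagged_crosscorr(
    rate_series: np.ndarray,
    behavior_series: np.ndarray,
    max_lag_s: float,
    step_s: float = DEFAULT_BIN_S,
    min_overlap_bins: int = 10,
) -> CrossCorrResult:
    """Pearson correlation at every lag in [-max_lag, +max_lag].

    Positive lag means the rate follows the behavior (neural activity lags
    the stimulus). Series must share the same grid with bin width
    ``step_s``; the overlap shrinks with |lag| (no padding) and lags with
    fewer than ``min_overlap_bins`` overlapping bins are omitted.
    """
    x = np.asarray(rate_series, dtype=float)
    y = np.asarray(behavior_series, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must share one grid")
    if max_lag_s < step_s:
        raise ValueError("max_lag must be at least one step")
    max_k = int(round(max_lag_s / step_s))
    lags, rs = [], []
    for k in range(-max_k, max_k + 1):
        if k >= 0:  # rate delayed by k bins relative to behavior
            xs, ys = x[k:], y[: len(y) - k]
        else:
            xs, ys = x[: len(x) + k], y[-k:]
        if len(xs) < min_overlap_bins:
            continue
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(xs, ys)[0, 1])
        lags.append(k * step_s)
        rs.append(r)
    if not lags:
        raise ValueError("no lag had sufficient overlap")
    lags = np.asarray(lags)
    rs = np.asarray(rs)
    peak = int(np.argmax(rs))
    return CrossCorrResult(
        lags_s=lags, r_at_lag=rs, peak_lag_s=float(lags[peak]), peak_r=float(rs[peak])
    )
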