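"""Synthetic flights, spike trains, recordings and terrains.

The generator produces data with the statistical structure the analysis
pipeline assumes, so every downstream stage can be tested against known
ground truth without any field data:

- a trefoil flight path (three straight lobes over a feeder joined by
  right-hand circular arcs) flown at constant speed and altitude, sampled as
  100 Hz telemetry;
- inhomogeneous-Poisson spike trains whose rate follows the copter's yaw
  speed at a configurable latency, with an enforced refractory period;
- two-channel 16-bit recordings at 20 kHz containing shared (common-mode)
  rotor/motor-like noise with per-channel gain mismatch, independent
  band-limited noise, occasional transient artifacts, and injected spike
  waveforms split with opposite polarity across the channels (so channel
  subtraction cancels the shared noise but reinforces the spikes);
- smooth random terrain height grids with a polygonal field mask.

All outputs are bit-reproducible from (parameters, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon

from .beeview import TerrainModel
from .session import RawRecording, TelemetryTrack, wrap_angle

__all__ = [
    "GroundTruth",
    "NoiseModel",
    "gen_trefoil_telemetry",
    "gen_spike_trains",
    "gen_recording",
    "gen_terrain",
    "sample_inhomogeneous_poisson",
    "make_template",
    "default_templates",
    "default_noise_model",
    "speed_envelope",
    "write_ground_truth",
    "read_ground_truth",
]

logger = logging.getLogger(__name__)

#: Spike waveform length in samples at 20 kHz (1.44 ms window, rounded up to odd).
TEMPLATE_LEN = 29

_GOLDEN = (1.0 + 5.0**0.5) / 2.0


@dataclass
class GroundTruth:
    """Generative ground truth for one synthetic session."""

    unit_spike_times: list  # per-unit arrays of seconds, strictly increasing
    injected_lag_s: float
    rate_gain: float  # Hz per rad/s of yaw speed
    baseline_rate_hz: float
    channel_gains: tuple = (2.0, 1.0)
    repetition_bounds: list = field(default_factory=list)  # [start_s, end_s)
    refractory_s: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        self.unit_spike_times = [
            np.asarray(t, dtype=float) for t in self.unit_spike_times
        ]
        for t in self.unit_spike_times:
            if len(t) >= 2:
                d = np.diff(t)
                if np.any(d <= 0):
                    raise ValueError("spike times must be strictly increasing")
                if self.refractory_s > 0 and np.any(d < self.refractory_s):
                    raise ValueError("spike train violates its refractory period")
        for i in range(len(self.repetition_bounds) - 1):
            if self.repetition_bounds[i][1] > self.repetition_bounds[i + 1][0]:
                raise ValueError("repetition bounds must be ordered, non-overlapping")

    @property
    def n_units(self) -> int:
        return len(self.unit_spike_times)

    def all_spike_times(self) -> np.ndarray:
        """Pooled, sorted spike times over all units."""
        if not self.unit_spike_times:
            return np.empty(0)
        return np.sort(np.concatenate(self.unit_spike_times))


@dataclass
class NoiseModel:
    """Recording-noise description.

    ``common_mode_harmonics`` are rotor/motor tones (frequency Hz, amplitude)
    shared by both channels up to the per-channel gains; the overall
    common-mode level is scaled over time by ``amplitude_envelope`` (a
    callable of time in seconds, typically derived from copter speed).
    ``impulse_rate_hz`` adds Poisson-timed transient artifacts (short
    common-mode bursts). Independent per-channel Gaussian noise of standard
    deviation ``independent_noise_sd`` is band-limited to ``band_hz`` by FFT
    masking, mirroring the recording hardware's 300 Hz - 10 kHz bandpass.
    """

    common_mode_harmonics: Sequence = ((600.0, 10.0), (1200.0, 8.0), (2400.0, 7.0))
    amplitude_envelope: Callable | None = None
    impulse_rate_hz: float = 0.2
    independent_noise_sd: float = 1.0
    band_hz: tuple = (300.0, 10_000.0)

    def __post_init__(self) -> None:
        for f, a in self.common_mode_harmonics:
            if a < 0:
                raise ValueError("harmonic amplitudes must be >= 0")
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")

    def validate_rate(self, sample_hz: float) -> None:
        if self.band_hz[1] > sample_hz / 2:
            raise ValueError("band upper edge must not exceed Nyquist")


# --------------------------------------------------------------------------
# trefoil flight geometry
# --------------------------------------------------------------------------


class _Straight:
    def __init__(self, p0, heading, length):
        self.p0 = np.asarray(p0, float)
        self.heading = float(heading)
        self.length = float(length)
        self._u = np.array([np.cos(heading), np.sin(heading)])

    def point(self, s):
        return self.p0[:, None] + np.multiply.outer(self._u, s)

    def heading_at(self, s):
        return np.full(np.shape(s), self.heading)

    @property
    def end(self):
        return self.p0 + self._u * self.length


class _ArcCW:
    """Clockwise (right-turn) circular arc."""

    def __init__(self, p0, heading0, radius, turn_rad):
        self.p0 = np.asarray(p0, float)
        self.h0 = float(heading0)
        self.r = float(radius)
        self.turn = float(turn_rad)
        self.length = self.r * self.turn
        # center sits to the right of the heading
        self.center = self.p0 + self.r * np.array([np.sin(self.h0), -np.cos(self.h0)])

    def heading_at(self, s):
        return self.h0 - np.asarray(s) / self.r

    def point(self, s):
        h = self.heading_at(s)
        return self.center[:, None] + self.r * np.stack([-np.sin(h), np.cos(h)])

    @property
    def end(self):
        return self.point(np.array([self.length]))[:, 0]


def _rsr_connect(p0, h0, p1, h1, radius):
    """Right-Straight-Right Dubins connection between two poses.

    Both turns are clockwise (right turns, as flown in the experiments).
    Returns the list of segments (possibly with zero-length members
    omitted). Exact: the path ends at exactly (p1, h1).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)

    def right_center(p, h):
        return p + radius * np.array([np.sin(h), -np.cos(h)])

    c0 = right_center(p0, h0)
    c1 = right_center(p1, h1)
    d = c1 - c0
    dist = float(np.hypot(*d))
    segs = []
    if dist < 1e-9:
        turn = float(np.mod(h0 - h1, 2 * np.pi))
        if turn > 1e-12:
            segs.append(_ArcCW(p0, h0, radius, turn))
        return segs
    h_t = float(np.arctan2(d[1], d[0]))
    turn0 = float(np.mod(h0 - h_t, 2 * np.pi))
    arc0 = _ArcCW(p0, h0, radius, turn0)
    if turn0 > 1e-12:
        segs.append(arc0)
    segs.append(_Straight(arc0.end if turn0 > 1e-12 else p0, h_t, dist))
    turn1 = float(np.mod(h_t - h1, 2 * np.pi))
    if turn1 > 1e-12:
        segs.append(_ArcCW(segs[-1].end, h_t, radius, turn1))
    return segs


def gen_trefoil_telemetry(
    speed_m_s: float = 5.5,
    altitude_m: float = 15.0,
    feeder_xy: tuple = (0.0, 0.0),
    leg_beyond_m: float = 80.0,
    n_repetitions: int = 3,
    sample_hz: float = 100.0,
    seed: int = 0,
    start_xy: tuple = (-150.0, -150.0),
    turn_radius_m: float = 15.0,
):
    """Constant-speed trefoil flight telemetry plus repetition bounds.

    One repetition: from the start corner straight over the feeder and
    ``leg_beyond_m`` past it, then a right turn back over the feeder from a
    bearing rotated 120 degrees clockwise — twice more, three lobes in total
    — and finally a right turn onto the return path to the start corner.
    Consecutive straight lobes are joined by exact right-turn/straight/
    right-turn (Dubins RSR) connections, so the repetition is a closed loop
    through the start pose and every repetition retraces it identically. Yaw
    is the instantaneous path heading; yaw rate is its finite-difference
    derivative.

    Returns ``(TelemetryTrack, repetition_bounds)`` where each bound is
    ``[start_s, end_s)`` on the telemetry clock; bounds are contiguous and
    a single repetition covers the whole flight. ``seed`` is accepted for
    interface uniformity; the geometry is deterministic.
    """
    if speed_m_s <= 0 or altitude_m <= 0 or leg_beyond_m <= 0 or turn_radius_m <= 0:
        raise ValueError("geometry parameters must be positive")
    if n_repetitions < 1 or sample_hz <= 0:
        raise ValueError("need n_repetitions >= 1 and positive sample rate")

    feeder = np.asarray(feeder_xy, float)
    start = np.asarray(start_xy, float)
    if np.allclose(feeder, start):
        raise ValueError("feeder and start must differ")

    segments = []
    total = 0.0

    def push(seg):
        nonlocal total
        if seg.length > 0:
            segments.append((total, seg))
            total += seg.length

    h1 = float(np.arctan2(*(feeder - start)[::-1]))
    bearings = [h1, h1 - 2 * np.pi / 3, h1 - 4 * np.pi / 3]
    d_in = leg_beyond_m  # inbound run-up to the feeder on lobes 2 and 3

    # one repetition's straight lobes as (start point, heading, length)
    lobes = []
    leg0_len = float(np.hypot(*(feeder - start))) + leg_beyond_m
    lobes.append((start, bearings[0], leg0_len))
    for h in bearings[1:]:
        a = feeder - d_in * np.array([np.cos(h), np.sin(h)])
        lobes.append((a, h, d_in + leg_beyond_m))

    bounds_len = []
    for _rep in range(n_repetitions):
        rep_start = total
        for k, (p, h, length) in enumerate(lobes):
            leg = _Straight(p, h, length)
            push(leg)
            nxt = lobes[(k + 1) % 3]
            target_pose = (nxt[0], nxt[1]) if k < 2 else (start, bearings[0])
            for seg in _rsr_connect(leg.end, h, *target_pose, turn_radius_m):
                push(seg)
        bounds_len.append((rep_start, total))

    # sample at constant speed
    n_samp = int(np.floor(total / speed_m_s * sample_hz)) + 1
    t = np.arange(n_samp) / sample_hz
    s = np.minimum(t * speed_m_s, total - 1e-9)
    seg_starts = np.array([s0 for s0, _ in segments])
    seg_idx = np.searchsorted(seg_starts, s, side="right") - 1
    xy = np.empty((2, n_samp))
    yaw = np.empty(n_samp)
    for i, (s0, seg) in enumerate(segments):
        sel = seg_idx == i
        if not np.any(sel):
            continue
        local = s[sel] - s0
        xy[:, sel] = seg.point(local)
        yaw[sel] = seg.heading_at(local)
    yaw_c = np.unwrap(yaw)
    yaw_rate = np.gradient(yaw_c, t)
    track = TelemetryTrack(
        t_s=t,
        x_m=xy[0],
        y_m=xy[1],
        alt_m=np.full(n_samp, altitude_m),
        yaw_rad=wrap_angle(yaw_c),
        yaw_rate_rad_s=yaw_rate,
        speed_m_s=np.full(n_samp, speed_m_s),
    )
    bounds = [(s0 / speed_m_s, s1 / speed_m_s) for s0, s1 in bounds_len]
    # the final repetition closes at the end of the sampled track
    bounds[-1] = (bounds[-1][0], float(t[-1]))
    return track, bounds


# --------------------------------------------------------------------------
# spike trains
# --------------------------------------------------------------------------


#: Time resolution to which generated spike times are snapped: one sample at
#: the 20 kHz acquisition rate. Spike waveforms are necessarily injected at
#: integer sample positions, so the ground truth is realized on this grid.
TIME_RESOLUTION_S = 5e-5


def sample_inhomogeneous_poisson(
    rate_fn: Callable,
    t0: float,
    t1: float,
    lam_max: float,
    rng: np.random.Generator,
    refractory_s: float = 0.0,
    time_resolution_s: float = TIME_RESOLUTION_S,
) -> np.ndarray:
    """Inhomogeneous Poisson times on [t0, t1) by thinning, with a refractory
    dead time enforced by forward deletion.

    ``rate_fn`` must be vectorized and bounded by ``lam_max``. Accepted times
    are snapped to ``time_resolution_s`` (the acquisition sample grid) and the
    dead time is enforced *strictly* on the snapped times, so consecutive
    spikes are always more than ``refractory_s`` apart even after sample
    quantization — matching the hard floor plus near-zero density just above
    it seen in real single-unit interspike-interval histograms.
    """
    if lam_max < 0:
        raise ValueError("lam_max must be >= 0")
    if lam_max == 0 or t1 <= t0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    lam = np.asarray(rate_fn(cand), dtype=float)
    if np.any(lam > lam_max * (1 + 1e-9)):
        raise ValueError("rate_fn exceeds lam_max")
    keep = rng.uniform(0.0, lam_max, size=n_cand) < lam
    times = cand[keep]
    if time_resolution_s > 0:
        times = np.unique(np.round(times / time_resolution_s) * time_resolution_s)
        times = times[(times >= t0) & (times < t1)]
    if refractory_s > 0 and len(times) > 1:
        min_gap = refractory_s + max(time_resolution_s, 0.0) * 0.5
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] > min_gap:
                kept.append(t)
        times = np.asarray(kept)
    return times


def gen_spike_trains(
    telemetry: TelemetryTrack,
    n_units: int = 3,
    baseline_rate_hz: float = 5.0,
    rate_gain: float = 80.0,
    lag_s: float = 0.7,
    refractory_s: float = 0.004,
    seed: int = 0,
    channel_gains: tuple = (2.0, 1.0),
    repetition_bounds=None,
    refractory_margin_s: float = 0.001,
) -> GroundTruth:
    """Per-unit spike trains driven by lagged yaw speed.

    Each unit is an inhomogeneous Poisson process with rate
    ``lambda(t) = baseline + rate_gain * |yaw_rate(t - lag_s)|`` (yaw speed
    clamped at the telemetry start for ``t - lag_s`` before coverage),
    thinned independently per unit, with the refractory period enforced by
    forward deletion. Deterministic for a fixed seed.

    The enforced dead time is ``refractory_s + refractory_margin_s``: a pure
    dead-time Poisson process piles interspike-interval density directly at
    the absolute floor, whereas well-isolated single units show a relative
    refractory period with near-zero density just above it. The 1 ms default
    margin reproduces that gap; set it to 0 for a hard floor exactly at
    ``refractory_s``.
    """
    if baseline_rate_hz < 0 or rate_gain < 0:
        raise ValueError("rates must be >= 0")
    if lag_s < 0 or refractory_s < 0 or refractory_margin_s < 0:
        raise ValueError("lag, refractory period and margin must be >= 0")
    if telemetry.duration_s <= lag_s:
        raise ValueError("telemetry shorter than the requested lag")
    t0, t1 = float(telemetry.t_s[0]), float(telemetry.t_s[-1])
    abs_yaw_rate = np.abs(telemetry.yaw_rate_rad_s)

    def lam(t):
        tq = np.clip(np.asarray(t) - lag_s, t0, t1)
        return baseline_rate_hz + rate_gain * np.interp(tq, telemetry.t_s, abs_yaw_rate)

    lam_max = baseline_rate_hz + rate_gain * float(abs_yaw_rate.max(initial=0.0))
    dead_time = refractory_s + refractory_margin_s
    trains = []
    for u in range(n_units):
        rng = np.random.default_rng([seed, u])
        trains.append(
            sample_inhomogeneous_poisson(lam, t0, t1, lam_max, rng, dead_time)
        )
    return GroundTruth(
        unit_spike_times=trains,
        injected_lag_s=lag_s,
        rate_gain=rate_gain,
        baseline_rate_hz=baseline_rate_hz,
        channel_gains=tuple(channel_gains),
        repetition_bounds=list(repetition_bounds or []),
        refractory_s=refractory_s,
        seed=seed,
    )


# --------------------------------------------------------------------------
# spike templates
# --------------------------------------------------------------------------


def make_template(
    kind: str = "biphasic",
    n: int = TEMPLATE_LEN,
    trough_width: float = 2.0,
    overshoot: float = 0.35,
    overshoot_pos: float = 2.2,
    overshoot_width: float = 1.6,
    pre_amp: float = 0.3,
    pre_pos: float = 2.2,
) -> np.ndarray:
    """Negative-going spike waveform, trough at the center, trough depth -1.

    Kinds: ``biphasic`` (trough then positive repolarization overshoot),
    ``triphasic`` (positive deflection before the trough as well). Lobe
    positions/widths are in units of the trough width, so shapes scale
    consistently with duration.
    """
    i = np.arange(n) - n // 2
    trough = -np.exp(-0.5 * (i / trough_width) ** 2)
    over = overshoot * np.exp(
        -0.5 * ((i - overshoot_pos * trough_width) / (overshoot_width * trough_width)) ** 2
    )
    w = trough + over
    if kind == "triphasic":
        w = w + pre_amp * np.exp(
            -0.5 * ((i + pre_pos * trough_width) / (overshoot_width * trough_width)) ** 2
        )
    elif kind != "biphasic":
        raise ValueError(f"unknown template kind {kind!r}")
    # taper the outermost quarter on each side so the waveform returns to
    # baseline smoothly within its window (no step when injected into a trace)
    n_taper = max(n // 4, 1)
    taper = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
    taper[:n_taper] = ramp
    taper[-n_taper:] = ramp[::-1]
    w = w * taper
    return w / -w.min()


def default_templates(n_units: int = 3) -> list:
    """Distinct unit templates: width, symmetry and lobe structure vary.

    Trough widths correspond to the 0.3-1 ms spike durations typical of
    extracellular single-unit recordings; the positive-lobe geometry differs
    strongly between units (early vs. late repolarization, presence of a
    pre-trough deflection) so that units are separable in shape space and
    not merely in amplitude.
    """
    specs = [
        # kind, trough_width, overshoot, over_pos, over_width, pre_amp, pre_pos
        ("biphasic", 2.0, 0.90, 1.6, 1.0, 0.0, 2.2),
        ("triphasic", 2.8, 0.15, 3.0, 1.1, 0.85, 1.6),
        ("biphasic", 3.1, 0.80, 3.2, 0.8, 0.0, 2.2),
        ("triphasic", 2.5, 0.45, 2.2, 1.5, 0.30, 2.2),
    ]
    out = []
    for u in range(n_units):
        kind, width, over, opos, owid, pre, ppos = specs[u % len(specs)]
        # widen slightly on each cycle through the base shapes
        width *= 1.0 + 0.3 * (u // len(specs))
        out.append(
            make_template(
                kind,
                trough_width=width,
                overshoot=over,
                overshoot_pos=opos,
                overshoot_width=owid,
                pre_amp=pre,
                pre_pos=ppos,
            )
        )
    return out


# --------------------------------------------------------------------------
# recordings
# --------------------------------------------------------------------------


def speed_envelope(
    telemetry: TelemetryTrack, base: float = 1.0, accel_gain: float = 0.5
) -> Callable:
    """Common-mode amplitude envelope tied to flight dynamics.

    Acceleration (including centripetal acceleration in turns, proxied by
    speed * |yaw rate|) raises the envelope above ``base``; this emulates the
    noisier periods during copter maneuvers.
    """
    lin_acc = np.abs(np.gradient(telemetry.speed_m_s, telemetry.t_s))
    cent_acc = telemetry.speed_m_s * np.abs(telemetry.yaw_rate_rad_s)
    acc = lin_acc + cent_acc
    top = float(acc.max(initial=0.0))
    scale = acc / top if top > 0 else acc

    def env(t):
        return base + accel_gain * np.interp(
            np.asarray(t, float), telemetry.t_s, scale
        )

    return env


def default_noise_model(telemetry: TelemetryTrack | None = None) -> NoiseModel:
    env = speed_envelope(telemetry) if telemetry is not None else None
    return NoiseModel(amplitude_envelope=env)


def _bandlimit(x: np.ndarray, sample_hz: float, band: tuple) -> np.ndarray:
    """Band-limit by FFT masking, preserving the input's variance scale."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sample_hz)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    y = np.fft.irfft(spec, n=len(x))
    frac = mask.mean()
    return y / np.sqrt(frac) if frac > 0 else y


def gen_recording(
    ground_truth: GroundTruth,
    templates: Sequence | None = None,
    noise_model: NoiseModel | None = None,
    channel_gains: tuple | None = None,
    sample_hz: float = 20_000.0,
    seed: int | None = None,
    duration_s: float | None = None,
    spike_amplitude: float | Sequence = 12.0,
    spike_amp_scale: Callable | None = None,
    counts_per_unit: float = 250.0,
) -> RawRecording:
    """Two-channel 16-bit recording with injected spikes and shared noise.

    ``channel_i(t) = gains_i * common_noise(t) + spike_i(t) + independent_i(t)``
    where the spike contribution is split with opposite polarity across the
    channels (+w/2 on channel A, -w/2 on channel B), so the gain-matched
    differential cancels the common-mode noise and reassembles the full
    waveform. ``spike_amp_scale``, if given, is a callable of time scaling
    each spike's amplitude (used to emulate episodes of poor signal).
    Output is quantized to int16 at ``counts_per_unit`` counts per model
    unit; a clipping fraction above 1% is logged as a warning.
    """
    gt = ground_truth
    templates = list(templates) if templates is not None else default_templates(gt.n_units)
    if len(templates) != gt.n_units:
        raise ValueError("need exactly one template per unit")
    noise_model = noise_model or NoiseModel()
    noise_model.validate_rate(sample_hz)
    gains = tuple(channel_gains) if channel_gains is not None else gt.channel_gains
    seed = gt.seed if seed is None else seed
    rng = np.random.default_rng([seed, 9001])

    all_t = gt.all_spike_times()
    if duration_s is None:
        duration_s = float(all_t[-1] + 0.05) if len(all_t) else 1.0
    n = int(round(duration_s * sample_hz))
    t = np.arange(n) / sample_hz

    # common-mode noise: harmonics with random phase, shaped by the envelope
    common = np.zeros(n)
    for f_hz, amp in noise_model.common_mode_harmonics:
        common += amp * np.sin(2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi))
    if noise_model.amplitude_envelope is not None:
        common *= noise_model.amplitude_envelope(t)
    # transient artifacts: short decaying common-mode bursts
    if noise_model.impulse_rate_hz > 0:
        amp_sum = sum(a for _, a in noise_model.common_mode_harmonics)
        n_imp = rng.poisson(noise_model.impulse_rate_hz * duration_s)
        imp_len = int(0.002 * sample_hz)
        decay = np.exp(-np.arange(imp_len) / (imp_len / 4.0))
        for t_imp in rng.uniform(0, duration_s, size=n_imp):
            i0 = int(t_imp * sample_hz)
            seg = slice(i0, min(i0 + imp_len, n))
            burst = 2.0 * amp_sum * rng.standard_normal(seg.stop - i0)
            common[seg] += burst * decay[: seg.stop - i0]

    # spike contributions, opposite polarity across channels
    amps = np.broadcast_to(np.asarray(spike_amplitude, float), (gt.n_units,))
    spikes = np.zeros(n)
    half = TEMPLATE_LEN // 2
    for u, times in enumerate(gt.unit_spike_times):
        w = np.asarray(templates[u], float)
        if len(w) != TEMPLATE_LEN:
            raise ValueError(f"templates must span {TEMPLATE_LEN} samples")
        for ts in times:
            c = int(round(ts * sample_hz))
            i0, i1 = c - half, c + half + 1
            j0, j1 = max(i0, 0), min(i1, n)
            if j0 >= j1:
                continue
            scale = amps[u] * (spike_amp_scale(ts) if spike_amp_scale else 1.0)
            spikes[j0:j1] += scale * w[j0 - i0 : j1 - i0]

    chans = []
    for ch, (gain, pol) in enumerate(zip(gains, (0.5, -0.5))):
        indep = noise_model.independent_noise_sd * rng.standard_normal(n)
        if noise_model.independent_noise_sd > 0:
            indep = _bandlimit(indep, sample_hz, noise_model.band_hz)
        chans.append(gain * common + pol * spikes + indep)

    counts = [np.round(c * counts_per_unit) for c in chans]
    clip_frac = float(np.mean([(np.abs(c) > 32767).mean() for c in counts]))
    if clip_frac > 0.01:
        logger.warning("quantization clipped %.2f%% of samples", 100 * clip_frac)
    counts = [np.clip(c, -32768, 32767).astype(np.int16) for c in counts]
    return RawRecording(
        channel_a=counts[0], channel_b=counts[1], sample_rate_hz=sample_hz
    )


# --------------------------------------------------------------------------
# terrain
# --------------------------------------------------------------------------


def gen_terrain(
    extent_m: tuple = (200.0, 200.0),
    cell_m: float = 1.0,
    field_polygon: Sequence | None = None,
    seed: int = 0,
    flat: bool = False,
    relief_m: float = 2.0,
    smooth_m: float = 10.0,
    origin_xy_m: tuple = (0.0, 0.0),
) -> TerrainModel:
    """Smooth random height field with a polygonal field mask.

    ``flat=True`` yields all-zero heights. The default field polygon is the
    central 60% rectangle of the extent. Reproducible from (parameters, seed).
    """
    ex, ey = extent_m
    if ex <= 0 or ey <= 0 or cell_m <= 0:
        raise ValueError("extent and cell size must be positive")
    n_cols = int(round(ex / cell_m))
    n_rows = int(round(ey / cell_m))
    if flat:
        heights = np.zeros((n_rows, n_cols))
    else:
        rng = np.random.default_rng([seed, 777])
        raw = rng.standard_normal((n_rows, n_cols))
        heights = gaussian_filter(raw, sigma=smooth_m / cell_m, mode="reflect")
        sd = heights.std()
        if sd > 0:
            heights *= relief_m / (3 * sd)

    x0, y0 = origin_xy_m
    if field_polygon is None:
        field_polygon = [
            (x0 + 0.2 * ex, y0 + 0.2 * ey),
            (x0 + 0.8 * ex, y0 + 0.2 * ey),
            (x0 + 0.8 * ex, y0 + 0.8 * ey),
            (x0 + 0.2 * ex, y0 + 0.8 * ey),
        ]
    poly = Polygon(field_polygon)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate field polygon")
    xs = x0 + (np.arange(n_cols) + 0.5) * cell_m
    ys = y0 + (np.arange(n_rows) + 0.5) * cell_m
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for r in range(n_rows):
        y = ys[n_rows - 1 - r]  # row 0 = north edge
        for c in range(n_cols):
            mask[r, c] = poly.contains(Point(xs[c], y))
    return TerrainModel(
        origin_xy_m=(x0, y0), cell_m=cell_m, heights=heights, field_mask=mask
    )


# --------------------------------------------------------------------------
# ground-truth I/O
# --------------------------------------------------------------------------


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "unit_spike_times": [t.tolist() for t in gt.unit_spike_times],
        "injected_lag_s": gt.injected_lag_s,
        "rate_gain": gt.rate_gain,
        "baseline_rate_hz": gt.baseline_rate_hz,
        "channel_gains": list(gt.channel_gains),
        "repetition_bounds": [list(b) for b in gt.repetition_bounds],
        "refractory_s": gt.refractory_s,
        "seed": gt.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_ground_truth(path) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    payload["channel_gains"] = tuple(payload["channel_gains"])
    payload["repetition_bounds"] = [tuple(b) for b in payload["repetition_bounds"]]
    return GroundTruth(**payload)
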