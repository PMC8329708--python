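"""Data model and I/O for recordings and telemetry, and their time alignment.

The recording clock and the copter telemetry clock are related by a single
constant offset (GPS-timestamped hardware keeps them within a fraction of a
millisecond); :func:`align` applies that offset and exposes interpolated
telemetry lookup at arbitrary recording times.

Conventions: time in float64 seconds; positions in local metric east/north
coordinates; yaw in radians, ENU frame, counterclockwise positive, stored
wrapped to (-pi, pi] and interpolated on the circle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "RawRecording",
    "TelemetryTrack",
    "TelemetryState",
    "Session",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_telemetry",
    "write_telemetry",
    "align",
    "wrap_angle",
]

#: Columns of the telemetry CSV, in order.
TELEMETRY_COLUMNS = (
    "t_s",
    "x_m",
    "y_m",
    "alt_m",
    "yaw_rad",
    "yaw_rate_rad_s",
    "speed_m_s",
)

_TELEMETRY_HEADER_COMMENT = (
    "# yaw_rad: ENU frame, counterclockwise positive, radians in (-pi, pi]\n"
)


class FormatError(ValueError):
    """Raised for files that do not match the expected on-disk format."""


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass
class RawRecording:
    """Two synchronized extracellular channels.

    Samples are stored as int16 counts (the acquisition bit depth) or float;
    both channels share one sample clock.
    """

    channel_a: np.ndarray
    channel_b: np.ndarray
    sample_rate_hz: float = 20_000.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a)
        self.channel_b = np.asarray(self.channel_b)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channels must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.channel_a)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times(self) -> np.ndarray:
        """Sample times on the recording clock."""
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class TelemetryTrack:
    """Timestamped pose/kinematics stream at a nominal 100 Hz."""

    t_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    alt_m: np.ndarray
    yaw_rad: np.ndarray
    yaw_rate_rad_s: np.ndarray
    speed_m_s: np.ndarray

    def __post_init__(self) -> None:
        for name in TELEMETRY_COLUMNS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_s)
        for name in TELEMETRY_COLUMNS[1:]:
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if n >= 2 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("telemetry time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TELEMETRY_COLUMNS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TelemetryTrack":
        missing = set(TELEMETRY_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"telemetry CSV missing columns: {sorted(missing)}")
        return cls(**{c: df[c].to_numpy(dtype=float) for c in TELEMETRY_COLUMNS})


@dataclass
class TelemetryState:
    """Interpolated telemetry at a single instant."""

    t_s: float
    x_m: float
    y_m: float
    alt_m: float
    yaw_rad: float
    yaw_rate_rad_s: float
    speed_m_s: float


def read_recording(path) -> RawRecording:
    """Read a 2-channel 16-bit PCM WAV file.

    Raises :class:`FormatError` on wrong channel count or sample format.
    """
    rate, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise FormatError(f"expected 16-bit PCM samples, got {data.dtype}")
    if data.ndim != 2 or data.shape[1] != 2:
        n_ch = 1 if data.ndim == 1 else data.shape[1]
        raise FormatError(f"expected 2 channels, got {n_ch}")
    return RawRecording(
        channel_a=data[:, 0].copy(),
        channel_b=data[:, 1].copy(),
        sample_rate_hz=float(rate),
    )


def write_recording(rec: RawRecording, path) -> None:
    """Write a recording as 2-channel 16-bit PCM WAV (round-trip bit-exact)."""
    a = np.asarray(rec.channel_a)
    b = np.asarray(rec.channel_b)
    if a.dtype != np.int16:
        if np.any(np.abs(a) > 32767) or np.any(np.abs(b) > 32767):
            raise ValueError("float samples exceed int16 range; quantize first")
        a = np.round(a).astype(np.int16)
        b = np.round(b).astype(np.int16)
    data = np.column_stack([a, b.astype(np.int16)])
    wavfile.write(path, int(round(rec.sample_rate_hz)), data)


def read_telemetry(path) -> TelemetryTrack:
    """Read a telemetry CSV (7 named columns, '#' comment lines allowed).

    Validates strictly increasing time; raises on non-monotonic rows.
    """
    df = pd.read_csv(path, comment="#")
    track = TelemetryTrack.from_frame(df)
    return track


def write_telemetry(track: TelemetryTrack, path) -> None:
    buf = io.StringIO()
    buf.write(_TELEMETRY_HEADER_COMMENT)
    track.to_frame().to_csv(buf, index=False, float_format="%.9g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


@dataclass
class Session:
    """A recording aligned onto the telemetry time base.

    ``clock_offset_s`` is added to recording time to map it onto telemetry
    time: ``t_tel = t_rec + clock_offset_s``.
    """

    recording: RawRecording
    telemetry: TelemetryTrack
    clock_offset_s: float = 0.0
    _yaw_unwrapped: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._yaw_unwrapped = np.unwrap(self.telemetry.yaw_rad)

    def recording_to_telemetry_time(self, t_rec) -> np.ndarray:
        return np.asarray(t_rec, dtype=float) + self.clock_offset_s

    def lookup(self, t_rec: float) -> TelemetryState:
        """Interpolated telemetry state at a recording-clock time.

        Positions and scalar kinematics are interpolated linearly; yaw is
        interpolated on the circle (via the unwrapped angle), so a lookup
        across the +/-pi wrap returns the shortest-arc interpolant.
        """
        tel = self.telemetry
        t = float(self.recording_to_telemetry_time(t_rec))
        if t < tel.t_s[0] or t > tel.t_s[-1]:
            raise ValueError(f"time {t} s outside telemetry range")
        yaw = wrap_angle(np.interp(t, tel.t_s, self._yaw_unwrapped))
        return TelemetryState(
            t_s=t,
            x_m=float(np.interp(t, tel.t_s, tel.x_m)),
            y_m=float(np.interp(t, tel.t_s, tel.y_m)),
            alt_m=float(np.interp(t, tel.t_s, tel.alt_m)),
            yaw_rad=float(yaw),
            yaw_rate_rad_s=float(np.interp(t, tel.t_s, tel.yaw_rate_rad_s)),
            speed_m_s=float(np.interp(t, tel.t_s, tel.speed_m_s)),
        )

    def lookup_arrays(self, t_rec: np.ndarray) -> pd.DataFrame:
        """Vectorized :meth:`lookup` over an array of recording times."""
        tel = self.telemetry
        t = self.recording_to_telemetry_time(t_rec)
        if np.any(t < tel.t_s[0]) or np.any(t > tel.t_s[-1]):
            raise ValueError("some times fall outside telemetry range")
        out = {"t_s": t}
        for name in ("x_m", "y_m", "alt_m", "yaw_rate_rad_s", "speed_m_s"):
            out[name] = np.interp(t, tel.t_s, getattr(tel, name))
        out["yaw_rad"] = wrap_angle(np.interp(t, tel.t_s, self._yaw_unwrapped))
        return pd.DataFrame(out)


def align(
    recording: RawRecording,
    telemetry: TelemetryTrack,
    clock_offset_s: float = 0.0,
) -> Session:
    """Merge a recording with telemetry using a constant clock offset.

    Raises if the shifted recording interval does not overlap the telemetry
    interval.
    """
    if not np.isfinite(clock_offset_s):
        raise ValueError("clock offset must be finite")
    rec_t0 = recording.start_time_s + clock_offset_s
    rec_t1 = rec_t0 + recording.duration_s
    if rec_t1 <= telemetry.t_s[0] or rec_t0 >= telemetry.t_s[-1]:
        raise ValueError("recording and telemetry do not overlap in time")
    return Session(recording=recording, telemetry=telemetry, clock_offset_s=clock_offset_s)
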