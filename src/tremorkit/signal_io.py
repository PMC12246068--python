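"""Reading, resampling, windowing and labelling of gyroscope recordings.

A recording is a list of contiguous blocks ("segments"): within a block the
sampling is uniform; blocks are split wherever the inter-sample interval
exceeds 1.5x the nominal interval (non-wear, charging, dropouts).  Analysis
operates on consecutive non-overlapping 4-s windows that never span a gap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

CSV_COLUMNS = ["time_iso", "gyro_x", "gyro_y", "gyro_z"]

#: fixed priority order used to break activity-label ties deterministically
ACTIVITY_PRIORITY = [
    "sitting", "standing", "gait", "postural_transition",
    "running_exercising", "cycling", "driving", "upper_limb_activity",
    "periodic_activity", "rest", "voluntary_movement", "other",
]


class FormatError(ValueError):
    """Raised for malformed input files (names the offending row)."""


@dataclass
class Segment:
    """Contiguous uniformly sampled block of tri-axial angular velocity."""

    start_time: pd.Timestamp
    fs: float
    samples: np.ndarray  # (N, 3) deg/s

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration_s)


@dataclass
class GyroRecording:
    subject_id: str
    segments: list[Segment] = field(default_factory=list)

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)


@dataclass
class WindowRecord:
    """One 4-s analysis window, optionally carrying training labels."""

    subject_id: str
    start_time: pd.Timestamp
    fs: float
    samples: np.ndarray
    label_tremor: bool | None = None
    label_activity: str | None = None


@dataclass
class AnnotationTrack:
    """Interval annotations: (start, end, channel, value).

    ``channel`` is ``tremor`` (value truthy/falsy) or ``activity`` (value is
    a category name); activity intervals must not overlap each other.
    """

    intervals: list[tuple[pd.Timestamp, pd.Timestamp, str, object]]

    def __post_init__(self):
        acts = []
        for start, end, channel, value in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {start}..{end}")
            if channel not in ("tremor", "activity"):
                raise ValueError(f"unknown channel {channel!r}")
            if channel == "activity":
                acts.append((start, end))
        acts.sort()
        for (s1, e1), (s2, e2) in zip(acts, acts[1:]):
            if s2 < e1:
                raise ValueError("overlapping activity intervals")

    def channel(self, name: str):
        return [(s, e, v) for s, e, c, v in self.intervals if c == name]


# ---------------------------------------------------------------------------


def read_recording(path, subject_id: str | None = None,
                   gap_factor: float = 1.5) -> GyroRecording:
    """Parse a ``time_iso,gyro_x,gyro_y,gyro_z`` CSV into a recording.

    The nominal sampling interval is the median inter-sample interval of the
    file; any interval exceeding ``gap_factor`` times the nominal starts a
    new segment, whose own rate is re-inferred from its median interval
    (robust to timestamp jitter).
    """
    import pathlib

    path = pathlib.Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    times = pd.to_datetime(df["time_iso"]).values.astype("datetime64[ns]")
    if len(times) < 2:
        raise FormatError(f"{path.name}: fewer than 2 samples")
    dt = np.diff(times).astype("timedelta64[ns]").astype(np.int64) / 1e9
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        # 1-based file row of the sample whose timestamp does not advance
        raise FormatError(f"{path.name}: non-monotone time at row {bad[0] + 3}")
    samples = df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        row = int(np.argwhere(~np.isfinite(samples))[0, 0]) + 2
        raise FormatError(f"{path.name}: non-finite sample at row {row}")
    nominal = float(np.median(dt))
    breaks = np.flatnonzero(dt > gap_factor * nominal) + 1
    bounds = np.concatenate(([0], breaks, [len(times)]))
    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < 2:
            continue
        seg_dt = float(np.median(dt[s:e - 1]))
        segments.append(Segment(start_time=pd.Timestamp(times[s]),
                                fs=1.0 / seg_dt,
                                samples=samples[s:e]))
    return GyroRecording(subject_id=subject_id or path.stem, segments=segments)


def resample_canonical(rec: GyroRecording,
                       targets: tuple[int, ...] = (50, 100)) -> GyroRecording:
    """Resample every segment to whichever canonical rate is closest.

    Ties prefer the higher rate; anti-aliased polyphase (rational) resampling;
    rates below 50 Hz are refused because the tremor band plus harmonics
    would sit too close to Nyquist.
    """
    out = []
    for seg in rec.segments:
        if seg.fs < min(targets) - 1e-9:
            raise ValueError(
                f"sampling rate {seg.fs:.1f} Hz unsupported (< {min(targets)} Hz)")
        target = min(sorted(targets, reverse=True),
                     key=lambda t: abs(seg.fs - t))
        if abs(seg.fs - target) / target < 1e-6:
            out.append(Segment(seg.start_time, float(target), seg.samples))
            continue
        ratio = Fraction(target) / Fraction(seg.fs).limit_denominator(10 ** 6)
        ratio = ratio.limit_denominator(1000)
        resampled = scipy.signal.resample_poly(
            seg.samples, ratio.numerator, ratio.denominator, axis=0)
        out.append(Segment(seg.start_time, float(target), resampled))
    return GyroRecording(rec.subject_id, out)


def segment_windows(rec: GyroRecording, window_s: float = 4.0
                    ) -> list[WindowRecord]:
    """Consecutive non-overlapping windows per segment; trailing partial
    windows are discarded and no window spans a gap."""
    windows = []
    for seg in rec.segments:
        size = int(round(window_s * seg.fs))
        n_win = len(seg.samples) // size
        for i in range(n_win):
            windows.append(WindowRecord(
                subject_id=rec.subject_id,
                start_time=seg.start_time + pd.Timedelta(seconds=i * window_s),
                fs=seg.fs,
                samples=seg.samples[i * size:(i + 1) * size]))
    return windows


def _overlap_s(w_start, w_end, a_start, a_end) -> float:
    lo = max(w_start, a_start)
    hi = min(w_end, a_end)
    return max((hi - lo).total_seconds(), 0.0)


def label_windows(windows: list[WindowRecord], annotations: AnnotationTrack,
                  window_s: float = 4.0) -> list[WindowRecord]:
    """Attach tremor/activity labels from interval annotations.

    A window is tremor when tremor intervals cover at least half of it
    (boundary inclusive: exactly 50% counts).  The activity label is the
    category with maximal overlap, ties broken by a fixed priority order.
    Windows with zero annotation coverage keep ``None`` labels and are
    excluded from training.
    """
    tremor_iv = annotations.channel("tremor")
    activity_iv = annotations.channel("activity")
    out = []
    for w in windows:
        w_end = w.start_time + pd.Timedelta(seconds=window_s)
        t_overlap = sum(_overlap_s(w.start_time, w_end, s, e)
                        for s, e, v in tremor_iv if v)
        cover = t_overlap + sum(_overlap_s(w.start_time, w_end, s, e)
                                for s, e, _ in activity_iv)
        if cover <= 0.0:
            out.append(WindowRecord(w.subject_id, w.start_time, w.fs,
                                    w.samples, None, None))
            continue
        tremor = t_overlap >= window_s / 2.0 - 1e-9
        acc: dict[str, float] = {}
        for s, e, value in activity_iv:
            ov = _overlap_s(w.start_time, w_end, s, e)
            if ov > 0:
                acc[value] = acc.get(value, 0.0) + ov
        activity = None
        if acc:
            def rank(item):
                name, ov = item
                prio = ACTIVITY_PRIORITY.index(name) \
                    if name in ACTIVITY_PRIORITY else len(ACTIVITY_PRIORITY)
                return (-ov, prio, name)
            activity = sorted(acc.items(), key=rank)[0][0]
        out.append(WindowRecord(w.subject_id, w.start_time, w.fs, w.samples,
                                tremor, activity))
    return out


def windows_to_array(windows: list[WindowRecord]) -> np.ndarray:
    """Stack windows of identical length into an (n, L, 3) array."""
    if not windows:
        return np.empty((0, 0, 3))
    sizes = {w.samples.shape[0] for w in windows}
    if len(sizes) != 1:
        raise ValueError("windows have mixed lengths (mixed sampling rates?)")
    return np.stack([w.samples for w in windows])


def coverage_check(rec: GyroRecording, windows: list[WindowRecord],
                   window_s: float = 4.0) -> bool:
    """True when windows tile the recording up to < window_s per segment."""
    covered = len(windows) * window_s
    if covered > rec.total_duration_s + 1e-6:
        return False
    slack = sum(s.duration_s % window_s for s in rec.segments)
    return rec.total_duration_s - covered <= slack + 1e-6
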