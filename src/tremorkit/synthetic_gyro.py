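"""Synthetic multi-day wrist-gyroscope cohorts with per-window ground truth.

The simulator emulates the signal classes a wrist-worn gyroscope sees in
free living, at desk scale and with exact labels:

* episodic 3-7 Hz rest tremor with a second harmonic, lognormal peak
  amplitude, raised-cosine onset/offset ramps and slow (0.1-0.3 Hz) amplitude
  modulation, projected onto a random (per-episode) fixed axis;
* slow voluntary arm movement as a band-limited (0.5-3 Hz) stochastic process;
* gait arm swing at a 0.9-1.1 Hz fundamental with decaying harmonics 2f..5f
  (reaching into the tremor band);
* cycling-like periodic motion at 0.8-1.5 Hz whose slowly decaying harmonics
  deliberately land in 3-7 Hz (the hard confuser for a tremor detector);
* white sensor noise on every axis and slow baseline drift below 0.5 Hz;
* one non-wear ("charging") gap per day, snapped to the 4-s window grid.

Each day is a schedule of fixed-length activity bouts drawn from per-hour
activity probabilities; tremor episodes arrive as a Poisson process on the
maximal rest runs of tremulous subjects.  Ground truth is emitted per
complete 4-s window: a window is labelled tremor when tremor was present for
at least 50% of its samples, and carries the most prevalent activity class.

Everything is driven by a single seed; identical configs reproduce identical
sample streams and labels bit for bit.
"""
from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .config import PipelineConfig
from .signal_io import GyroRecording, Segment

ACTIVITIES = ("rest", "voluntary_movement", "gait", "cycling")

TRUTH_COLUMNS = ["subject_id", "window_start", "tremor", "activity",
                 "true_freq_hz", "true_amp"]


def default_activity_schedule() -> np.ndarray:
    """Per-hour probabilities of (rest, voluntary_movement, gait, cycling).

    Nights (22:00-07:00) are almost entirely rest; daytime mixes rest with
    voluntary arm use, walking and occasional cycling, roughly matching the
    ~50% share of active (non-rest) daytime reported for wrist wearables.
    """
    sched = np.zeros((24, 4))
    for h in range(24):
        if h < 7 or h >= 22:
            sched[h] = (0.97, 0.03, 0.0, 0.0)
        else:
            sched[h] = (0.55, 0.30, 0.10, 0.05)
    return sched


@dataclass
class SimulationConfig:
    """Cohort-level generator settings (amplitudes in deg/s, rates per hour)."""

    n_subjects: int = 20
    fraction_tremor_subjects: float = 0.5
    days_per_subject: int = 2
    day_hours: float = 24.0
    fs: int = 100
    tremor_freq_range: tuple[float, float] = (3.5, 6.5)
    tremor_amplitude_logmean: float = math.log(20.0)
    tremor_amplitude_logsd: float = 0.75
    harmonic_ratio: float = 0.25
    episode_rate_per_hour: float = 6.0
    episode_duration_logmean: float = math.log(60.0)
    episode_duration_logsd: float = 0.7
    activity_schedule: np.ndarray = field(default_factory=default_activity_schedule)
    bout_s: float = 60.0
    voluntary_rms: float = 25.0
    gait_amplitude: float = 40.0
    cycling_amplitude: float = 15.0
    cycling_harmonic_decay: float = 0.55
    noise_sd: float = 1.0
    drift_sd: float = 1.5
    drift_cutoff_hz: float = 0.3
    gap_hours_per_day: float = 1.0
    start_date: str = "2024-01-01"
    seed: int = 0

    def validate(self) -> None:
        sched = np.asarray(self.activity_schedule, dtype=float)
        checks = [
            (self.fs in (50, 100), "fs must be 50 or 100 Hz"),
            (self.n_subjects >= 1, "n_subjects must be >= 1"),
            (0.0 <= self.fraction_tremor_subjects <= 1.0,
             "fraction_tremor_subjects must lie in [0, 1]"),
            (self.days_per_subject >= 1, "days_per_subject must be >= 1"),
            (0.0 < self.day_hours <= 24.0, "day_hours must lie in (0, 24]"),
            (3.0 <= self.tremor_freq_range[0] <= self.tremor_freq_range[1] <= 7.0,
             "tremor_freq_range must be contained in [3, 7] Hz"),
            (0.0 < self.drift_cutoff_hz < 0.5,
             "drift_cutoff_hz must lie in (0, 0.5)"),
            (sched.shape == (24, 4), "activity_schedule must be 24 x 4"),
            (np.all(sched >= 0) and np.all(sched <= 1)
             and np.allclose(sched.sum(axis=1), 1.0),
             "activity_schedule rows must be probabilities summing to 1"),
            (0.0 <= self.gap_hours_per_day < self.day_hours,
             "gap_hours_per_day must be shorter than the day"),
            (self.noise_sd >= 0 and self.drift_sd >= 0,
             "noise levels must be non-negative"),
            (self.episode_rate_per_hour >= 0, "episode rate must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        for name in ("tremor_amplitude_logmean", "tremor_amplitude_logsd",
                     "episode_duration_logmean", "episode_duration_logsd",
                     "harmonic_ratio", "voluntary_rms", "gait_amplitude",
                     "cycling_amplitude"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


# ---------------------------------------------------------------------------
# waveform primitives


def _raised_cosine_ramp(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    r = min(n_ramp, n // 2)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] *= ramp
        env[-r:] *= ramp[::-1]
    return env


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def render_tremor_episode(n: int, fs: float, freq: float, peak_amp: float,
                          harmonic_ratio: float, rng: np.random.Generator,
                          ramp_s: float = 2.0, mod_depth: float = 0.2
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One tremor episode: (n, 3) signal and its (n,) amplitude envelope.

    Waveform: ``A(t) [sin(2 pi f t + phi) + r sin(4 pi f t + phi2)]`` on a
    random fixed axis, with raised-cosine on/off ramps and +-``mod_depth``
    sinusoidal modulation at 0.1-0.3 Hz (waxing/waning).
    """
    t = np.arange(n) / fs
    f_mod = rng.uniform(0.1, 0.3)
    phi, phi2, phi_m = rng.uniform(0, 2 * np.pi, size=3)
    env = peak_amp * _raised_cosine_ramp(n, int(round(ramp_s * fs)))
    env = env * (1.0 + mod_depth * np.sin(2 * np.pi * f_mod * t + phi_m))
    wave = np.sin(2 * np.pi * freq * t + phi) \
        + harmonic_ratio * np.sin(4 * np.pi * freq * t + phi2)
    axis = _random_unit_vector(rng)
    return env[:, None] * wave[:, None] * axis[None, :], env


def _harmonic_motion(n: int, fs: float, f0: float, amp: float,
                     decays: np.ndarray, rng: np.random.Generator,
                     ramp_s: float = 0.5) -> np.ndarray:
    t = np.arange(n) / fs
    wave = np.zeros(n)
    for k, d in enumerate(decays, start=1):
        wave += d * np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi))
    wave *= amp * _raised_cosine_ramp(n, int(round(ramp_s * fs)))
    return wave[:, None] * _random_unit_vector(rng)[None, :]


@functools.lru_cache(maxsize=8)
def _movement_sos(fs: float):
    return scipy.signal.butter(4, [0.5, 3.0], btype="bandpass",
                               fs=fs, output="sos")


@functools.lru_cache(maxsize=8)
def _drift_sos(fs: float, cutoff: float):
    return scipy.signal.butter(2, cutoff, btype="lowpass", fs=fs,
                               output="sos")


def _voluntary_movement(n: int, fs: float, rms: float,
                        rng: np.random.Generator) -> np.ndarray:
    x = scipy.signal.sosfilt(_movement_sos(fs), rng.normal(size=(n, 3)),
                             axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x *= rms / math.sqrt(3.0) / sd
    env = _raised_cosine_ramp(n, int(round(0.5 * fs)))
    return x * env[:, None]


def _gait_signal(n, fs, amp, rng):
    f0 = rng.uniform(0.9, 1.1)
    return _harmonic_motion(n, fs, f0, amp, 0.4 ** np.arange(5), rng)


def _cycling_signal(n, fs, amp, decay, rng):
    f0 = rng.uniform(0.8, 1.5)
    return _harmonic_motion(n, fs, f0, amp, decay ** np.arange(5), rng)


def _drift(n: int, fs: float, sd: float, cutoff: float,
           rng: np.random.Generator) -> np.ndarray:
    """Slow baseline wander: lowpass-filtered noise below ``cutoff``.

    Synthesised at a decimated rate (content sits far below 1 Hz) and
    linearly interpolated to the sampling grid.
    """
    if sd <= 0:
        return np.zeros((n, 3))
    fs_lo = 2.0
    n_lo = max(int(math.ceil(n / fs * fs_lo)) + 2, 16)
    x = scipy.signal.sosfilt(_drift_sos(fs_lo, cutoff),
                             rng.normal(size=(n_lo, 3)), axis=0)
    s = x.std(axis=0)
    s[s == 0] = 1.0
    x *= sd / s
    t = np.arange(n) / fs
    t_lo = np.arange(n_lo) / fs_lo
    return np.stack([np.interp(t, t_lo, x[:, a]) for a in range(3)], axis=1)


# ---------------------------------------------------------------------------
# per-day simulation


@dataclass
class _Day:
    """Raw output for one simulated day (before gap removal)."""

    samples: np.ndarray          # (n, 3)
    activity: np.ndarray         # (n,) int index into ACTIVITIES
    tremor_mask: np.ndarray      # (n,) bool
    tremor_env: np.ndarray       # (n,) envelope deg/s (0 outside episodes)


def _runs(bool_arr: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of the True runs of a boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], bool_arr.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _simulate_day(cfg: SimulationConfig, rng: np.random.Generator,
                  has_tremor: bool, tremor_freq: float) -> _Day:
    fs = cfg.fs
    n = int(round(cfg.day_hours * 3600)) * fs
    x = rng.normal(0.0, cfg.noise_sd, size=(n, 3)) if cfg.noise_sd > 0 \
        else np.zeros((n, 3))
    x += _drift(n, fs, cfg.drift_sd, cfg.drift_cutoff_hz, rng)

    # activity bouts from the per-hour schedule
    bout_len = int(round(cfg.bout_s * fs))
    n_bouts = -(-n // bout_len)
    hour = (np.arange(n_bouts) * cfg.bout_s // 3600).astype(int) % 24
    probs = np.asarray(cfg.activity_schedule, dtype=float)[hour]
    u = rng.random(n_bouts)
    acts = np.minimum((u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1),
                      len(ACTIVITIES) - 1)
    activity = np.repeat(acts, bout_len)[:n]

    for b in range(n_bouts):
        a = acts[b]
        if a == 0:
            continue
        s, e = b * bout_len, min((b + 1) * bout_len, n)
        m = e - s
        if a == 1:
            x[s:e] += _voluntary_movement(m, fs, cfg.voluntary_rms, rng)
        elif a == 2:
            x[s:e] += _gait_signal(m, fs, cfg.gait_amplitude, rng)
        else:
            x[s:e] += _cycling_signal(m, fs, cfg.cycling_amplitude,
                                      cfg.cycling_harmonic_decay, rng)

    mask = np.zeros(n, dtype=bool)
    env_all = np.zeros(n)
    if has_tremor and cfg.episode_rate_per_hour > 0:
        for s, e in _runs(activity == 0):
            run_hours = (e - s) / fs / 3600.0
            for _ in range(rng.poisson(cfg.episode_rate_per_hour * run_hours)):
                dur_s = rng.lognormal(cfg.episode_duration_logmean,
                                      cfg.episode_duration_logsd)
                m = int(round(min(max(dur_s, 4.0), (e - s) / fs) * fs))
                start = s + int(rng.integers(0, e - s - m + 1))
                amp = rng.lognormal(cfg.tremor_amplitude_logmean,
                                    cfg.tremor_amplitude_logsd)
                sig, env = render_tremor_episode(
                    m, fs, tremor_freq, amp, cfg.harmonic_ratio, rng)
                x[start:start + m] += sig
                mask[start:start + m] = True
                env_all[start:start + m] = np.maximum(
                    env_all[start:start + m], env)
    return _Day(samples=x, activity=activity, tremor_mask=mask,
                tremor_env=env_all)


def window_labels_from_mask(tremor_mask: np.ndarray, window: int) -> np.ndarray:
    """Apply the >=50%-of-window rule to a sample-level tremor mask."""
    n_win = tremor_mask.size // window
    frac = tremor_mask[:n_win * window].reshape(n_win, window).mean(axis=1)
    return frac >= 0.5


def _day_truth(day: _Day, cfg: SimulationConfig, subject_id: str,
               day_start: pd.Timestamp, tremor_freq: float,
               keep: np.ndarray) -> pd.DataFrame:
    """Per-window ground truth for the kept (non-gap) samples of one day.

    ``keep`` marks non-gap samples; gap edges are window-aligned so kept
    windows coincide with the windows of the written/streamed segments.
    """
    fs = cfg.fs
    window = 4 * fs
    n_win = day.samples.shape[0] // window

    def per_window(arr, red):
        return red(arr[:n_win * window].reshape(n_win, window))

    frac = per_window(day.tremor_mask, lambda a: a.mean(axis=1))
    tremor = frac >= 0.5
    counts = np.stack([per_window(day.activity == k,
                                  lambda a: a.sum(axis=1))
                       for k in range(len(ACTIVITIES))], axis=1)
    act_idx = np.argmax(counts, axis=1)       # ties -> lowest index (rest first)
    masked_env = np.where(day.tremor_mask, day.tremor_env, 0.0)
    env_sum = per_window(masked_env, lambda a: a.sum(axis=1))
    mask_cnt = per_window(day.tremor_mask, lambda a: a.sum(axis=1))
    amp = np.divide(env_sum, mask_cnt, out=np.full(n_win, np.nan),
                    where=mask_cnt > 0)
    kept_win = per_window(keep, lambda a: a.all(axis=1))
    starts = day_start + pd.to_timedelta(np.arange(n_win) * 4, unit="s")
    df = pd.DataFrame({
        "subject_id": subject_id,
        "window_start": starts,
        "tremor": tremor,
        "activity": np.asarray(ACTIVITIES)[act_idx],
        "true_freq_hz": np.where(tremor, tremor_freq, np.nan),
        "true_amp": np.where(tremor, amp, np.nan),
    })
    return df[kept_win].reset_index(drop=True)


def _gap_keep_mask(cfg: SimulationConfig, rng: np.random.Generator,
                   n: int) -> np.ndarray:
    """Boolean keep-mask with one gap per day, aligned to the 4-s grid."""
    keep = np.ones(n, dtype=bool)
    window = 4 * cfg.fs
    gap_windows = int(round(cfg.gap_hours_per_day * 3600 / 4))
    if gap_windows <= 0:
        return keep
    n_win = n // window
    if gap_windows >= n_win:
        raise ValueError("gap longer than the simulated day")
    start_w = int(rng.integers(0, n_win - gap_windows + 1))
    keep[start_w * window:(start_w + gap_windows) * window] = False
    return keep


# ---------------------------------------------------------------------------
# cohort-level API


def _subject_plan(cfg: SimulationConfig):
    n_trem = int(round(cfg.n_subjects * cfg.fraction_tremor_subjects))
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng([cfg.seed, i])
        has_tremor = i < n_trem
        freq = float(rng.uniform(*cfg.tremor_freq_range)) if has_tremor else np.nan
        yield f"S{i:03d}", has_tremor, freq, rng


def iter_subject_segments(cfg: SimulationConfig):
    """Yield (subject_id, segment_start, samples, truth_df) lazily.

    The streaming core of the simulator: one day is materialised at a time,
    so multi-day cohorts can be featurised without holding raw signals.
    Segments are the maximal contiguous non-gap spans of each day.
    """
    cfg.validate()
    t0 = pd.Timestamp(cfg.start_date)
    for subject_id, has_tremor, freq, rng in _subject_plan(cfg):
        for d in range(cfg.days_per_subject):
            day_start = t0 + pd.Timedelta(days=d)
            day = _simulate_day(cfg, rng, has_tremor, freq)
            keep = _gap_keep_mask(cfg, rng, day.samples.shape[0])
            truth = _day_truth(day, cfg, subject_id, day_start, freq, keep)
            for s, e in _runs(keep):
                seg_start = day_start + pd.Timedelta(seconds=s / cfg.fs)
                seg_truth = truth[(truth.window_start >= seg_start)
                                  & (truth.window_start
                                     < day_start + pd.Timedelta(seconds=e / cfg.fs))]
                yield subject_id, seg_start, day.samples[s:e], seg_truth


def simulate_cohort(cfg: SimulationConfig
                    ) -> tuple[list[GyroRecording], pd.DataFrame]:
    """Materialise the full cohort: one recording per subject + truth table.

    Suitable for desk-scale configs; multi-day cohorts should prefer
    :func:`simulate_and_featurize`, which never holds a full recording.
    """
    recordings: dict[str, GyroRecording] = {}
    truths = []
    for subject_id, start, samples, truth in iter_subject_segments(cfg):
        rec = recordings.setdefault(subject_id,
                                    GyroRecording(subject_id, []))
        last = rec.segments[-1] if rec.segments else None
        if last is not None and (
                last.start_time
                + pd.Timedelta(seconds=len(last.samples) / cfg.fs) == start):
            last.samples = np.concatenate([last.samples, samples])
        else:
            rec.segments.append(Segment(start_time=start, fs=float(cfg.fs),
                                        samples=samples.copy()))
        truths.append(truth)
    truth_df = pd.concat(truths, ignore_index=True) if truths \
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    return list(recordings.values()), truth_df


def simulate_and_featurize(cfg: SimulationConfig,
                           pipeline: PipelineConfig = PipelineConfig()
                           ) -> pd.DataFrame:
    """Stream the cohort through spectral featurisation.

    Returns one row per complete 4-s window with feature columns
    (peak_freq_hz, mfcc_1..12, low_band_power, tremor_power), ground-truth
    training labels (label_tremor, label_activity) and truth metadata.
    """
    from .spectral_features import featurize_array

    frames = []
    window = 4 * cfg.fs
    for subject_id, start, samples, truth in iter_subject_segments(cfg):
        n_win = samples.shape[0] // window
        if n_win == 0:
            continue
        arr = samples[:n_win * window].reshape(n_win, window, 3)
        feats = featurize_array(arr, cfg.fs, pipeline)
        feats.insert(0, "subject_id", subject_id)
        feats.insert(1, "window_start",
                     start + pd.to_timedelta(np.arange(n_win) * 4, unit="s"))
        t = truth.reset_index(drop=True)
        if len(t) != n_win or not (t.window_start.values
                                   == feats.window_start.values).all():
            raise AssertionError("truth/window misalignment in simulator")
        feats["label_tremor"] = t.tremor.values
        feats["label_activity"] = t.activity.values
        feats["true_freq_hz"] = t.true_freq_hz.values
        feats["true_amp"] = t.true_amp.values
        frames.append(feats)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# window-level synthesis (training experiments and unit tests)


def simulate_activity_windows(activity: str, n: int, cfg: SimulationConfig,
                              rng: np.random.Generator) -> np.ndarray:
    """Stack of isolated 4-s windows of one signal class, shape (n, 4*fs, 3).

    ``activity`` is one of ``rest``, ``voluntary_movement``, ``gait``,
    ``cycling`` or ``tremor`` (continuous tremor at a random in-band
    frequency, no ramps).  Useful for controlled classifier experiments such
    as the cycling-oversampling comparison.
    """
    fs = cfg.fs
    m = 4 * fs
    out = np.empty((n, m, 3))
    for i in range(n):
        x = rng.normal(0.0, cfg.noise_sd, size=(m, 3)) if cfg.noise_sd > 0 \
            else np.zeros((m, 3))
        if activity == "tremor":
            freq = rng.uniform(*cfg.tremor_freq_range)
            amp = rng.lognormal(cfg.tremor_amplitude_logmean,
                                cfg.tremor_amplitude_logsd)
            sig, _ = render_tremor_episode(m, fs, freq, amp,
                                           cfg.harmonic_ratio, rng, ramp_s=0.0)
            x += sig
        elif activity == "voluntary_movement":
            x += _voluntary_movement(m, fs, cfg.voluntary_rms, rng)
        elif activity == "gait":
            x += _gait_signal(m, fs, cfg.gait_amplitude, rng)
        elif activity == "cycling":
            x += _cycling_signal(m, fs, cfg.cycling_amplitude,
                                 cfg.cycling_harmonic_decay, rng)
        elif activity != "rest":
            raise ValueError(f"unknown activity {activity!r}")
        out[i] = x
    return out


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(recordings: list[GyroRecording], truth: pd.DataFrame,
                  dir_path) -> list[str]:
    """Write one time-series CSV per subject plus a labels.tsv truth table.

    CSV contract: header ``time_iso,gyro_x,gyro_y,gyro_z``, ISO-8601 local
    timestamps, values in deg/s at full float precision (round-trip safe).
    """
    import pathlib

    dir_path = pathlib.Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    written = []
    for rec in recordings:
        frames = []
        for seg in rec.segments:
            times = seg.start_time + pd.to_timedelta(
                np.arange(len(seg.samples)) / seg.fs, unit="s")
            frames.append(pd.DataFrame({
                "time_iso": times.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                "gyro_x": seg.samples[:, 0],
                "gyro_y": seg.samples[:, 1],
                "gyro_z": seg.samples[:, 2],
            }))
        path = dir_path / f"{rec.subject_id}.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written.append(str(path))
    labels = truth.copy()
    labels["window_start_iso"] = pd.to_datetime(
        labels["window_start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    labels = labels[["subject_id", "window_start_iso", "tremor", "activity",
                     "true_freq_hz", "true_amp"]]
    label_path = dir_path / "labels.tsv"
    labels.to_csv(label_path, sep="\t", index=False)
    written.append(str(label_path))
    return written


def read_fixture_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["window_start"] = pd.to_datetime(df.pop("window_start_iso"))
    return df
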