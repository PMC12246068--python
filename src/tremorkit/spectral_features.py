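"""Per-window spectral features for tremor detection.

Each 4-s tri-axial gyroscope window is summarised by

* a Welch power spectral density per axis, summed over the three axes
  (rotation-robust: the sum is invariant to which axis the tremor projects on),
* the peak frequency of the summed PSD,
* 12 mel-frequency cepstral coefficients (MFCCs) computed from a 15-filter
  triangular filterbank spanning 0-25 Hz with a frequency warp adjusted for
  inertial signals,
* band power in the 0.5-3 Hz "slow arm movement" band, and
* tremor power ``log10(P_T + 1)`` where ``P_T`` is the power inside a 1.25 Hz
  band centred on the dominant 3-7 Hz peak.

MFCC orders 1..12 are invariant to rescaling of the raw signal (a global gain
shifts every log filterbank energy by the same constant, which lives entirely
in the discarded order-0 coefficient).  This is what makes the trained
detector transferable across devices with different gains and drift levels.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .config import BandConfig, FilterbankConfig, PipelineConfig, WelchConfig

# Floor for log filterbank energies.  Keeping it far below any physical
# energy preserves MFCC scale invariance even for downscaled signals (a
# larger floor of ~1e-12 already perturbs coefficients at the 1e-9 level
# when windows are attenuated 10x).
_LOG_EPS = 1e-30


@dataclass
class PsdSummary:
    """One-sided Welch PSD summed over the three gyroscope axes.

    ``psd_total`` is a density in (deg/s)^2/Hz: its integral over frequency
    approximates the signal variance summed over axes (Parseval).
    """

    freqs: np.ndarray
    psd_total: np.ndarray
    welch_params: dict

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class MelFilterbank:
    """Triangular filterbank on the PSD frequency grid."""

    freqs: np.ndarray
    edges: np.ndarray        # n_filters + 2 edge frequencies, Hz
    weights: np.ndarray      # (n_filters, len(freqs)), each row >= 0

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return self.edges[1:-1]


@dataclass
class WindowFeatures:
    """Spectral summary of one 4-s window."""

    peak_freq_hz: float | None
    mfcc: np.ndarray
    low_band_power: float
    tremor_power: float
    psd: PsdSummary | None = None


# ---------------------------------------------------------------------------
# Welch PSD


def welch_psd(samples: np.ndarray, fs: float,
              welch: WelchConfig = WelchConfig()) -> PsdSummary:
    """Welch PSD of an (N, 3) window, summed across axes.

    Per-axis estimates use ``welch.segment_s`` segments with the configured
    taper and overlap, one-sided density normalisation, constant detrend.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError(f"expected (N, 3) samples, got {samples.shape}")
    if not np.all(np.isfinite(samples)):
        raise ValueError("window contains non-finite samples")
    nperseg = int(round(welch.segment_s * fs))
    freqs, pxx = scipy.signal.welch(
        samples, fs=fs, window=welch.taper, nperseg=nperseg,
        noverlap=int(round(nperseg * welch.overlap)),
        detrend="constant", scaling="density", axis=0)
    return PsdSummary(freqs=freqs, psd_total=pxx.sum(axis=1),
                      welch_params={"segment_len_s": welch.segment_s,
                                    "overlap_fraction": welch.overlap,
                                    "taper": welch.taper, "fs": fs})


def peak_frequency(psd: PsdSummary,
                   search_range: tuple[float, float] = (0.5, 25.0)
                   ) -> float | None:
    """Frequency of the summed-PSD maximum within ``search_range`` (inclusive).

    Ties resolve to the lowest frequency; an identically-zero PSD yields
    ``None`` (the window is treated as non-tremor downstream).
    """
    lo, hi = search_range
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    seg = psd.psd_total[mask]
    if seg.size == 0 or np.max(seg) <= 0.0:
        return None
    return float(psd.freqs[mask][int(np.argmax(seg))])


# ---------------------------------------------------------------------------
# Filterbank and MFCCs


def _warp_mel_inertial(break_hz: float) -> tuple[Callable, Callable]:
    def warp(f):
        return np.log1p(np.asarray(f, dtype=float) / break_hz)

    def unwarp(w):
        return break_hz * np.expm1(np.asarray(w, dtype=float))

    return warp, unwarp


def _warp_linear() -> tuple[Callable, Callable]:
    ident = lambda f: np.asarray(f, dtype=float)  # noqa: E731
    return ident, ident


def build_filterbank(fs: float,
                     fb: FilterbankConfig = FilterbankConfig(),
                     welch: WelchConfig = WelchConfig(),
                     warp_funcs: tuple[Callable, Callable] | None = None
                     ) -> MelFilterbank:
    """Triangular filterbank on the Welch grid of a window at rate ``fs``.

    ``n_filters + 2`` edges are obtained by inverse-warping equally spaced
    points of the warp function over the analysis band; filter ``j`` rises
    linearly from edge ``j`` to edge ``j+1`` and falls to edge ``j+2``
    (peak 1).  With the default concave warp the filters are narrow over the
    tremor band and widen with frequency; ``warp_funcs`` may supply any
    monotone (warp, unwarp) pair.
    """
    df = 1.0 / welch.segment_s
    freqs = np.arange(0.0, fs / 2 + df / 2, df)
    if warp_funcs is not None:
        warp, unwarp = warp_funcs
    elif fb.warp == "mel_inertial":
        warp, unwarp = _warp_mel_inertial(fb.warp_break_hz)
    elif fb.warp == "linear":
        warp, unwarp = _warp_linear()
    else:
        raise ValueError(f"unknown warp preset {fb.warp!r}")
    lo, hi = fb.band
    edges = unwarp(np.linspace(warp(lo), warp(hi), fb.n_filters + 2))
    edges = np.clip(edges, lo, hi)
    weights = np.zeros((fb.n_filters, freqs.size))
    for j in range(fb.n_filters):
        left, center, right = edges[j], edges[j + 1], edges[j + 2]
        rising = (freqs - left) / max(center - left, 1e-12)
        falling = (right - freqs) / max(right - center, 1e-12)
        weights[j] = np.clip(np.minimum(rising, falling), 0.0, None)
    return MelFilterbank(freqs=freqs, edges=edges, weights=weights)


def compute_mfcc(psd: PsdSummary, fb: MelFilterbank,
                 n_coefficients: int = 12, eps: float = _LOG_EPS
                 ) -> np.ndarray:
    """Cepstral coefficients of orders 1..n from log filterbank energies.

    ``E_j = sum_f weights_j(f) * psd(f)``; coefficients are the orthonormal
    DCT-II of ``ln(E + eps)`` with the order-0 (overall log-energy) term
    discarded, which is exactly what makes the result scale-invariant.
    """
    if psd.psd_total.shape != fb.freqs.shape:
        raise ValueError("PSD and filterbank use different frequency grids")
    energies = fb.weights @ psd.psd_total
    logs = np.log(energies + eps)
    coeffs = scipy.fft.dct(logs, type=2, norm="ortho")
    return coeffs[1:n_coefficients + 1]


# ---------------------------------------------------------------------------
# Band powers


def band_power(psd: PsdSummary, lo: float, hi: float) -> float:
    """Trapezoidal integral of the summed PSD over ``[lo, hi)`` in (deg/s)^2.

    Band edges off the frequency grid are handled by linear interpolation, so
    the integral is additive over adjacent bands to rounding error.
    """
    if not (0.0 <= lo < hi <= psd.freqs[-1] + 1e-9):
        raise ValueError(f"invalid band [{lo}, {hi}] for Nyquist {psd.freqs[-1]}")
    inner = psd.freqs[(psd.freqs > lo) & (psd.freqs < hi)]
    xs = np.concatenate(([lo], inner, [min(hi, psd.freqs[-1])]))
    ys = np.interp(xs, psd.freqs, psd.psd_total)
    return float(np.trapezoid(ys, xs))


def tremor_power(psd: PsdSummary, bands: BandConfig = BandConfig()) -> float:
    """``log10(P_T + 1)`` with ``P_T`` the power in a ``power_bandwidth``-wide
    band centred on the dominant peak of the 3-7 Hz tremor band.

    The integral uses the rectangle rule over PSD bins whose centres fall in
    the band (bin width x density).  On the 0.5 Hz grid the 1.25 Hz band
    always covers the dominant bin and both neighbours, i.e. the full main
    lobe of a Hann-windowed tone, so a pure tone of amplitude A recovers
    ``P_T = A^2/2``.  The band is not clipped at the 3/7 Hz borders.
    """
    lo, hi = bands.rest_tremor_band
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    seg = psd.psd_total[mask]
    if seg.size == 0 or np.max(seg) <= 0.0:
        return 0.0
    f_dom = psd.freqs[mask][int(np.argmax(seg))]
    half = bands.power_bandwidth / 2.0
    in_band = np.abs(psd.freqs - f_dom) <= half + 1e-9
    p_t = float(psd.psd_total[in_band].sum() * psd.df)
    return float(np.log10(p_t + 1.0))


# ---------------------------------------------------------------------------
# Vectorised featurisation


_MFCC_COLS = [f"mfcc_{i}" for i in range(1, 13)]
FEATURE_COLUMNS = ["peak_freq_hz", *_MFCC_COLS, "low_band_power", "tremor_power"]


def featurize_array(windows: np.ndarray, fs: float,
                    config: PipelineConfig = PipelineConfig(),
                    chunk: int = 4096) -> pd.DataFrame:
    """Features for a stack of windows, shape (n_windows, 4*fs, 3).

    Vectorised equivalent of the single-window operations above (asserted
    equal in the test suite); processes in chunks to bound memory.
    """
    windows = np.asarray(windows)
    n = windows.shape[0]
    fb = build_filterbank(fs, config.filterbank, config.welch)
    out = {c: np.empty(n) for c in FEATURE_COLUMNS}
    welch = config.welch
    nperseg = int(round(welch.segment_s * fs))
    bands = config.bands
    nc = config.filterbank.n_coefficients
    for s in range(0, n, chunk):
        w = np.asarray(windows[s:s + chunk], dtype=float)
        freqs, pxx = scipy.signal.welch(
            w, fs=fs, window=welch.taper, nperseg=nperseg,
            noverlap=int(round(nperseg * welch.overlap)),
            detrend="constant", scaling="density", axis=1)
        psd = pxx.sum(axis=2)                      # (m, F)
        df = freqs[1] - freqs[0]
        # peak frequency over the generic search band
        p_lo, p_hi = bands.peak_search
        pmask = (freqs >= p_lo) & (freqs <= p_hi)
        seg = psd[:, pmask]
        peak = freqs[pmask][np.argmax(seg, axis=1)]
        peak = np.where(seg.max(axis=1) > 0.0, peak, np.nan)
        out["peak_freq_hz"][s:s + len(w)] = peak
        # MFCCs
        logs = np.log(psd @ fb.weights.T + _LOG_EPS)
        coeffs = scipy.fft.dct(logs, type=2, norm="ortho", axis=1)
        for i in range(nc):
            out[f"mfcc_{i + 1}"][s:s + len(w)] = coeffs[:, i + 1]
        # 0.5-3 Hz band power (band edges lie on the grid)
        m_lo, m_hi = bands.movement_band
        i_lo = int(round(m_lo / df))
        i_hi = int(round(m_hi / df))
        out["low_band_power"][s:s + len(w)] = np.trapezoid(
            psd[:, i_lo:i_hi + 1], dx=df, axis=1)
        # tremor power
        t_lo, t_hi = bands.rest_tremor_band
        tmask = (freqs >= t_lo) & (freqs <= t_hi)
        tseg = psd[:, tmask]
        f_dom = freqs[tmask][np.argmax(tseg, axis=1)]
        half = bands.power_bandwidth / 2.0
        in_band = np.abs(freqs[None, :] - f_dom[:, None]) <= half + 1e-9
        p_t = (psd * in_band).sum(axis=1) * df
        p_t = np.where(tseg.max(axis=1) > 0.0, p_t, 0.0)
        out["tremor_power"][s:s + len(w)] = np.log10(p_t + 1.0)
    return pd.DataFrame(out)


def featurize_window(samples: np.ndarray, fs: float,
                     config: PipelineConfig = PipelineConfig()
                     ) -> WindowFeatures:
    """Single-window convenience wrapper returning a :class:`WindowFeatures`."""
    psd = welch_psd(samples, fs, config.welch)
    fb = build_filterbank(fs, config.filterbank, config.welch)
    return WindowFeatures(
        peak_freq_hz=peak_frequency(psd, config.bands.peak_search),
        mfcc=compute_mfcc(psd, fb, config.filterbank.n_coefficients),
        low_band_power=band_power(psd, *config.bands.movement_band),
        tremor_power=tremor_power(psd, config.bands),
        psd=psd)
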