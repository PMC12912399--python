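"""Heart-rate estimation from pulse signals.

The pipeline is: zero-phase sixth-order Butterworth bandpass over the
0.65-4 Hz cardiac band (39-240 BPM), then a per-window spectral peak search.
Each 6 s sliding window (5 s overlap) is treated as a single Hann-tapered
Welch segment whose spectrum is evaluated on a frequency grid no coarser
than 0.1 BPM (a zoomed DFT over the analysis band, equivalent to zero-padded
FFT bins there); the window's HR is 60 times the in-band peak frequency,
stamped at the window center.

Estimates and ground truth rarely share a time base, so :func:`align`
linearly interpolates the reference onto the estimate's timestamps before
any metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann

from .errors import AlignmentError, InputError, SamplingRateError
from .rppg_methods import RPPGSignal

#: cardiac analysis band in Hz (39-240 BPM)
BAND_HZ = (0.65, 4.0)
FILTER_ORDER = 6
WINDOW_LENGTH_S = 6.0
WINDOW_OVERLAP_S = 5.0
#: spectral grid spacing for the peak search, in BPM
GRID_BPM = 0.1
#: windows with more than this fraction of invalid samples are dropped
MAX_INVALID_FRACTION = 0.2


@dataclass
class HRSeries:
    """Beats-per-minute estimates at sliding-window centers."""

    timestamps: np.ndarray
    values: np.ndarray
    window_length: float | None = None
    window_overlap: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape or self.timestamps.ndim != 1:
            raise InputError("timestamps and values must be equal-length 1-D arrays")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InputError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return self.timestamps.size


@dataclass
class PairedHR:
    """Estimate/reference BPM pairs on the estimate's time grid."""

    timestamps: np.ndarray
    estimate: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if not (self.timestamps.shape == self.estimate.shape == self.reference.shape):
            raise InputError("paired series must have equal lengths")

    @property
    def n(self) -> int:
        return self.timestamps.size


@lru_cache(maxsize=64)
def _design_sos(fs: float, low: float, high: float, order: int) -> np.ndarray:
    if fs <= 2.0 * high:
        raise SamplingRateError(
            f"frame rate {fs} Hz cannot represent the {high} Hz cutoff "
            f"(need > {2 * high} Hz)"
        )
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_array(
    values: np.ndarray,
    fs: float,
    low: float = BAND_HZ[0],
    high: float = BAND_HZ[1],
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis."""
    sos = _design_sos(fs, low, high, order)
    if values.shape[-1] <= 3 * order:
        raise InputError(f"signal too short to filter (need > {3 * order} samples)")
    return sosfiltfilt(sos, values, axis=-1)


def bandpass(
    signal: RPPGSignal,
    low: float = BAND_HZ[0],
    high: float = BAND_HZ[1],
    order: int = FILTER_ORDER,
) -> RPPGSignal:
    """Forward-backward Butterworth bandpass of a pulse signal.

    Zero-phase filtering doubles the effective order but leaves peak
    locations untouched, which is all the downstream spectral HR estimator
    consumes; estimation here is offline so causality is not needed.
    """
    out = bandpass_array(signal.values, signal.frame_rate, low, high, order)
    return RPPGSignal(signal.frame_rate, out, signal.method_tag, signal.valid_mask)


@lru_cache(maxsize=32)
def _peak_search_plan(L: int, fs: float, f1: float, f2: float, grid_bpm: float):
    """Coarse FFT grid plus the fine-refinement DTFT matrix.

    The coarse grid (spacing <= 0.025 Hz, far below the Hann mainlobe width
    of a 6 s window) locates the dominant spectral lobe; the fine stage then
    evaluates the exact DTFT on a ``grid_bpm``-spaced grid spanning +/-0.25
    Hz around that lobe, so the returned peak sits on the prescribed fine
    frequency grid.
    """
    nfft = next_fast_len(max(L, int(np.ceil(fs / 0.025))))
    freqs = rfftfreq(nfft, d=1.0 / fs)
    band_idx = np.flatnonzero((freqs >= f1) & (freqs <= f2))
    df = grid_bpm / 60.0
    offsets = np.arange(-0.25, 0.25 + df / 2, df)
    t = np.arange(L) / fs
    refine = np.exp(-2j * np.pi * t[:, None] * offsets[None, :])  # (L, n_off)
    return nfft, freqs[band_idx], band_idx, offsets, refine, t


def welch_hr_batch(
    values: np.ndarray,
    fs: float,
    window_length: float = WINDOW_LENGTH_S,
    window_overlap: float = WINDOW_OVERLAP_S,
    band: tuple[float, float] = BAND_HZ,
    grid_bpm: float = GRID_BPM,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral-peak HR for a batch of signals ``(B, N)``.

    Returns ``(timestamps (n_windows,), bpm (B, n_windows))``.
    """
    values = np.atleast_2d(values)
    n = values.shape[-1]
    L = int(round(window_length * fs))
    hop = max(1, int(round((window_length - window_overlap) * fs)))
    if n < L:
        raise InputError(
            f"signal of {n} samples shorter than one {window_length} s window"
        )
    starts = np.arange(0, n - L + 1, hop)
    wins = np.lib.stride_tricks.sliding_window_view(values, L, axis=-1)[:, ::hop, :]
    wins = wins - wins.mean(axis=-1, keepdims=True)
    taper = hann(L, sym=False)
    tapered = wins * taper
    nfft, band_freqs, band_idx, offsets, refine, t = _peak_search_plan(
        L, float(fs), band[0], band[1], grid_bpm
    )
    coarse = np.abs(rfft(tapered, n=nfft, axis=-1)[..., band_idx]) ** 2
    f0 = band_freqs[np.argmax(coarse, axis=-1)]  # (B, n_windows)
    shape = f0.shape
    flat = tapered.reshape(-1, L)
    mod = flat * np.exp(-2j * np.pi * f0.reshape(-1)[:, None] * t[None, :])
    fine = np.abs(mod @ refine) ** 2
    # keep the refined peak inside the analysis band
    cand = f0.reshape(-1)[:, None] + offsets[None, :]
    fine[(cand < band[0]) | (cand > band[1])] = -1.0
    f_peak = f0.reshape(-1) + offsets[np.argmax(fine, axis=-1)]
    bpm = 60.0 * f_peak.reshape(shape)
    timestamps = starts / fs + window_length / 2.0
    return timestamps, bpm


def welch_hr(
    signal: RPPGSignal,
    window_length: float = WINDOW_LENGTH_S,
    window_overlap: float = WINDOW_OVERLAP_S,
    band: tuple[float, float] = BAND_HZ,
    grid_bpm: float = GRID_BPM,
    max_invalid_fraction: float = MAX_INVALID_FRACTION,
) -> HRSeries:
    """Sliding-window spectral HR estimate of one pulse signal.

    Windows hop by ``window_length - window_overlap``; windows containing
    more than ``max_invalid_fraction`` invalid samples are dropped.
    """
    timestamps, bpm = welch_hr_batch(
        signal.values[None, :], signal.frame_rate, window_length, window_overlap,
        band, grid_bpm,
    )
    bpm = bpm[0]
    if not signal.valid_mask.all():
        fs = signal.frame_rate
        L = int(round(window_length * fs))
        hop = max(1, int(round((window_length - window_overlap) * fs)))
        starts = np.arange(0, signal.values.size - L + 1, hop)
        invalid = ~signal.valid_mask
        frac = np.array([invalid[s : s + L].mean() for s in starts])
        keep = frac <= max_invalid_fraction
        if not keep.any():
            raise InputError("every window exceeds the invalid-sample budget")
        timestamps, bpm = timestamps[keep], bpm[keep]
    return HRSeries(timestamps, bpm, window_length, window_overlap)


def align(estimate: HRSeries, reference: HRSeries) -> PairedHR:
    """Linearly interpolate the reference onto the estimate's timestamps.

    Estimate samples outside the reference's time span are dropped; if the
    two spans are disjoint an :class:`AlignmentError` is raised.
    """
    if estimate.n < 1 or reference.n < 2:
        raise InputError("need >= 1 estimate point and >= 2 reference points")
    t0, t1 = reference.timestamps[0], reference.timestamps[-1]
    keep = (estimate.timestamps >= t0) & (estimate.timestamps <= t1)
    if not keep.any():
        raise AlignmentError(
            f"estimate span [{estimate.timestamps[0]:.2f}, "
            f"{estimate.timestamps[-1]:.2f}] s does not overlap reference span "
            f"[{t0:.2f}, {t1:.2f}] s"
        )
    ts = estimate.timestamps[keep]
    ref = np.interp(ts, reference.timestamps, reference.values)
    return PairedHR(ts, estimate.values[keep], ref)
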