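"""Evaluation metrics for remote HR measurement.

Three per-recording metrics quantify one ROI x method combination:

MAE
    Mean absolute error between the estimated and reference HR series, in
    BPM, after alignment onto a common time grid.
PCC
    Mean over 6 s signal segments of the per-segment Pearson correlation
    between the estimated pulse signal and the reference contact-PPG
    waveform (windowing keeps slow drifts from dominating the correlation).
SNR
    Mean over segments of ``10*log10`` of the ratio between spectral power
    inside a binary mask (within +/-12 BPM of the reference HR and of its
    first harmonic) and the power everywhere else.

The overall score (OS) for one activity min-max-normalizes each
participant-aggregated metric across ROIs (MAE inverted, so 1 is best) and
averages the three components; it lies in [0, 1] by construction.

The acceptance rate is the fraction of consecutive non-overlapping 25 s
measurement windows whose MAE is within 10 BPM, and the Bland-Altman
statistics summarize the per-window estimate-reference differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError
from .hr_estimation import WINDOW_LENGTH_S, WINDOW_OVERLAP_S, PairedHR

logger = logging.getLogger(__name__)

#: half-width of the SNR frequency mask around the reference HR, in BPM
SNR_MASK_BPM = 12.0
#: per-segment SNR clamp, in dB
SNR_CLAMP_DB = 60.0
ACCEPTANCE_WINDOW_S = 25.0
ACCEPTANCE_THRESHOLD_BPM = 10.0
_EPS = 1e-12


@dataclass
class WindowedSignalPair:
    """Windowed estimated-pulse / reference-PPG segments on a shared grid.

    ``estimate_segments`` and ``reference_segments`` are (n_segments, m)
    arrays; ``reference_hr`` holds one BPM value per segment for the SNR
    mask.
    """

    frame_rate: float
    estimate_segments: np.ndarray
    reference_segments: np.ndarray
    reference_hr: np.ndarray

    def __post_init__(self) -> None:
        self.estimate_segments = np.atleast_2d(np.asarray(self.estimate_segments, float))
        self.reference_segments = np.atleast_2d(np.asarray(self.reference_segments, float))
        self.reference_hr = np.asarray(self.reference_hr, dtype=float)
        if self.estimate_segments.shape != self.reference_segments.shape:
            raise InputError("estimate and reference segments must have equal shape")
        n, m = self.estimate_segments.shape
        if n < 1 or m < 2:
            raise InputError("need >= 1 segment of >= 2 samples")
        if self.reference_hr.shape != (n,):
            raise InputError("one reference HR value per segment required")

    @property
    def n_segments(self) -> int:
        return self.estimate_segments.shape[0]


def segment_pair(
    estimate: np.ndarray,
    reference: np.ndarray,
    frame_rate: float,
    reference_hr_times: np.ndarray,
    reference_hr_values: np.ndarray,
    window_length: float = WINDOW_LENGTH_S,
    window_overlap: float = WINDOW_OVERLAP_S,
) -> WindowedSignalPair:
    """Cut two same-grid signals into the sliding windows the PCC/SNR
    metrics consume; each segment's reference HR is the median of the
    reference series inside its time span."""
    estimate = np.asarray(estimate, float)
    reference = np.asarray(reference, float)
    if estimate.shape != reference.shape or estimate.ndim != 1:
        raise InputError("estimate and reference must be equal-length 1-D signals")
    L = int(round(window_length * frame_rate))
    hop = max(1, int(round((window_length - window_overlap) * frame_rate)))
    if estimate.size < L:
        raise InputError("signals shorter than one metric window")
    xs = np.lib.stride_tricks.sliding_window_view(estimate, L)[::hop]
    ys = np.lib.stride_tricks.sliding_window_view(reference, L)[::hop]
    starts = np.arange(0, estimate.size - L + 1, hop)
    seg_hr = np.empty(starts.size)
    t = reference_hr_times
    for i, s in enumerate(starts):
        t0, t1 = s / frame_rate, (s + L) / frame_rate
        sel = (t >= t0) & (t <= t1)
        seg_hr[i] = np.median(reference_hr_values[sel]) if sel.any() else np.interp(
            (t0 + t1) / 2, t, reference_hr_values
        )
    return WindowedSignalPair(frame_rate, np.array(xs), np.array(ys), seg_hr)


def mae(pair: PairedHR) -> float:
    """Mean absolute HR error in BPM."""
    if pair.n == 0:
        raise InputError("empty paired series")
    return float(np.mean(np.abs(pair.estimate - pair.reference)))


def _pcc_segments(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment Pearson correlation in the product-moment computational
    form; returns (values, defined-mask)."""
    m = x.shape[1]
    sx, sy = x.sum(axis=1), y.sum(axis=1)
    sxx, syy = (x * x).sum(axis=1), (y * y).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    num = m * sxy - sx * sy
    varx = m * sxx - sx * sx
    vary = m * syy - sy * sy
    defined = (varx > _EPS * m * m) & (vary > _EPS * m * m)
    den = np.sqrt(np.where(defined, varx, 1.0)) * np.sqrt(np.where(defined, vary, 1.0))
    return np.where(defined, num / den, np.nan), defined


def windowed_pcc(pair: WindowedSignalPair) -> float:
    """Mean per-segment Pearson correlation between pulse and reference.

    Segments where either signal has zero variance are excluded (and
    counted in the log); if every segment is degenerate the correlation is
    undefined.
    """
    vals, defined = _pcc_segments(pair.estimate_segments, pair.reference_segments)
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info("windowed_pcc: excluded %d zero-variance segment(s)", n_excluded)
    if not defined.any():
        raise ComputationError("all segments have zero variance; PCC undefined")
    return float(np.nanmean(vals))


def snr(
    pair: WindowedSignalPair,
    mask_bpm: float = SNR_MASK_BPM,
    clamp_db: float = SNR_CLAMP_DB,
) -> float:
    """Masked-spectrum signal-to-noise ratio in dB.

    Per segment, the FFT power within +/-``mask_bpm`` of the reference HR
    and of its first harmonic counts as signal; everything else as noise.
    Segment values are clamped to +/-``clamp_db`` so pure-tone edge cases
    stay finite.
    """
    x = pair.estimate_segments
    n_seg, m = x.shape
    spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
    freqs = np.fft.rfftfreq(m, d=1.0 / pair.frame_rate)
    f_ref = pair.reference_hr[:, None] / 60.0
    half = mask_bpm / 60.0
    mask = (np.abs(freqs[None, :] - f_ref) <= half) | (
        np.abs(freqs[None, :] - 2.0 * f_ref) <= half
    )
    total = spec.sum(axis=1)
    if np.any(total <= 0):
        raise InputError("segment with zero total spectral power")
    sig = (spec * mask).sum(axis=1)
    noise = np.maximum(total - sig, _EPS * total)
    sig = np.maximum(sig, _EPS * total)
    seg_snr = np.clip(10.0 * np.log10(sig / noise), -clamp_db, clamp_db)
    return float(seg_snr.mean())


def _minmax_component(values: np.ndarray, invert: bool) -> np.ndarray:
    lo, hi = np.min(values), np.max(values)
    if hi - lo <= _EPS * max(1.0, abs(hi), abs(lo)):
        # metric constant across ROIs: neutral contribution
        return np.full(values.shape, 0.5)
    comp = (values - lo) / (hi - lo)
    return 1.0 - comp if invert else comp


def overall_score(table: pd.DataFrame) -> pd.Series:
    """Per-ROI overall score for one activity.

    ``table`` is indexed by ROI with columns ``mae``, ``pcc``, ``snr``
    holding the participant-aggregated metric values.  Each metric is
    min-max normalized across ROIs (MAE inverted so lower error scores
    higher) and the three components are averaged.
    """
    if len(table) < 2:
        raise InputError("overall score needs >= 2 ROIs")
    if not np.all(np.isfinite(table[["mae", "pcc", "snr"]].to_numpy())):
        raise InputError("aggregated metrics must be finite")
    comps = (
        _minmax_component(table["mae"].to_numpy(), invert=True)
        + _minmax_component(table["pcc"].to_numpy(), invert=False)
        + _minmax_component(table["snr"].to_numpy(), invert=False)
    )
    return pd.Series(comps / 3.0, index=table.index, name="os")


def _window_slices(pair: PairedHR, window_seconds: float) -> list[np.ndarray]:
    t = pair.timestamps
    span = t[-1] - t[0]
    if span < window_seconds:
        raise InputError(
            f"paired series spans {span:.1f} s < one {window_seconds} s window"
        )
    n_windows = int(span // window_seconds)
    slices = []
    for i in range(n_windows):
        lo = t[0] + i * window_seconds
        hi = lo + window_seconds
        sel = (t >= lo) & ((t < hi) | ((i == n_windows - 1) & (t <= hi)))
        if sel.any():
            slices.append(np.flatnonzero(sel))
    return slices


def acceptance_rate(
    pair: PairedHR,
    window_seconds: float = ACCEPTANCE_WINDOW_S,
    threshold_bpm: float = ACCEPTANCE_THRESHOLD_BPM,
) -> float:
    """Fraction of consecutive 25 s windows whose MAE is within 10 BPM."""
    slices = _window_slices(pair, window_seconds)
    ok = 0
    for idx in slices:
        window_mae = np.mean(np.abs(pair.estimate[idx] - pair.reference[idx]))
        ok += window_mae <= threshold_bpm
    return ok / len(slices)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    window_centers: np.ndarray
    window_means: np.ndarray
    window_diffs: np.ndarray


def bland_altman(pair: PairedHR, window_seconds: float = ACCEPTANCE_WINDOW_S) -> BlandAltmanResult:
    """Bland-Altman agreement statistics on 25 s window means.

    Each window contributes one difference (window-mean estimate minus
    window-mean reference); the limits of agreement are the mean difference
    +/- 1.96 sample standard deviations.
    """
    slices = _window_slices(pair, window_seconds)
    if len(slices) < 2:
        raise InputError("Bland-Altman needs >= 2 windows")
    diffs, means, centers = [], [], []
    for idx in slices:
        e, r = pair.estimate[idx].mean(), pair.reference[idx].mean()
        diffs.append(e - r)
        means.append((e + r) / 2.0)
        centers.append(pair.timestamps[idx].mean())
    diffs = np.array(diffs)
    d = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        d, d - 1.96 * sd, d + 1.96 * sd,
        np.array(centers), np.array(means), diffs,
    )
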