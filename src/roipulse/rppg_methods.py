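"""Conversion of mean-RGB traces into pulse signals.

Four classical rPPG algorithms are implemented:

CHROM
    Chrominance combination X = 3*Rn - 2*Gn, Y = 1.5*Rn + Gn - 1.5*Bn on
    temporally normalized channels, combined as X - alpha*Y with
    alpha = sigma(X)/sigma(Y), on short Hann-weighted sub-windows that are
    overlap-added.
POS
    Projection of window-normalized channels onto the plane orthogonal to
    the skin tone, rows (0, 1, -1) and (-2, 1, 1), alpha-tuned by the
    standard-deviation ratio of the two projections, overlap-added the same
    way.
LGI
    Local group invariance: remove the leading left singular direction u of
    the RGB channel matrix with the projector P = I - u u^T and keep the
    second projected component.  Operates on the full processing span.
OMIT
    Orthogonal matrix image transformation: thin QR of the 3 x N channel
    matrix (Householder reflections), P = I - q1 q1^T from the first
    orthonormal column, pulse = second component of P applied to the
    channels.  Full span, like LGI.

All methods are invariant to a global positive rescaling of the trace (the
normalizations divide it out for CHROM/POS; for LGI/OMIT the projector is
scale-free so the output scales without moving the spectral peak), and all
outputs are returned zero-mean.

Batched variants (``*_batch``, shape ``(batch, n, 3) -> (batch, n)``) back
the per-trace API and are used directly by the study evaluation pipeline,
where thousands of ROI traces are converted at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .errors import InputError
from .roi_scheme import RGBTrace

METHODS = ("CHROM", "POS", "LGI", "OMIT")

_EPS = 1e-12
#: invalid-sample gaps up to this many seconds are linearly interpolated;
#: longer gaps split the trace into independently processed segments.
MAX_INTERP_GAP_S = 1.0


@dataclass
class RPPGSignal:
    """Estimated pulse signal at the video frame rate."""

    frame_rate: float
    values: np.ndarray
    method_tag: str
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InputError("pulse signal must be a nonempty 1-D array")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise InputError("valid_mask must match values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with degenerate denominators mapped to 0 (alpha tie rule)."""
    return np.where(np.abs(den) > _EPS, num / np.where(np.abs(den) > _EPS, den, 1.0), 0.0)


def _overlap_add(rgb: np.ndarray, fs: float, window_seconds: float, projector) -> np.ndarray:
    """Hann-weighted overlap-add of a per-window chrominance projection.

    ``projector(cn)`` maps window-normalized channels ``(B, L, 3)`` to a
    pulse chunk ``(B, L)``.
    """
    B, N, _ = rgb.shape
    L = int(round(window_seconds * fs))
    L = max(4, min(L - L % 2, N - N % 2))
    hop = L // 2
    starts = list(range(0, N - L + 1, hop))
    if starts[-1] + L < N:
        starts.append(N - L)
    win = hann(L, sym=True)
    out = np.zeros((B, N))
    wsum = np.zeros(N)
    for s in starts:
        seg = rgb[:, s : s + L, :]
        mu = seg.mean(axis=1, keepdims=True)
        cn = seg / np.where(np.abs(mu) > _EPS, mu, 1.0)
        chunk = projector(cn)
        chunk = chunk - chunk.mean(axis=1, keepdims=True)
        out[:, s : s + L] += win * chunk
        wsum[s : s + L] += win
    out /= np.maximum(wsum, _EPS)
    return out - out.mean(axis=1, keepdims=True)


def _chrom_projector(cn: np.ndarray) -> np.ndarray:
    x = 3.0 * cn[..., 0] - 2.0 * cn[..., 1]
    y = 1.5 * cn[..., 0] + cn[..., 1] - 1.5 * cn[..., 2]
    alpha = _safe_div(x.std(axis=1), y.std(axis=1))
    return x - alpha[:, None] * y


def _pos_projector(cn: np.ndarray) -> np.ndarray:
    s1 = cn[..., 1] - cn[..., 2]
    s2 = -2.0 * cn[..., 0] + cn[..., 1] + cn[..., 2]
    alpha = _safe_div(s1.std(axis=1), s2.std(axis=1))
    return s1 + alpha[:, None] * s2


def chrom_batch(rgb: np.ndarray, fs: float, window_seconds: float = 1.6) -> np.ndarray:
    return _overlap_add(rgb, fs, window_seconds, _chrom_projector)


def pos_batch(rgb: np.ndarray, fs: float, window_seconds: float = 1.6) -> np.ndarray:
    return _overlap_add(rgb, fs, window_seconds, _pos_projector)


def lgi_batch(rgb: np.ndarray, fs: float, window_seconds: float = 1.6) -> np.ndarray:
    # leading left singular vector of the 3 x N channel matrix, via the
    # 3 x 3 Gram matrix over time
    gram = np.einsum("bnc,bnd->bcd", rgb, rgb)
    _, vecs = np.linalg.eigh(gram)
    u = vecs[:, :, -1]  # (B, 3); P = I - u u^T is invariant to u's sign
    coef = np.einsum("bnc,bc->bn", rgb, u)
    proj = rgb - coef[:, :, None] * u[:, None, :]
    out = proj[..., 1]
    return out - out.mean(axis=1, keepdims=True)


def omit_batch(rgb: np.ndarray, fs: float, window_seconds: float = 1.6) -> np.ndarray:
    x = np.swapaxes(rgb, 1, 2)  # (B, 3, N)
    q, _ = np.linalg.qr(x)  # reduced: q is (B, 3, 3), Householder-based
    q1 = q[:, :, 0]  # P = I - q1 q1^T is invariant to q1's sign
    coef = np.einsum("bnc,bc->bn", rgb, q1)
    proj = rgb - coef[:, :, None] * q1[:, None, :]
    out = proj[..., 1]
    return out - out.mean(axis=1, keepdims=True)


_BATCH_FUNCS = {
    "CHROM": chrom_batch,
    "POS": pos_batch,
    "LGI": lgi_batch,
    "OMIT": omit_batch,
}


def _valid_segments(valid: np.ndarray, fs: float) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Fill short invalid gaps by linear interpolation; return the fill mask
    and the [start, stop) spans separated by gaps longer than
    ``MAX_INTERP_GAP_S`` seconds."""
    n = valid.size
    max_gap = int(round(MAX_INTERP_GAP_S * fs))
    filled = valid.copy()
    segments: list[tuple[int, int]] = []
    idx = np.flatnonzero(valid)
    seg_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            filled[prev : i + 1] = True
        else:
            segments.append((seg_start, prev + 1))
            seg_start = i
        prev = i
    segments.append((seg_start, prev + 1))
    return filled, segments


def apply_rppg(trace: RGBTrace, method: str, window_seconds: float = 1.6) -> RPPGSignal:
    """Convert one mean-RGB trace into a zero-mean pulse estimate.

    Invalid samples are linearly interpolated across gaps of at most one
    second; longer gaps split the trace into segments that are converted
    independently (the gap itself is zero-filled and marked invalid in the
    output).
    """
    if method not in METHODS:
        raise ValueError(f"unknown rPPG method {method!r}; expected one of {METHODS}")
    if trace.frame_rate <= 0:
        raise InputError("trace frame_rate must be positive")
    valid = trace.valid_mask
    if not valid.any():
        raise InputError("trace has no valid samples")
    fs = trace.frame_rate
    samples = trace.samples
    if not valid.all():
        t = np.arange(valid.size)
        samples = samples.copy()
        for ch in range(3):
            samples[:, ch] = np.interp(t, t[valid], samples[valid, ch])
    out_valid, segments = _valid_segments(valid, fs)
    func = _BATCH_FUNCS[method]
    out = np.zeros(valid.size)
    min_len = 4
    for s, e in segments:
        if e - s < min_len:
            out_valid[s:e] = False
            continue
        out[s:e] = func(samples[None, s:e, :], fs, window_seconds)[0]
    if not out_valid.any():
        raise InputError("no valid segment long enough to process")
    out[~out_valid] = 0.0
    out[out_valid] -= out[out_valid].mean()
    return RPPGSignal(fs, out, method, out_valid)
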