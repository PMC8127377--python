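"""Self-calibration of the streak noise level per scale and per horizontal
segment.

The sinogram is convolved with a separable detail filter (vertical low-pass
Gaussian x horizontal high-pass db3 wavelet) that suppresses most of the
signal while passing the streaks at known gain; a median-absolute-deviation
estimator then reads off the noise standard deviation robustly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from destreak.noise_model import CorrelationKernel, _embed_kernel, residual_streak_kernel

__all__ = [
    "DB3_HIGHPASS",
    "detail_kernel",
    "mad_std",
    "estimate_sigma",
    "calibrate_segments",
    "segment_windows",
    "CalibrationProfile",
]

# Orthonormal Daubechies-3 scaling filter and its quadrature-mirror
# high-pass; 6 taps, unit L2 norm, three vanishing moments.
_DB3_LOWPASS = np.array(
    [
        0.3326705529500825,
        0.8068915093110924,
        0.4598775021184914,
        -0.1350110200102546,
        -0.0854412738820267,
        0.0352262918857095,
    ]
)
DB3_HIGHPASS = (-1.0) ** np.arange(6) * _DB3_LOWPASS[::-1]

MAD_TO_STD = 1.4826  # reciprocal of the 0.75 standard-normal quantile


def mad_std(values) -> float:
    """Robust std estimate: 1.4826 * median(|v - median(v)|)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("mad_std needs at least 2 values")
    return float(MAD_TO_STD * np.median(np.abs(v - np.median(v))))


def _gaussian_column(m_v: int) -> np.ndarray:
    length = m_v // 2
    x = np.arange(length) - (length - 1) / 2.0
    phi = np.exp(-(x**2) / (2.0 * (m_v / 12.0) ** 2))
    return phi / phi.sum()


def detail_kernel(m_v: int) -> CorrelationKernel:
    """Separable detail filter: unit-sum vertical Gaussian of length
    ``m_v // 2`` (std ``m_v / 12``) times the unit-L2 horizontal db3
    high-pass; low-passes vertically, high-passes horizontally."""
    if m_v < 12:
        raise ValueError(f"m_v = {m_v} too small for the detail filter (need >= 12)")
    return CorrelationKernel(np.outer(_gaussian_column(m_v), DB3_HIGHPASS))


def _detail_field(S: np.ndarray) -> np.ndarray:
    """Circular convolution of the sinogram with the detail filter."""
    S = np.asarray(S, dtype=float)
    kern = detail_kernel(S.shape[0]).values
    emb = _embed_kernel(kern, S.shape)
    return np.fft.ifft2(np.fft.fft2(S) * np.fft.fft2(emb)).real


@lru_cache(maxsize=128)
def _residual_gain(width: int, mc_iters: int) -> float:
    """Per-pixel std of the detail-filtered unit-level residual streak model:
    L2 norm of the circular convolution of the db3 high-pass with the
    residual horizontal profile."""
    h = residual_streak_kernel(width, mc_iters=mc_iters)
    psi = np.zeros(width)
    psi[: DB3_HIGHPASS.size] = DB3_HIGHPASS
    conv = np.fft.ifft(np.fft.fft(psi) * np.fft.fft(h)).real
    return float(np.linalg.norm(conv))


def _gain(model: str, width: int, mc_iters: int) -> float:
    if model == "white":
        # unit-sum Gaussian passes the vertically constant streaks at gain 1;
        # the unit-L2 high-pass leaves horizontally white noise at std 1
        return float(np.linalg.norm(DB3_HIGHPASS))
    if model == "residual":
        return _residual_gain(width, mc_iters)
    raise ValueError(f"unknown noise model {model!r}")


def _row_slice(m_v: int) -> slice:
    """Rows kept in the MAD sample: half the filter height trimmed at each
    end (the sinogram is not vertically periodic)."""
    ex = (m_v // 2) // 2
    if m_v - 2 * ex < 4:
        ex = max(0, (m_v - 4) // 2)
    return slice(ex, m_v - ex)


def _sigma_from_field(D: np.ndarray, segment, model: str, mc_iters: int) -> float:
    m_v, width = D.shape
    rows = _row_slice(m_v)
    if segment is not None:
        a, b = segment
        if b - a < 12:
            raise ValueError(f"segment {segment} narrower than 12 px")
        sample = D[rows, a:b]
    else:
        sample = D[rows, :]
    return mad_std(sample) / _gain(model, width, mc_iters)


def estimate_sigma(S: np.ndarray, k: int, K: int, segment=None, mc_iters: int = 4096) -> float:
    """Streak noise level of a scale-``k`` sinogram.

    At the coarsest scale (``k == K``) the noise is modeled as horizontally
    white; at finer scales the input is expected to be the coarse-replaced
    sinogram and the residual streak model (with its Monte-Carlo gain) is
    used.
    """
    model = "white" if k == K else "residual"
    return _sigma_from_field(_detail_field(S), segment, model, mc_iters)


def segment_windows(width: int, intervals) -> dict:
    """Raised-cosine recombination windows, normalized to sum to one at
    every column (exact partition of unity)."""
    total = np.zeros(width)
    raw = {}
    for a, b in intervals:
        L = b - a
        w = np.hanning(L + 2)[1:-1]  # strictly positive raised cosine
        raw[(a, b)] = w
        total[a:b] += w
    if np.any(total <= 0):
        raise ValueError("segments do not cover the full width")
    return {iv: w / total[iv[0] : iv[1]] for iv, w in raw.items()}


@dataclass
class CalibrationProfile:
    """Per-scale, per-segment streak noise levels."""

    seg_width: int = 39
    overlap: float = 0.5
    window: str = "raised-cosine"
    scales: dict = field(default_factory=dict)  # {k: [((a, b), sigma), ...]}

    def to_dict(self) -> dict:
        return {
            "seg_width": self.seg_width,
            "overlap": self.overlap,
            "window": self.window,
            "scales": {
                str(k): [{"start": a, "stop": b, "sigma": s} for (a, b), s in rows]
                for k, rows in self.scales.items()
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _segment_intervals(width: int, seg_width: int, overlap: float):
    if width <= seg_width:
        return [(0, width)]
    step = max(1, int(round(seg_width * (1.0 - overlap))))
    starts = list(range(0, width - seg_width + 1, step))
    if starts[-1] != width - seg_width:
        starts.append(width - seg_width)
    return [(s, s + seg_width) for s in starts]


def calibrate_segments(
    S: np.ndarray,
    k: int,
    K: int,
    seg_width: int = 39,
    overlap: float = 0.5,
    mc_iters: int = 4096,
) -> CalibrationProfile:
    """Estimate the noise level on overlapping full-height segments of a
    scale-``k`` sinogram (the last segment is clamped to the right edge)."""
    S = np.asarray(S, dtype=float)
    width = S.shape[1]
    model = "white" if k == K else "residual"
    D = _detail_field(S)
    rows = [
        (iv, _sigma_from_field(D, iv, model, mc_iters))
        for iv in _segment_intervals(width, seg_width, overlap)
    ]
    return CalibrationProfile(seg_width=seg_width, overlap=overlap, scales={k: rows})
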