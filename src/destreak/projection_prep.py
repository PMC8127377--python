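"""Projection-domain preparation and end-to-end orchestration.

Bright/dark-field normalization and Beer-Lambert log transform, detection
and median repair of extreme streaks caused by defective detector pixels,
and the per-sinogram multiscale denoising loop over a projection stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "ProjectionStack",
    "DefectMask",
    "normalize_and_log",
    "angular_median",
    "detect_defective",
    "repair_columns",
    "destreak_stack",
]

logger = logging.getLogger(__name__)

_NORM_EPS = 1e-6


@dataclass
class ProjectionStack:
    """Raw or log-domain projections (angle x row x column) with fields."""

    data: np.ndarray
    bright: np.ndarray | None = None
    dark: np.ndarray | None = None
    pixel_size: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("projection stack must be 3-D (angle, row, column)")
        for name in ("bright", "dark"):
            f = getattr(self, name)
            if f is not None:
                f = np.asarray(f, dtype=float)
                if f.ndim == 3:  # multiple frames: average
                    f = f.mean(axis=0)
                if f.shape != self.data.shape[1:]:
                    raise ValueError(
                        f"{name}-field shape {f.shape} inconsistent with projections {self.data.shape[1:]}"
                    )
                setattr(self, name, f)


DefectMask = np.ndarray  # boolean (row, column)


def normalize_and_log(P_raw: np.ndarray, I_B: np.ndarray, I_D: np.ndarray | None = None, eps: float = _NORM_EPS) -> np.ndarray:
    """Bright-field the raw projections and apply the attenuation-positive
    log transform: ``P_log = -ln((P_raw - I_D) / (I_B - I_D))``.

    Multiple bright/dark frames are averaged first; the normalized
    transmission is clamped below at ``eps`` before the logarithm.
    """
    P_raw = np.asarray(P_raw, dtype=float)
    I_B = np.asarray(I_B, dtype=float)
    if I_B.ndim == 3:
        I_B = I_B.mean(axis=0)
    if I_D is None:
        I_D = np.zeros_like(I_B)
    else:
        I_D = np.asarray(I_D, dtype=float)
        if I_D.ndim == 3:
            I_D = I_D.mean(axis=0)
    denom = I_B - I_D
    bad = int(np.count_nonzero(denom <= 0))
    if bad:
        raise ValueError(f"bright-field minus dark-field nonpositive at {bad} pixels")
    P_norm = (P_raw - I_D) / denom
    n_clamped = int(np.count_nonzero(P_norm < eps))
    if n_clamped:
        logger.warning("clamped %d nonpositive transmission values at eps=%g", n_clamped, eps)
    return -np.log(np.clip(P_norm, eps, None))


def angular_median(P_log: np.ndarray) -> np.ndarray:
    """Per-pixel median across the angular (first) dimension."""
    P_log = np.asarray(P_log)
    if P_log.ndim != 3 or P_log.shape[0] < 1:
        raise ValueError("need a 3-D stack with at least one angle")
    return np.median(P_log, axis=0)


def _cubic_basis(window: int):
    """Bivariate cubic basis (10 terms) sampled on a window, and the fit
    operator pieces shared by every window position."""
    half = window // 2
    ax = (np.arange(window) - half) / max(half, 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    cols = []
    for total in range(4):
        for py in range(total + 1):
            px = total - py
            cols.append((yy**py) * (xx**px))
    A = np.stack([c.ravel() for c in cols], axis=1)  # (w*w, 10)
    pinv = np.linalg.solve(A.T @ A, A.T)  # (10, w*w)
    return ax, cols, A, pinv


def detect_defective(M: np.ndarray, window: int = 19, c_sigma: float = 5.0) -> DefectMask:
    """Mark pixels whose residual from a local bivariate cubic fit exceeds
    ``c_sigma`` times the sample std of the window residuals.

    Windows are clamped inside the image near the borders.  The least-squares
    fit is evaluated through convolutions, so the cost is independent of the
    window size beyond the FFTs.
    """
    M = np.asarray(M, dtype=float)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    h, w = M.shape
    if window > min(h, w):
        raise ValueError("window larger than image")
    ax, basis, A, pinv = _cubic_basis(window)
    nb = A.shape[1]

    # coefficient fields for every valid window center, via correlation
    kernels = [pinv[b].reshape(window, window) for b in range(nb)]
    coef = np.stack(
        [fftconvolve(M, k[::-1, ::-1], mode="valid") for k in kernels], axis=0
    )  # (10, h-w+1, w-w+1)
    tfields = np.stack([fftconvolve(M, b[::-1, ::-1], mode="valid") for b in basis], axis=0)
    # sum over window of m^2 and of fitted*m -> residual sum of squares
    n_win = window * window
    box = fftconvolve(M**2, np.ones((window, window)), mode="valid")
    rss = box - np.einsum("bxy,bxy->xy", coef, tfields)
    resid_std = np.sqrt(np.clip(rss, 0.0, None) / (n_win - nb))

    half = window // 2
    # each pixel maps to the nearest valid window center (clamped)
    ro = np.clip(np.arange(h), half, h - 1 - half) - half
    co = np.clip(np.arange(w), half, w - 1 - half) - half
    rg, cg = np.meshgrid(ro, co, indexing="ij")
    # offset of the pixel inside its (possibly clamped) window
    dy = (np.arange(h)[:, None] - (rg + half)) / max(half, 1)
    dx = (np.arange(w)[None, :] - (cg + half)) / max(half, 1)
    fit = np.zeros((h, w))
    b_idx = 0
    for total in range(4):
        for py in range(total + 1):
            px = total - py
            fit += coef[b_idx, rg, cg] * (dy**py) * (dx**px)
            b_idx += 1
    resid = M - fit
    sstd = resid_std[rg, cg]
    atol = 1e-8 * max(1.0, float(np.abs(M).max()))
    return np.abs(resid) > (c_sigma * sstd + atol)


def repair_columns(P_log: np.ndarray, mask: DefectMask, window: int = 5) -> np.ndarray:
    """Replace every pixel of a defective detector column, per angle, by the
    median of non-defective pixels in a (row, column) window around it.

    The window grows until it contains at least 3 valid pixels.  Non-masked
    pixels are untouched; repeated application with the same mask is a
    no-op.
    """
    P = np.asarray(P_log, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != P.shape[1:]:
        raise ValueError("mask shape must match (row, column) of the stack")
    h, w = mask.shape
    defect = np.argwhere(mask)
    for r, c in defect:
        half = window // 2
        while True:
            r0, r1 = max(0, r - half), min(h, r + half + 1)
            c0, c1 = max(0, c - half), min(w, c + half + 1)
            valid = ~mask[r0:r1, c0:c1]
            if valid.sum() >= 3:
                break
            if r0 == 0 and r1 == h and c0 == 0 and c1 == w:
                raise ValueError(f"no non-defective pixels available to repair ({r}, {c})")
            half += 2
        sub = P[:, r0:r1, c0:c1]
        P[:, r, c] = np.median(sub[:, valid], axis=1)
    return P


def destreak_stack(P_raw: np.ndarray, I_B: np.ndarray, I_D: np.ndarray | None = None, cfg=None):
    """Full automatic pipeline: normalize and log-transform, detect and
    repair extreme streaks, then denoise every sinogram (detector row) with
    the multiscale collaborative filter.

    Returns ``(P_log_estimate, DefectMask)`` with the estimate in the log
    domain, same shape as the input stack.
    """
    from destreak.scale_pyramid import multiscale_denoise

    if cfg is None:
        from destreak.cli_io import PipelineConfig

        cfg = PipelineConfig()
    P_log = normalize_and_log(P_raw, I_B, I_D)
    M = angular_median(P_log)
    if min(M.shape) < cfg.detect_window:
        logger.warning(
            "detector map %s smaller than the %dx%d detection window; skipping extreme-streak detection",
            M.shape, cfg.detect_window, cfg.detect_window,
        )
        mask = np.zeros(M.shape, dtype=bool)
    else:
        mask = detect_defective(M, window=cfg.detect_window, c_sigma=cfg.c_sigma)
    if mask.any():
        logger.info("repairing %d defective detector pixels", int(mask.sum()))
        P_log = repair_columns(P_log, mask, window=cfg.repair_window)
    out = np.empty_like(P_log)
    for r in range(P_log.shape[1]):
        out[:, r, :], _ = multiscale_denoise(P_log[:, r, :], cfg)
    return out, mask
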