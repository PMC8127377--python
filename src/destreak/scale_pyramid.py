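"""Binning / debinning pyramid and the coarse-to-fine multiscale denoising
recursion.

Binning replaces adjacent pixels by their SUM (so one horizontal binning of
white streak noise doubles its variance); debinning is its iterative
spline-based right inverse.  The multiscale recursion denoises the coarsest
horizontally binned sinogram first, then at each finer scale replaces the
coarse horizontal content with the coarser estimate and denoises the
residual streak noise, and finally re-injects the result into the vertical
coarse band of the full-size sinogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

__all__ = [
    "bin_axis",
    "debin_axis",
    "replace_coarse",
    "choose_scales",
    "ScaleStack",
    "build_scale_stack",
    "multiscale_denoise",
]


def bin_axis(image: np.ndarray, axis: int, factor: int) -> np.ndarray:
    """Sum non-overlapping windows of ``factor`` pixels along ``axis``.

    A tail shorter than ``factor`` is completed by edge replication before
    summing.
    """
    image = np.asarray(image, dtype=float)
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    extent = image.shape[axis]
    if factor > extent:
        raise ValueError(f"factor {factor} exceeds extent {extent} along axis {axis}")
    if factor == 1:
        return image.copy()
    x = np.moveaxis(image, axis, -1)
    pad = (-extent) % factor
    if pad:
        x = np.concatenate([x, np.repeat(x[..., -1:], pad, axis=-1)], axis=-1)
    out = x.reshape(x.shape[:-1] + (x.shape[-1] // factor, factor)).sum(axis=-1)
    return np.moveaxis(out, -1, axis)


def _spline_upsample(y: np.ndarray, target_extent: int, factor: int) -> np.ndarray:
    """Cubic-spline interpolation of coarse samples (placed at bin centers)
    onto the fine grid; operates along the last axis."""
    m_c = y.shape[-1]
    centers = factor * np.arange(m_c) + (factor - 1) / 2.0
    fine = np.arange(target_extent, dtype=float)
    k = min(3, m_c - 1)
    if k == 0:
        return np.repeat(y, target_extent, axis=-1)[..., :target_extent]
    spl = make_interp_spline(centers, y, k=k, axis=-1)
    return spl(fine)


def debin_axis(
    y: np.ndarray,
    axis: int,
    target_extent: int,
    n_iters: int = 60,
    tol: float = 1e-8,
    factor: int | None = None,
) -> np.ndarray:
    """Iterative right inverse of :func:`bin_axis`: returns ``u`` with
    ``bin_axis(u, axis, factor) == y`` within ``tol``.

    Initialized with a cubic-spline upsampling of ``y / factor``, then
    refined by ``u += upsample((y - bin(u)) / factor)``.
    """
    y = np.asarray(y, dtype=float)
    coarse = y.shape[axis]
    if factor is None:
        factor = int(math.ceil(target_extent / coarse))
    if math.ceil(target_extent / factor) != coarse:
        raise ValueError(
            f"coarse extent {coarse} inconsistent with target {target_extent} at factor {factor}"
        )
    yl = np.moveaxis(y, axis, -1)
    u = _spline_upsample(yl / factor, target_extent, factor)
    for _ in range(n_iters):
        resid = yl - np.moveaxis(bin_axis(np.moveaxis(u, -1, axis), axis, factor), axis, -1)
        if np.abs(resid).max() < tol:
            break
        u = u + _spline_upsample(resid / factor, target_extent, factor)
    return np.moveaxis(u, -1, axis)


def replace_coarse(
    Z: np.ndarray, Y_coarse: np.ndarray, axis: int = 1, factor: int = 2, n_iters: int = 60
) -> np.ndarray:
    """Replace the coarse-scale components of ``Z`` along ``axis`` by those
    of ``Y_coarse``: ``Z + debin(Y_coarse - bin(Z))``.

    Consequently ``bin(result) == Y_coarse`` within debin tolerance while
    the fine-scale detail of ``Z`` is preserved.
    """
    b = bin_axis(Z, axis, factor)
    if b.shape != np.shape(Y_coarse):
        raise ValueError(f"coarse estimate shape {np.shape(Y_coarse)} != binned shape {b.shape}")
    return Z + debin_axis(
        np.asarray(Y_coarse, dtype=float) - b, axis, Z.shape[axis], factor=factor, n_iters=n_iters
    )


def choose_scales(m: int, n: int, target_height: int = 64, min_width: int = 64) -> tuple[int, int]:
    """Vertical bin factor and number of horizontal scales.

    ``f_v`` brings the height to roughly ``target_height`` pixels; ``K``
    halves the width while the coarsest sinogram stays at least
    ``min_width`` wide (comfortably wider than the 39-pixel matching
    neighborhood).
    """
    f_v = max(1, round(m / target_height))
    K = max(0, int(math.floor(math.log2(n / min_width)))) if n >= min_width else 0
    return f_v, K


@dataclass
class ScaleStack:
    """Vertically binned sinogram and its horizontally halved versions."""

    z0: np.ndarray
    scales: list = field(default_factory=list)  # [Z_0, Z_1, ..., Z_K]
    f_v: int = 1

    @property
    def K(self) -> int:
        return len(self.scales) - 1


def build_scale_stack(Z: np.ndarray, f_v: int, K: int) -> ScaleStack:
    z0 = bin_axis(Z, axis=0, factor=f_v)
    scales = [z0]
    for _ in range(K):
        scales.append(bin_axis(scales[-1], axis=1, factor=2))
    return ScaleStack(z0=z0, scales=scales, f_v=f_v)


def _denoise_scale(S, k, K, cfg, calib, forced_rows):
    """Segmentwise collaborative filtering of one scale of the pyramid.

    All segments of a scale share the PSD shape up to the scalar noise
    level, so the covariance maps are built once per scale (for a unit
    level) and rescaled per segment.
    """
    from destreak.collaborative_filter import denoise
    from destreak.noise_calibration import calibrate_segments, segment_windows
    from destreak.noise_model import (
        CovarianceMaps,
        psd_from_kernel,
        residual_streak_kernel,
        streak_kernel,
        tile_streak_profile,
    )

    m_v, width = S.shape
    model = "white" if k == K else "residual"
    if forced_rows is not None:
        rows = forced_rows
    else:
        rows = calibrate_segments(
            S,
            k=k,
            K=K,
            seg_width=cfg.segment_width,
            overlap=cfg.segment_overlap,
            mc_iters=cfg.residual_mc_iters,
        ).scales[k]
    calib.scales[k] = rows
    wins = segment_windows(width, [iv for iv, _ in rows])
    unit_cov = {}  # segment shape -> CovarianceMaps at unit noise level
    out = np.zeros_like(S, dtype=float)
    for (a, b), sigma in rows:
        seg = S[:, a:b]
        win = wins[(a, b)]
        if sigma <= 0 or min(seg.shape) < cfg.filter.block_size:
            est = seg
        else:
            if seg.shape not in unit_cov:
                if model == "white":
                    kern = streak_kernel(m_v, 1.0)
                else:
                    prof = residual_streak_kernel(b - a, mc_iters=cfg.residual_mc_iters)
                    kern = tile_streak_profile(prof, m_v, 1.0)
                psd1 = psd_from_kernel(kern, seg.shape)
                unit_cov[seg.shape] = CovarianceMaps(psd1, cfg.filter.block_size, cfg.filter.transform_2d)
            cov = unit_cov[seg.shape].scaled(sigma**2)
            est = denoise(seg, cov.psd, cfg.filter, cov=cov)
        out[:, a:b] += est * win[None, :]
    return out


def multiscale_denoise(Z: np.ndarray, cfg=None, profile=None):
    """Coarse-to-fine multiscale streak removal of a single sinogram.

    ``Z`` must be oriented streaks-vertical (angle along rows, displacement
    along columns).  Returns ``(estimate, CalibrationProfile)``; the profile
    holds the per-scale, per-segment noise levels actually used.  Passing a
    ``profile`` (mapping scale -> segment rows) overrides self-calibration.
    """
    from destreak.noise_calibration import CalibrationProfile

    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("sinogram must be 2-D")
    if cfg is None:
        from destreak.cli_io import PipelineConfig

        cfg = PipelineConfig()
    m, n = Z.shape
    f_v_auto, K_auto = choose_scales(m, n, cfg.target_height, cfg.min_coarse_width)
    f_v = cfg.f_v if cfg.f_v is not None else f_v_auto
    K = cfg.K if cfg.K is not None else K_auto
    stack = build_scale_stack(Z, f_v, K)
    calib = CalibrationProfile(seg_width=cfg.segment_width, overlap=cfg.segment_overlap)

    def forced(k):
        if profile is None:
            return None
        rows = profile.scales if hasattr(profile, "scales") else profile
        return rows.get(k)

    y = _denoise_scale(stack.scales[K], K, K, cfg, calib, forced(K))
    for k in range(K - 1, -1, -1):
        z_tilde = replace_coarse(stack.scales[k], y, axis=1, factor=2, n_iters=cfg.debin_iters)
        y = _denoise_scale(z_tilde, k, K, cfg, calib, forced(k))
    estimate = Z + debin_axis(y - stack.z0, axis=0, target_extent=m, factor=f_v, n_iters=cfg.debin_iters)
    return estimate, calib
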