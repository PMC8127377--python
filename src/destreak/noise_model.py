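"""Stationary correlated-noise model: kernels, power spectra and exact
transform-domain coefficient variances.

The noise is modeled as ``eta = nu (*) g`` where ``nu`` is unit-variance
i.i.d. Gaussian, ``(*)`` is circular 2-D convolution and ``g`` the
correlation kernel; the per-pixel standard deviation equals ``||g||_2``.
The dual frequency-domain description is the power spectral density
``Psi = |DFT(g)|**2`` (unnormalized forward DFT, DC at the corner); with
this convention the autocovariance is ``r = IDFT(Psi)`` and
``sum(Psi) = |X| * ||g||_2**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from destreak.transforms import transform_matrix

__all__ = [
    "CorrelationKernel",
    "PowerSpectrum",
    "GroupGeometry",
    "SpectrumVariances",
    "psd_from_kernel",
    "kernel_from_psd",
    "generate_noise",
    "streak_kernel",
    "residual_streak_kernel",
    "autocovariance",
    "group_variances",
    "group_variances_dense",
    "block_difference_variances",
    "CovarianceMaps",
]

_IMAG_TOL = 1e-10


@dataclass(frozen=True)
class CorrelationKernel:
    """Convolution kernel defining noise correlation and strength.

    The L2 norm of ``values`` equals the per-pixel noise standard deviation.
    """

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("kernel must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")

    @property
    def std(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class PowerSpectrum:
    """Nonnegative PSD on a fixed support, standard DFT layout (DC at corner)."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("PSD must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("PSD must be nonnegative")

    @property
    def shape(self):
        return self.values.shape

    @property
    def pixel_variance(self) -> float:
        return float(self.values.sum() / self.values.size)


@dataclass(frozen=True)
class GroupGeometry:
    """Positions of M equally sized square blocks inside an image."""

    block_size: int
    positions: tuple
    image_shape: tuple

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(tuple(int(c) for c in p) for p in self.positions))
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))
        if len(self.positions) < 1:
            raise ValueError("a group needs at least one block")
        b = self.block_size
        h, w = self.image_shape
        for r, c in self.positions:
            if not (0 <= r <= h - b and 0 <= c <= w - b):
                raise ValueError(f"block at {(r, c)} not fully inside {self.image_shape}")

    @property
    def n_blocks(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SpectrumVariances:
    """Variance of every 3-D group-spectrum coefficient, shaped (M, N)."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < -1e-12):
            raise ValueError("variances must be nonnegative")
        object.__setattr__(self, "values", np.clip(self.values, 0.0, None))


def _embed_kernel(values: np.ndarray, shape) -> np.ndarray:
    """Embed a kernel centered at the origin of ``shape`` with wraparound."""
    kh, kw = values.shape
    h, w = shape
    if kh > h or kw > w:
        raise ValueError(f"kernel {values.shape} larger than target shape {tuple(shape)}")
    out = np.zeros(shape)
    out[:kh, :kw] = values
    return np.roll(out, (-(kh // 2), -(kw // 2)), axis=(0, 1))


def psd_from_kernel(g: CorrelationKernel, shape) -> PowerSpectrum:
    """PSD of the noise generated by kernel ``g`` on the given support."""
    emb = _embed_kernel(g.values, shape)
    return PowerSpectrum(np.abs(np.fft.fft2(emb)) ** 2)


def kernel_from_psd(psd: PowerSpectrum) -> CorrelationKernel:
    """Zero-phase root kernel of a PSD; inverse of :func:`psd_from_kernel`."""
    g = np.fft.ifft2(np.sqrt(psd.values))
    if np.abs(g.imag).max() > 1e-8 * max(1.0, np.abs(g.real).max()):
        raise ValueError("PSD does not correspond to a real zero-phase kernel")
    return CorrelationKernel(g.real)


def autocovariance(psd: PowerSpectrum) -> np.ndarray:
    """Noise autocovariance r(tau) = IDFT(Psi); r[0, 0] is the pixel variance."""
    r = np.fft.ifft2(psd.values)
    if np.abs(r.imag).max() > _IMAG_TOL * max(1.0, np.abs(r.real).max()):
        raise AssertionError("autocovariance has a non-negligible imaginary part")
    return r.real


def generate_noise(g: CorrelationKernel, shape, seed=None) -> np.ndarray:
    """Draw a correlated noise field: circular convolution of i.i.d. N(0,1)
    with ``g``.  Deterministic for a given ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nu = rng.standard_normal(shape)
    emb = _embed_kernel(g.values, shape)
    return np.fft.ifft2(np.fft.fft2(nu) * np.fft.fft2(emb)).real


def streak_kernel(height: int, sigma: float) -> CorrelationKernel:
    """Full-height constant column kernel: horizontally white, vertically
    constant streak noise with per-pixel std ``sigma``."""
    if height < 1:
        raise ValueError("height must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return CorrelationKernel(np.full((height, 1), sigma / np.sqrt(height)))


@lru_cache(maxsize=64)
def residual_streak_kernel(width: int, mc_iters: int = 4096, seed: int = 0) -> np.ndarray:
    """Unit-L2 1-D horizontal profile of the streak noise left at a scale
    after its coarse horizontal content is replaced by a perfectly denoised
    coarser estimate.

    Monte-Carlo: per iteration, draw a white row ``w`` and form the residual
    ``r = w - debin(bin(w))`` of one horizontal bin/debin level; accumulate
    the per-frequency sample standard deviation of ``DFT(r)``; the kernel is
    the zero-phase inverse transform of that profile, rescaled to unit L2.
    Input-independent, hence cached.  Tile vertically (entries divided by
    ``sqrt(height)``) to obtain the 2-D kernel.
    """
    from destreak.scale_pyramid import bin_axis, debin_axis

    if width < 4:
        raise ValueError("width must be >= 4")
    if mc_iters < 2:
        raise ValueError("mc_iters must be >= 2")
    rng = np.random.default_rng(seed)
    profile_sq = np.zeros(width)
    # chunked to bound memory at large widths / iteration counts
    chunk = max(1, int(2e6) // width)
    done = 0
    while done < mc_iters:
        n = min(chunk, mc_iters - done)
        w = rng.standard_normal((n, width))
        r = w - debin_axis(bin_axis(w, axis=1, factor=2), axis=1, target_extent=width)
        profile_sq += np.sum(np.abs(np.fft.fft(r, axis=1)) ** 2, axis=0)
        done += n
    profile = np.sqrt(profile_sq / mc_iters)
    h = np.fft.ifft(profile)
    if np.abs(h.imag).max() > 1e-8 * np.abs(h.real).max():  # pragma: no cover
        raise AssertionError("residual profile is not symmetric")
    h = h.real
    h /= np.linalg.norm(h)
    h.setflags(write=False)
    return h


def tile_streak_profile(profile: np.ndarray, height: int, sigma: float = 1.0) -> CorrelationKernel:
    """Repeat a unit-L2 1-D horizontal profile down ``height`` rows, keeping
    the 2-D kernel L2 norm equal to ``sigma``."""
    values = sigma * np.outer(np.full(height, 1.0 / np.sqrt(height)), profile)
    return CorrelationKernel(values)


# ---------------------------------------------------------------------------
# Transform-domain coefficient variances


def _basis_2d(T2D: np.ndarray) -> np.ndarray:
    """All separable 2-D basis blocks of a transform matrix, shaped (b*b, b, b)."""
    b = T2D.shape[0]
    return np.einsum("ia,jb->ijab", T2D, T2D).reshape(b * b, b, b)


class CovarianceMaps:
    """Per-2-D-coefficient covariance of blocks at every relative offset.

    For stationary noise with PSD ``Psi``, the covariance between the i-th
    2-D transform coefficient of two blocks at relative offset ``d`` is
    ``cov_i(d) = IDFT(|DFT(w_i)|^2 * Psi)(d)`` where ``w_i`` is the basis
    block embedded in the image support.  These maps make both group
    variances and block-difference matching penalties cheap lookups.
    """

    def __init__(self, psd: PowerSpectrum, block_size: int, transform_2d: str = "dct"):
        self.psd = psd
        self.block_size = int(block_size)
        self.shape = psd.shape
        T = transform_matrix(transform_2d, self.block_size)
        basis = _basis_2d(T)  # (N, b, b)
        h, w = self.shape
        if self.block_size > min(h, w):
            raise ValueError("block larger than PSD support")
        from scipy import fft as sfft

        emb = np.zeros((basis.shape[0], h, w))
        emb[:, : self.block_size, : self.block_size] = basis
        spec = np.abs(sfft.rfft2(emb, axes=(1, 2))) ** 2
        psd_half = psd.values[:, : spec.shape[2]]
        maps = sfft.irfft2(spec * psd_half[None], s=(h, w), axes=(1, 2))
        self.maps = np.ascontiguousarray(maps)  # (N, h, w)
        self._flat = self.maps.reshape(self.maps.shape[0], -1)
        self._flatT = np.ascontiguousarray(self._flat.T)  # (h*w, N): gather-friendly
        self.var0 = self.maps[:, 0, 0].copy()  # single-block coefficient variances

    def scaled(self, factor: float) -> "CovarianceMaps":
        """Cheap copy with all covariances (hence the PSD) scaled by
        ``factor``; avoids re-deriving maps when only the noise level
        changes."""
        obj = object.__new__(CovarianceMaps)
        obj.psd = PowerSpectrum(self.psd.values * factor)
        obj.block_size = self.block_size
        obj.shape = self.shape
        obj.maps = self.maps * factor
        obj._flat = obj.maps.reshape(obj.maps.shape[0], -1)
        obj._flatT = np.ascontiguousarray(obj._flat.T)
        obj.var0 = self.var0 * factor
        return obj

    def cov_at(self, dr: np.ndarray, dc: np.ndarray) -> np.ndarray:
        """Covariances for relative offsets; broadcastable integer arrays."""
        h, w = self.shape
        lin = (np.asarray(dr) % h) * w + (np.asarray(dc) % w)
        return self._flat.take(lin.ravel(), axis=1).reshape((self.maps.shape[0],) + np.shape(lin))

    def group_variances(self, positions, T1D: np.ndarray) -> np.ndarray:
        """Exact variances of the 3-D group spectrum, shaped (M, N)."""
        pos = np.asarray(positions, dtype=int)
        M = pos.shape[0]
        N = self.maps.shape[0]
        h, w = self.shape
        dr = pos[None, :, 0] - pos[:, None, 0]
        dc = pos[None, :, 1] - pos[:, None, 1]
        lin = (dr % h) * w + (dc % w)
        C = self._flatT.take(lin.ravel(), axis=0).reshape(M, M * N)  # C[a, (b, i)]
        # var[j, i] = sum_ab T1[j,a] T1[j,b] C[a,b,i], via one gemm + reduce
        Y = (T1D @ C).reshape(M, M, N)  # Y[j, b, i]
        var = np.einsum("jb,jbi->ji", T1D, Y)
        return np.clip(var, 0.0, None)

    def difference_variances(self, offset) -> np.ndarray:
        """Per-2-D-coefficient variance of the difference of two blocks at
        relative offset ``offset``: 2*(cov_i(0) - cov_i(d))."""
        d = np.asarray(offset, dtype=int)
        c = self.cov_at(d[..., 0], d[..., 1])
        return np.clip(2.0 * (self.var0.reshape((-1,) + (1,) * (c.ndim - 1)) - c), 0.0, None)


def group_variances_dense(
    psd: PowerSpectrum, geom: GroupGeometry, T2D: np.ndarray, T1D: np.ndarray
) -> SpectrumVariances:
    """Dense-covariance route: build the MN x MN pixel covariance from the
    autocovariance and project it on every tensor-product basis vector.

    Reference implementation; use :func:`group_variances` in production.
    """
    r = autocovariance(psd)
    h, w = psd.shape
    b = geom.block_size
    M = geom.n_blocks
    rows = []
    cols = []
    for pr, pc in geom.positions:
        rr, cc = np.mgrid[pr : pr + b, pc : pc + b]
        rows.append(rr.ravel())
        cols.append(cc.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    dr = rows[:, None] - rows[None, :]
    dc = cols[:, None] - cols[None, :]
    Sigma = r[dr % h, dc % w]  # (MN, MN)
    basis2 = _basis_2d(T2D).reshape(b * b, b * b)  # (N, N_pix)
    # W columns: tensor basis vectors for every (j, i)
    W = np.einsum("ja,ip->jiap", T1D, basis2).reshape(M * b * b, M * b * b)
    # variance of coefficient (j, i) = w^T Sigma w
    V = np.einsum("ka,ab,kb->k", W, Sigma, W, optimize=True)
    return SpectrumVariances(np.clip(V.reshape(M, b * b), 0.0, None))


def group_variances(
    psd: PowerSpectrum,
    geom: GroupGeometry,
    T2D=None,
    T1D=None,
    dense_limit: int = 4096,
) -> SpectrumVariances:
    """Variance of each 3-D spectrum coefficient of a block group under
    stationary noise with PSD ``psd``.

    Dense covariance computation for small problems (``M*N <= dense_limit``),
    spectral fast path above; the two routes agree on their overlap.
    """
    if psd.shape != tuple(geom.image_shape):
        raise ValueError(f"PSD shape {psd.shape} != image shape {geom.image_shape}")
    b = geom.block_size
    M = geom.n_blocks
    if T2D is None:
        T2D = transform_matrix("dct", b)
    elif isinstance(T2D, str):
        T2D = transform_matrix(T2D, b)
    if T1D is None:
        T1D = transform_matrix("haar", M)
    elif isinstance(T1D, str):
        T1D = transform_matrix(T1D, M)
    if M * b * b <= dense_limit:
        return group_variances_dense(psd, geom, T2D, T1D)
    cov = CovarianceMaps(psd, b)
    # CovarianceMaps assumes the default 2-D transform; honor custom matrices
    # through the dense route only.
    if not np.allclose(T2D, transform_matrix("dct", b)):
        return group_variances_dense(psd, geom, T2D, T1D)
    return SpectrumVariances(cov.group_variances(geom.positions, T1D))


def block_difference_variances(psd: PowerSpectrum, block_size: int, offset, transform_2d: str = "dct") -> np.ndarray:
    """Variance of each 2-D transform coefficient of the difference of two
    blocks at relative ``offset`` under noise ``psd``."""
    cov = CovarianceMaps(psd, block_size, transform_2d)
    return cov.difference_variances(offset)
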