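"""Orthonormal transform matrices used by the collaborative filter.

All transforms are returned as matrices ``T`` acting on column data as
``coeffs = T @ x``; orthonormality (``T @ T.T = I``) is required by the
transform-domain variance bookkeeping.
"""

from functools import lru_cache

import numpy as np

__all__ = ["dct_matrix", "haar_matrix", "transform_matrix"]


@lru_cache(maxsize=32)
def dct_matrix(n: int) -> np.ndarray:
    """Orthonormal DCT-II matrix of size ``n``."""
    k = np.arange(n)[:, None]
    m = np.arange(n)[None, :]
    T = np.cos(np.pi * (2 * m + 1) * k / (2 * n))
    T *= np.sqrt(2.0 / n)
    T[0] /= np.sqrt(2.0)
    return T


@lru_cache(maxsize=32)
def haar_matrix(n: int) -> np.ndarray:
    """Orthonormal Haar matrix; ``n`` must be a power of two."""
    if n < 1 or (n & (n - 1)) != 0:
        raise ValueError(f"Haar transform length must be a power of two, got {n}")
    T = np.array([[1.0]])
    while T.shape[0] < n:
        s = 1.0 / np.sqrt(2.0)
        top = np.kron(T, [s, s])
        bottom = np.kron(np.eye(T.shape[0]), [s, -s])
        T = np.vstack([top, bottom])
    return T


def transform_matrix(name: str, n: int) -> np.ndarray:
    """Look up an orthonormal transform by name ("dct", "haar" or "identity")."""
    if name == "dct":
        return dct_matrix(n)
    if name == "haar":
        return haar_matrix(n)
    if name in ("identity", "eye"):
        return np.eye(n)
    raise ValueError(f"unknown transform {name!r}")
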