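"""Low-level numeric kernels and an internal buffer pool.

Panel regressions at full scale touch ~60 MB matrices; repeated fresh
allocations dominate runtime on constrained machines, so the fitting path
reuses preallocated workspaces and fuses the group-demeaning passes.  The
numba-compiled kernels fall back to equivalent (slower) numpy code when numba
is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _demean_sweep_nb(Z, codes, cnt, m):  # pragma: no cover - compiled
    n, k = Z.shape
    m[:, :] = 0.0
    for i in range(n):
        c = codes[i]
        for j in range(k):
            m[c, j] += Z[i, j]
    mx = 0.0
    for g in range(m.shape[0]):
        inv = 1.0 / cnt[g]
        for j in range(k):
            m[g, j] *= inv
            a = abs(m[g, j])
            if a > mx:
                mx = a
    for i in range(n):
        c = codes[i]
        for j in range(k):
            Z[i, j] -= m[c, j]
    return mx


def _demean_sweep_np(Z, codes, cnt, m):
    m[:, :] = 0.0
    for j in range(Z.shape[1]):
        m[:, j] = np.bincount(codes, weights=Z[:, j], minlength=m.shape[0])
    m /= cnt[:, None]
    Z -= m[codes]
    return float(np.abs(m).max())


def demean_sweep(Z, codes, cnt, m) -> float:
    """Subtract group means of every column of Z in place; returns the
    largest absolute group mean removed."""
    if HAVE_NUMBA:
        return float(_demean_sweep_nb(Z, codes, cnt, m))
    return _demean_sweep_np(Z, codes, cnt, m)


@njit(cache=True)
def _cluster_scores_nb(X, resid, clusters, H):  # pragma: no cover - compiled
    H[:, :] = 0.0
    for i in range(X.shape[0]):
        c = clusters[i]
        r = resid[i]
        for j in range(X.shape[1]):
            H[c, j] += X[i, j] * r
    return H


def cluster_scores(X, resid, clusters, n_clusters) -> np.ndarray:
    """Per-cluster score sums: H[g] = sum_{i in g} X_i * u_i."""
    H = np.zeros((n_clusters, X.shape[1]))
    if HAVE_NUMBA:
        _cluster_scores_nb(X, resid, clusters, H)
        return H
    for j in range(X.shape[1]):
        H[:, j] = np.bincount(clusters, weights=X[:, j] * resid, minlength=n_clusters)
    return H


# -- buffer pool --------------------------------------------------------------

_POOL: dict[tuple, np.ndarray] = {}


def pooled(key: str, shape: tuple[int, ...], order: str = "C") -> np.ndarray:
    """A reusable uninitialized array of the requested shape.

    Buffers are cached by (key, trailing shape, order) and grown as needed;
    the returned view aliases the cache, so a caller must be done with the
    previous array of the same key before requesting another.
    """
    n, rest = shape[0], tuple(shape[1:])
    buf = _POOL.get((key, rest, order))
    if buf is None or buf.shape[0] < n:
        cap = int(n * 1.1) + 64
        buf = np.empty((cap,) + rest, order=order)
        _POOL[(key, rest, order)] = buf
    return buf[:n]


def clear_pool() -> None:
    _POOL.clear()
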