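"""Canonical correlation analysis and correlation primitives.

Every recognizer in this package is built on four primitives: full CCA
between two multi-channel views (rows are variables, columns are time
samples), its first canonical correlation, the plain Pearson correlation of
two 1-D projections, and a two-dimensional "matrix correlation" (Pearson
correlation of the flattened matrices) used by ensemble spatial filters.

The CCA solver whitens the two covariance blocks and takes the SVD of the
whitened cross-covariance, which is numerically stabler than a direct
eigendecomposition.  A tiny ridge proportional to the trace is added when a
block is rank-deficient (e.g. a constant channel).  Weight signs are fixed
by convention — the largest-magnitude entry of each first-view weight is
made positive and the paired second-view weight is flipped with it — so
that signed downstream correlations are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = ["CcaResult", "cca", "max_canonical_correlation", "pearson", "matrix_correlation"]

_RIDGE_SCALE = 1e-10


@dataclass
class CcaResult:
    """Canonical correlations (descending) and projection weights.

    ``Wx`` is (p, k), ``Wy`` is (q, k); column j of each projects its view
    onto the j-th canonical variate, with corr(WxjᵀX, WyjᵀY) = rho[j].
    """

    rho: np.ndarray
    Wx: np.ndarray
    Wy: np.ndarray


def _whitener(C: np.ndarray) -> np.ndarray:
    """Inverse principal square root of a symmetric PSD matrix, ridged if needed."""
    d = C.shape[0]
    ridge = _RIDGE_SCALE * np.trace(C) / d
    if ridge <= 0:
        raise ValueError("zero covariance: input has no variance at all")
    w, V = linalg.eigh(C + ridge * np.eye(d))
    tiny = w <= d * np.finfo(float).eps * w.max()
    if np.any(tiny):
        logger.warning("rank-deficient covariance block; regularized solve")
        w = np.maximum(w, d * np.finfo(float).eps * w.max())
    return V @ np.diag(w**-0.5) @ V.T


def cca(X: np.ndarray, Y: np.ndarray) -> CcaResult:
    """Canonical correlation analysis of two views sampled on a common time axis.

    Parameters
    ----------
    X : ndarray, shape (p, Ns)
    Y : ndarray, shape (q, Ns)
        Rows are variables (channels/harmonics), columns are time samples.

    Returns
    -------
    CcaResult with ``k = min(p, q)`` canonical pairs.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if Y.ndim == 1:
        Y = Y[None, :]
    if X.shape[1] != Y.shape[1]:
        raise ValueError("views must share the sample axis")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite input")
    if not (np.any(X) and np.any(Y)):
        raise ValueError("all-zero view has no canonical directions")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ns = X.shape[1]
    Cxx = Xc @ Xc.T / ns
    Cyy = Yc @ Yc.T / ns
    Cxy = Xc @ Yc.T / ns
    Kx = _whitener(Cxx)
    Ky = _whitener(Cyy)
    U, s, Vt = linalg.svd(Kx @ Cxy @ Ky, full_matrices=False)
    k = min(X.shape[0], Y.shape[0])
    rho = np.clip(s[:k], 0.0, 1.0 + 1e-10)
    Wx = Kx @ U[:, :k]
    Wy = Ky @ Vt.T[:, :k]
    # sign convention: dominant entry of each Wx column positive; flip pairs
    for j in range(k):
        i = int(np.argmax(np.abs(Wx[:, j])))
        if Wx[i, j] < 0:
            Wx[:, j] *= -1
            Wy[:, j] *= -1
    return CcaResult(rho=rho, Wx=Wx, Wy=Wy)


def max_canonical_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """First canonical correlation between two views (see :func:`cca`)."""
    return float(cca(X, Y).rho[0])


def center_whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center a view's rows and return (centered data, covariance whitener).

    Precomputation hook for scoring one view against many fixed partners:
    with ``(Xc, Kx)`` and ``(Yc, Ky)`` from this function, the first
    canonical correlation is the largest singular value of
    ``Kx @ (Xc @ Yc.T / Ns) @ Ky`` (see :func:`max_corr_precomputed`).
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    return Xc, _whitener(Xc @ Xc.T / X.shape[1])


def max_corr_precomputed(
    Xc: np.ndarray, Kx: np.ndarray, Yc: np.ndarray, Ky: np.ndarray
) -> float:
    """First canonical correlation from :func:`center_whiten` outputs."""
    M = Kx @ (Xc @ Yc.T / Xc.shape[1]) @ Ky
    s = linalg.svdvals(M)
    return float(np.clip(s[0], 0.0, 1.0 + 1e-10))


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two 1-D signals; 0 (with warning) if degenerate.

    A zero-variance input makes the correlation undefined; such projections
    carry no stimulus information, so the feature is set to 0.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    if u.size < 2:
        raise ValueError("need at least two samples")
    uc = u - u.mean()
    vc = v - v.mean()
    su = np.sqrt(uc @ uc)
    sv = np.sqrt(vc @ vc)
    if su == 0.0 or sv == 0.0:
        logger.warning("zero-variance input to pearson; returning 0")
        return 0.0
    return float(np.clip((uc @ vc) / (su * sv), -1.0, 1.0))


def matrix_correlation(A: np.ndarray, B: np.ndarray) -> float:
    """Two-dimensional correlation: Pearson correlation of the flattened matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return pearson(A.ravel(), B.ravel())
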