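"""Poisson-NMF primitives: the GKL objective, multiplicative updates, row normalization.

The model is ``V ~ Poisson(WH)`` with W (cells x K) and H (K x genes) nonnegative
and the rows of H constrained to sum to one, which removes the scale ambiguity of
the factorization. Maximizing the Poisson likelihood is equivalent to minimizing
the generalized Kullback-Leibler divergence D(V || WH), and the multiplicative
updates below never increase it.

All routines accept the count matrix either dense (ndarray) or sparse (CSR);
with sparse counts the elementwise ratio V / (WH) is only evaluated at the
stored nonzeros, which is what makes the updates cheap on large sparse data.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = ["rnorm", "gkl_divergence", "update_h", "update_w"]


def _values(V):
    return V.values if isinstance(V, CountMatrix) else V


def rnorm(A):
    """Row-normalize a nonnegative matrix so every row sums to one.

    Rows that sum to zero are returned as all-zero rows: there is no
    distribution to renormalize, and the fitting layer is responsible for
    detecting dead signatures.
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("rnorm requires a nonnegative matrix")
    s = A.sum(axis=1, keepdims=True)
    out = np.divide(A, s, out=np.zeros_like(A), where=s > 0)
    return out


def _check_shapes(V, W, H):
    N, M = V.shape
    if W.shape[0] != N or H.shape[1] != M or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"shapes do not conform: V {V.shape}, W {W.shape}, H {H.shape}"
        )


def _ratio_dense(V, WH):
    """V / WH with the 0/0 = 0 convention; V>0 over WH=0 is a modeling failure."""
    pos = V > 0
    if np.any(pos & (WH <= 0)):
        raise ZeroDivisionError(
            "reconstruction WH is zero where the data has positive counts "
            "(infinite GKL divergence)"
        )
    return np.divide(V, WH, out=np.zeros_like(WH), where=pos)


def _wh_at_nonzeros(V, W, H):
    """(WH) evaluated only at the stored coordinates of sparse V."""
    coo = V.tocoo()
    wh = np.einsum("ij,ij->i", W[coo.row], H[:, coo.col].T)
    return coo, wh


def _ratio_sparse(V, W, H):
    coo, wh = _wh_at_nonzeros(V, W, H)
    if np.any((coo.data > 0) & (wh <= 0)):
        raise ZeroDivisionError(
            "reconstruction WH is zero where the data has positive counts "
            "(infinite GKL divergence)"
        )
    data = np.divide(coo.data, wh, out=np.zeros_like(wh), where=coo.data > 0)
    return sp.csr_matrix((data, (coo.row, coo.col)), shape=V.shape)


def gkl_divergence(V, W, H) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH).

    Computes ``sum_{nm} V log V - V log(WH) - V + (WH)`` with the convention
    0 log 0 = 0. Nonnegative, and zero exactly when V equals WH elementwise.
    Raises ZeroDivisionError when some positive count sits on a zero of WH,
    where the divergence is infinite.
    """
    V = _values(V)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    _check_shapes(V, W, H)
    # sum(WH) = (column sums of W) . (row sums of H), cheap for any sparsity
    total_wh = float(W.sum(axis=0) @ H.sum(axis=1))
    if sp.issparse(V):
        coo, wh = _wh_at_nonzeros(V, W, H)
        v = coo.data
        pos = v > 0
        if np.any(pos & (wh <= 0)):
            raise ZeroDivisionError(
                "reconstruction WH is zero where the data has positive counts"
            )
        vlog = np.where(pos, v * np.log(np.where(pos, v, 1.0)), 0.0)
        vlogwh = np.where(pos, v * np.log(np.where(pos, wh, 1.0)), 0.0)
        return float(vlog.sum() - vlogwh.sum() - v.sum() + total_wh)
    V = np.asarray(V, dtype=float)
    WH = W @ H
    pos = V > 0
    if np.any(pos & (WH <= 0)):
        raise ZeroDivisionError(
            "reconstruction WH is zero where the data has positive counts"
        )
    vlog = np.where(pos, V * np.log(np.where(pos, V, 1.0)), 0.0)
    vlogwh = np.where(pos, V * np.log(np.where(pos, WH, 1.0)), 0.0)
    return float(vlog.sum() - vlogwh.sum() - V.sum() + total_wh)


def _ratio(V, W, H):
    if sp.issparse(V):
        return _ratio_sparse(V, W, H)
    return _ratio_dense(np.asarray(V, dtype=float), W @ H)


def update_h(V, W, H) -> np.ndarray:
    """One multiplicative update of the signature matrix H.

    Returns ``rnorm(H * (W^T (V / WH)))``. Zero entries of H stay exactly
    zero, and every output row sums to one.
    """
    V = _values(V)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    _check_shapes(V, W, H)
    R = _ratio(V, W, H)
    if sp.issparse(R):
        numer = H * (R.T @ W).T
    else:
        numer = H * (W.T @ R)
    return rnorm(numer)


def update_w(V, W, H) -> np.ndarray:
    """One multiplicative update of the weight matrix W: ``W * ((V / WH) H^T)``.

    No normalization is applied; zeros of W are preserved (0/0 = 0), so an
    all-zero row (a cell with no counts) stays all-zero without producing NaN.
    """
    V = _values(V)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    _check_shapes(V, W, H)
    R = _ratio(V, W, H)
    return W * (R @ H.T)
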