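"""Fitting the neighborhood-smoothed Poisson NMF.

Each iteration applies the two multiplicative Poisson-NMF updates and then
replaces every cell's weight vector by a Gaussian-kernel-weighted average of
its (same-batch) neighbors' weights:

    H <- rnorm(H * (W^T (V / WH)))
    W <- W * ((V / WH) H^T)
    W <- rnorm(S_phi) W          (per batch)

With the identity kernel (phi = 0, no smoothing) the iteration is exactly
plain Poisson NMF and the GKL objective is non-increasing. The smoothing step
can transiently raise the objective, so the trace is monitored for relative
change rather than asserted monotone.

Rank selection uses AIC = 2 * D(V || WH) + 2 * (N*K + K*M), computed on the
fitted (smoothed) factors; warm starts share one seed family across ranks so
AIC differences reflect K rather than initialization luck.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .containers import (
    BatchPartition,
    CountMatrix,
    FactorPair,
    FitResult,
    ModelScan,
    SmoothingKernel,
)
from .core import gkl_divergence, rnorm, update_h, update_w
from .spatial import gaussian_kernel, select_length_scale

__all__ = [
    "warm_start",
    "smoothing_update",
    "fit_nnmf",
    "aic",
    "select_k",
    "default_phi_grid",
]

logger = logging.getLogger(__name__)

#: cells above which per-batch kernels are truncated and stored sparse
DENSE_KERNEL_LIMIT = 6000


def _values(V):
    return V.values if isinstance(V, CountMatrix) else V


def warm_start(V, K: int, n_init: int = 3, n_iter: int = 100, seed: int = 0) -> FactorPair:
    """Best of several short plain-NMF runs, used to initialize the smoothed fit.

    Runs ``n_init`` independent plain Poisson-NMF fits of ``n_iter`` iterations
    from uniform(0, 1) random starts and returns the factor pair with the
    smallest GKL. Deterministic given the seed.
    """
    Vv = _values(V)
    N, M = Vv.shape
    if K > min(N, M):
        raise ValueError(f"rank K={K} exceeds min(N, M)={min(N, M)}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if n_init < 3:
        logger.warning("warm start with fewer than 3 initializations (n_init=%d)", n_init)
    rng = np.random.default_rng(seed)
    best: Optional[FactorPair] = None
    best_gkl = np.inf
    for _ in range(n_init):
        W = rng.uniform(size=(N, K))
        H = rnorm(rng.uniform(size=(K, M)))
        for _ in range(n_iter):
            H = update_h(Vv, W, H)
            W = update_w(Vv, W, H)
        g = gkl_divergence(Vv, W, H)
        if g < best_gkl:
            best_gkl = g
            best = FactorPair(W=W, H=H)
    return best


def smoothing_update(
    W: np.ndarray,
    kernels: Sequence[SmoothingKernel],
    batches: Optional[BatchPartition] = None,
) -> np.ndarray:
    """Replace each row of W by the kernel-weighted average of its batch's rows.

    ``W^b <- rnorm(S^b) W^b`` for every batch b. With ``batches=None`` a single
    kernel covering all rows is expected. Each output row is a convex
    combination of same-batch input rows, so nonnegativity is preserved.
    """
    W = np.asarray(W, dtype=float)
    if batches is None:
        if len(kernels) != 1 or kernels[0].n != W.shape[0]:
            raise ValueError("without batches, exactly one full-size kernel is required")
        return np.asarray(kernels[0].row_normalized @ W)
    if len(kernels) != batches.n_batches:
        raise ValueError("one kernel per batch is required")
    out = np.empty_like(W)
    for kernel, idx in zip(kernels, batches.indices()):
        if kernel.n != idx.size:
            raise ValueError("kernel size does not match batch size")
        out[idx] = kernel.row_normalized @ W[idx]
    return out


def default_phi_grid(X, num: int = 8) -> np.ndarray:
    """Geometric grid of candidate length scales spanning the coordinate extent.

    Ranges from roughly one percent to one half of the bounding-box diagonal,
    a span that brackets neighborhood sizes from a few cells to most of a slice.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    diag = float(np.linalg.norm(X.max(axis=0) - X.min(axis=0)))
    if diag <= 0:
        raise ValueError("degenerate coordinates: all cells coincide")
    return diag * np.geomspace(0.01, 0.5, num)


def _build_kernels(X, phi, batches, cutoff):
    kernels = []
    for idx in batches.indices():
        c = cutoff
        if c is None and idx.size > DENSE_KERNEL_LIMIT:
            c = 3.0
        kernels.append(gaussian_kernel(X[idx], phi, cutoff=c))
    return kernels


def fit_nnmf(
    V,
    X=None,
    K: int = 10,
    phi: Optional[float] = None,
    phi_grid=None,
    batches: Optional[BatchPartition] = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    n_init: int = 3,
    warm_iter: int = 100,
    smooth_every: int = 1,
    kernel_cutoff: Optional[float] = None,
    init: Optional[FactorPair] = None,
    kernels: Optional[Sequence[SmoothingKernel]] = None,
) -> FitResult:
    """Fit the neighborhood-smoothed Poisson NMF.

    Parameters
    ----------
    V : counts, cells x genes (CountMatrix, ndarray, or CSR)
    X : cell coordinates (N x d); may be omitted when ``phi=0`` (plain NMF)
    K : number of signatures
    phi : kernel length scale. ``None`` estimates it by the leave-self-out
        grid search; ``0`` disables smoothing (identity kernel), reducing the
        fit to plain Poisson NMF.
    batches : spatial batching; ``None`` uses a single batch over all cells
    max_iter, tol : stop when ``|delta GKL| / max(GKL, 1) < tol`` or after
        ``max_iter`` iterations (then ``converged=False``, no exception)
    seed, n_init, warm_iter : warm-start configuration
    smooth_every : apply the smoothing step every n-th iteration (default 1)
    kernel_cutoff : truncate kernels at ``cutoff * phi`` (sparse storage);
        ``None`` keeps small batches dense and truncates only large ones
    init : optional precomputed warm start (overrides the internal one)
    kernels : optional precomputed per-batch kernels (must match ``phi``)
    """
    Vv = _values(V)
    N = Vv.shape[0]

    smoothing = True
    if phi is None:
        if X is None:
            raise ValueError("coordinates are required to estimate phi")
        grid = default_phi_grid(X) if phi_grid is None else phi_grid
        phi, _ = select_length_scale(Vv, X, grid)
        logger.info("selected length scale phi=%g", phi)
    elif phi == 0:
        smoothing = False
        phi = 0.0
    if smoothing and X is None and kernels is None:
        raise ValueError("coordinates (or precomputed kernels) are required when phi > 0")

    if batches is None:
        batches = BatchPartition.single(N)
    if smoothing and kernels is None:
        from .spatial import _coords

        kernels = _build_kernels(_coords(X), phi, batches, kernel_cutoff)

    pair = init if init is not None else warm_start(Vv, K, n_init=n_init, n_iter=warm_iter, seed=seed)
    W, H = pair.W.copy(), rnorm(pair.H)

    trace = [gkl_divergence(Vv, W, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H = update_h(Vv, W, H)
        W = update_w(Vv, W, H)
        if smoothing and it % smooth_every == 0:
            W = smoothing_update(W, kernels, batches)
        g = gkl_divergence(Vv, W, H)
        trace.append(g)
        if abs(trace[-2] - g) / max(g, 1.0) < tol:
            converged = True
            break

    dead = np.flatnonzero(~W.any(axis=0))
    if dead.size:
        logger.warning(
            "fit has %d dead signature(s) (all-zero W column): %s",
            dead.size,
            (dead + 1).tolist(),
        )
    return FitResult(
        factors=FactorPair(W=W, H=H),
        phi=float(phi),
        gkl_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        seed=seed,
        batches=batches,
        effective_rank=K - dead.size,
    )


def aic(V, W, H) -> float:
    """Akaike information criterion: ``2 D(V||WH) + 2 (N*K + K*M)``.

    The Poisson log-likelihood is, up to a constant in the parameters, the
    negative GKL divergence, so AIC reduces to the divergence plus a penalty
    counting every entry of W and H.
    """
    W = np.asarray(W, dtype=float)
    N, K = W.shape
    M = np.asarray(H).shape[1]
    return 2.0 * gkl_divergence(V, W, H) + 2.0 * (N * K + K * M)


def select_k(V, X, K_grid, keep_fits: bool = False, **fit_kwargs) -> ModelScan:
    """Fit every candidate rank and pick the one minimizing AIC.

    The same warm-start seed is used for every K so that AIC differences
    reflect the rank rather than initialization luck; ties are broken toward
    the smaller K. Kernels are built once and shared across the ranks. A fit
    with dead signatures contributes its effective (nonzero) rank to the log
    but its AIC is computed at the nominal parameter count.
    """
    K_grid = [int(k) for k in K_grid]
    if not K_grid:
        raise ValueError("K_grid must be non-empty")
    Vv = _values(V)

    phi = fit_kwargs.pop("phi", None)
    batches = fit_kwargs.get("batches")
    kernels = fit_kwargs.pop("kernels", None)
    if phi is None:
        grid = fit_kwargs.pop("phi_grid", None)
        if grid is None:
            grid = default_phi_grid(X)
        phi, _ = select_length_scale(Vv, X, grid)
    if phi != 0 and kernels is None and X is not None:
        from .spatial import _coords

        b = batches if batches is not None else BatchPartition.single(Vv.shape[0])
        fit_kwargs.setdefault("batches", b)
        kernels = _build_kernels(_coords(X), phi, b, fit_kwargs.get("kernel_cutoff"))

    aics, n_prms, fits = [], [], []
    for K in K_grid:
        res = fit_nnmf(Vv, X, K=K, phi=phi, kernels=kernels, **fit_kwargs)
        if res.effective_rank < K:
            logger.warning("K=%d fit has effective rank %d", K, res.effective_rank)
        aics.append(aic(Vv, res.W, res.H))
        n_prms.append(Vv.shape[0] * K + K * Vv.shape[1])
        fits.append(res)
    aics = np.asarray(aics)
    best = min(range(len(K_grid)), key=lambda i: (aics[i], K_grid[i]))
    return ModelScan(
        K_grid=K_grid,
        aic_values=aics,
        n_prm_values=np.asarray(n_prms),
        best_K=K_grid[best],
        fits=fits if keep_fits else None,
    )
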