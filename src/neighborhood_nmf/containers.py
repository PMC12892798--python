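"""Shared data containers for counts, coordinates, factors and fit results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import scipy.sparse as sp

Matrix = "np.ndarray | sp.spmatrix"


def is_sparse(A) -> bool:
    return sp.issparse(A)


def as_dense(A) -> np.ndarray:
    """Densify a matrix if it is sparse; pass ndarrays through."""
    if sp.issparse(A):
        return np.asarray(A.todense())
    return np.asarray(A)


@dataclass
class CountMatrix:
    """A cells-by-genes matrix of nonnegative transcript counts.

    ``values`` may be a dense ndarray or a scipy CSR matrix; all numeric
    routines accept either representation. Cell and gene identifiers are
    carried along for alignment with coordinate tables and output files.
    """

    values: "np.ndarray | sp.csr_matrix"
    cell_ids: Optional[Sequence[str]] = None
    gene_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        V = self.values
        if V.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        data = V.data if sp.issparse(V) else V
        if not np.all(np.isfinite(data)):
            raise ValueError("count matrix contains non-finite entries")
        if data.size and data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i + 1}" for i in range(V.shape[0])]
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{j + 1}" for j in range(V.shape[1])]
        if len(self.cell_ids) != V.shape[0] or len(self.gene_ids) != V.shape[1]:
            raise ValueError("identifier lengths do not match matrix shape")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class SpatialCoords:
    """N x d matrix of cell locations, d in {1, 2, 3}, rows aligned to counts."""

    X: np.ndarray
    cell_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[1] not in (1, 2, 3):
            raise ValueError(f"coordinates must have 1-3 columns, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("coordinates contain non-finite entries")
        self.X = X

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class FactorPair:
    """A weight matrix W (cells x K) and a row-stochastic signature matrix H (K x genes)."""

    W: np.ndarray
    H: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 2 or self.H.ndim != 2 or self.W.shape[1] != self.H.shape[0]:
            raise ValueError("W and H shapes do not conform")
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("factors must be nonnegative")

    @property
    def K(self) -> int:
        return self.W.shape[1]

    @property
    def WH(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class BatchPartition:
    """Assignment of each cell to exactly one spatially compact batch."""

    assignment: np.ndarray
    seed: Optional[int] = None
    labels: Optional[Sequence] = None  # original batch names, e.g. slice ids

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be a flat vector")
        if self.assignment.size and self.assignment.min() < 0:
            raise ValueError("assignment contains negative batch indices")

    @property
    def n_batches(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_batches)

    def indices(self) -> Iterator[np.ndarray]:
        """Yield the cell-index array of each batch, in batch order."""
        for b in range(self.n_batches):
            yield np.flatnonzero(self.assignment == b)

    @classmethod
    def single(cls, n: int) -> "BatchPartition":
        return cls(assignment=np.zeros(n, dtype=int))


@dataclass
class SmoothingKernel:
    """Gaussian neighborhood kernel S over one batch plus its row-stochastic form."""

    S: "np.ndarray | sp.csr_matrix"
    phi: float
    _row_normalized: Optional["np.ndarray | sp.csr_matrix"] = field(
        default=None, repr=False
    )

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def row_normalized(self):
        """rnorm(S): rows rescaled to sum to one (the diagonal is 1, so no zero rows)."""
        if self._row_normalized is None:
            if sp.issparse(self.S):
                inv = 1.0 / np.asarray(self.S.sum(axis=1)).ravel()
                self._row_normalized = sp.diags(inv) @ self.S.tocsr()
            else:
                self._row_normalized = self.S / self.S.sum(axis=1, keepdims=True)
        return self._row_normalized


@dataclass
class FitResult:
    """Converged factors plus the objective trace and convergence metadata."""

    factors: FactorPair
    phi: float
    gkl_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: Optional[int]
    batches: Optional[BatchPartition]
    effective_rank: int

    @property
    def W(self) -> np.ndarray:
        return self.factors.W

    @property
    def H(self) -> np.ndarray:
        return self.factors.H

    @property
    def K(self) -> int:
        return self.factors.K

    @property
    def final_gkl(self) -> float:
        return float(self.gkl_trace[-1])


@dataclass
class ModelScan:
    """AIC curve over candidate ranks K and the selected rank."""

    K_grid: Sequence[int]
    aic_values: np.ndarray
    n_prm_values: np.ndarray
    best_K: int
    fits: Optional[Sequence[FitResult]] = None


@dataclass
class SyntheticDataset:
    """Poisson spatial counts with the generating factors kept as ground truth."""

    V: np.ndarray
    X: SpatialCoords
    W_true: np.ndarray
    H_true: np.ndarray
    phi_true: float
    seed: int

    @property
    def counts(self) -> CountMatrix:
        return CountMatrix(values=self.V)
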