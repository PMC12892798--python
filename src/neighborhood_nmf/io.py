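"""Reading counts and coordinates; writing fit results and simulated data.

Counts are accepted as MatrixMarket (.mtx, coordinate integer format) or as
delimited text with cell identifiers in the first column and gene identifiers
in the header. Matrices denser than 20% are kept as ndarrays, sparser ones as
CSR; every numeric routine in the package accepts both. All user-facing tables
number signatures and clusters from 1; internal indexing is 0-based.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, FitResult, SpatialCoords, as_dense

__all__ = [
    "read_counts",
    "read_coords",
    "filter_genes",
    "write_counts",
    "write_coords",
    "write_result",
    "read_factors",
]

logger = logging.getLogger(__name__)

SPARSE_DENSITY = 0.2


def _maybe_sparsify(V: np.ndarray):
    density = np.count_nonzero(V) / max(V.size, 1)
    return sp.csr_matrix(V) if density < SPARSE_DENSITY else V


def read_counts(
    path,
    fmt: Optional[str] = None,
    transpose: bool = False,
    min_gene_fraction: float = 0.0,
) -> CountMatrix:
    """Read a cells-by-genes count matrix from .mtx or delimited text.

    For delimited text the first column holds cell identifiers and the header
    holds gene identifiers; a header whose first field starts with "gene"
    signals a genes-by-cells layout and is transposed automatically. The
    ``transpose`` flag overrides any heuristic. Negative or non-finite entries
    are rejected. ``min_gene_fraction`` drops genes expressed (count > 0) in
    fewer than that fraction of cells.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".mtx": "mtx", ".csv": "csv"}.get(suffix, "tsv")
    if fmt == "mtx":
        V = scipy.io.mmread(path)
        V = sp.csr_matrix(V)
        if transpose:
            V = V.T.tocsr()
        cm = CountMatrix(values=V if V.nnz / max(np.prod(V.shape), 1) < SPARSE_DENSITY else as_dense(V))
    elif fmt in ("tsv", "csv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if str(df.index.name or "").lower().startswith("gene") and not transpose:
            df = df.T
        if transpose:
            df = df.T
        V = df.to_numpy(dtype=float)
        cm = CountMatrix(
            values=_maybe_sparsify(V),
            cell_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
        )
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    if min_gene_fraction > 0:
        cm = filter_genes(cm, min_gene_fraction)
    return cm


def filter_genes(counts: CountMatrix, min_fraction: float) -> CountMatrix:
    """Drop genes expressed in fewer than ``min_fraction`` of the cells."""
    V = counts.values
    expressed = np.asarray((V > 0).sum(axis=0)).ravel() / counts.n_cells
    keep = expressed >= min_fraction
    logger.info("gene filter kept %d of %d genes", int(keep.sum()), counts.n_genes)
    Vk = V[:, keep] if not sp.issparse(V) else V.tocsc()[:, keep].tocsr()
    return CountMatrix(
        values=Vk,
        cell_ids=list(counts.cell_ids),
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
    )


def read_coords(path, cell_ids: Optional[Sequence[str]] = None, expect_3d: bool = False):
    """Read a coordinate table (columns x, y[, z]; optional cell_id and slice).

    When ``cell_ids`` is given, rows are realigned to that order by identifier
    and a mismatch in the cell sets is a hard error. Returns
    ``(SpatialCoords, slice_labels or None)``.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    axes = [a for a in ("x", "y", "z") if a in cols]
    if not axes:
        raise ValueError("coordinate table must contain columns x[, y[, z]]")
    if expect_3d and "z" not in cols:
        raise ValueError("3D requested but the coordinate table has no z column")
    if cell_ids is not None:
        if "cell_id" not in cols:
            if len(df) != len(cell_ids):
                raise ValueError(
                    f"coordinate rows ({len(df)}) do not match counts cells "
                    f"({len(cell_ids)}) and no cell_id column is present"
                )
        else:
            df = df.set_index(df[cols["cell_id"]].astype(str))
            missing = [c for c in cell_ids if c not in df.index]
            if missing:
                raise ValueError(
                    f"{len(missing)} cell(s) in the counts have no coordinates "
                    f"(first missing: {missing[0]})"
                )
            df = df.loc[list(cell_ids)]
    X = df[[cols[a] for a in axes]].to_numpy(dtype=float)
    slices = None
    if "slice" in cols:
        slices = df[cols["slice"]].to_numpy()
    ids = list(cell_ids) if cell_ids is not None else None
    return SpatialCoords(X=X, cell_ids=ids), slices


def write_counts(counts: CountMatrix, path):
    """Write counts as MatrixMarket (coordinate integer) text."""
    V = counts.values
    if not sp.issparse(V):
        V = sp.coo_matrix(V)
    scipy.io.mmwrite(str(path), V, field="integer")


def write_coords(coords: SpatialCoords, path, slice_labels=None):
    names = ["x", "y", "z"][: coords.d]
    df = pd.DataFrame(coords.X, columns=names)
    df.insert(0, "cell_id", coords.cell_ids or [f"cell_{i + 1}" for i in range(coords.n)])
    if slice_labels is not None:
        df["slice"] = slice_labels
    df.to_csv(path, sep="\t", index=False)


def write_result(
    result: FitResult,
    outdir,
    cell_ids: Optional[Sequence[str]] = None,
    gene_ids: Optional[Sequence[str]] = None,
    top_gene_table: Optional[pd.DataFrame] = None,
    labels: Optional[dict] = None,
    config: Optional[dict] = None,
):
    """Serialize a fit to a directory: W.tsv, H.tsv, meta.json, batches.tsv.

    Optional extras: a ranked top-gene table (top_genes.tsv) and per-cell
    label vectors (labels.tsv, 1-based in the output).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    N, K = result.W.shape
    M = result.H.shape[1]
    cell_ids = list(cell_ids) if cell_ids is not None else [f"cell_{i + 1}" for i in range(N)]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene_{j + 1}" for j in range(M)]
    signames = [f"signature_{k + 1}" for k in range(K)]

    pd.DataFrame(result.W, index=cell_ids, columns=signames).to_csv(
        outdir / "W.tsv", sep="\t", index_label="cell_id"
    )
    pd.DataFrame(result.H, index=signames, columns=gene_ids).to_csv(
        outdir / "H.tsv", sep="\t", index_label="signature"
    )
    meta = {
        "K": K,
        "phi": result.phi,
        "seed": result.seed,
        "n_iter": result.n_iter,
        "converged": bool(result.converged),
        "effective_rank": result.effective_rank,
        "gkl_trace": [float(g) for g in result.gkl_trace],
    }
    if config:
        meta["config"] = config
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    if result.batches is not None:
        pd.DataFrame(
            {"cell_id": cell_ids, "batch": result.batches.assignment + 1}
        ).to_csv(outdir / "batches.tsv", sep="\t", index=False)
    if top_gene_table is not None:
        top_gene_table.to_csv(outdir / "top_genes.tsv", sep="\t", index=False)
    if labels:
        df = pd.DataFrame({"cell_id": cell_ids})
        for name, vec in labels.items():
            df[name] = np.asarray(vec) + 1  # 1-based in text outputs
        df.to_csv(outdir / "labels.tsv", sep="\t", index=False)


def read_factors(outdir):
    """Load W and H (and identifiers) back from a serialized fit directory."""
    outdir = Path(outdir)
    Wdf = pd.read_csv(outdir / "W.tsv", sep="\t", index_col=0)
    Hdf = pd.read_csv(outdir / "H.tsv", sep="\t", index_col=0)
    meta = json.loads((outdir / "meta.json").read_text())
    return Wdf, Hdf, meta
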