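"""Signature interpretation: gene reweighting, top-gene tables, and hard labels.

A fitted signature matrix H mixes genes that are unique to one signature with
housekeeping-style genes shared by many. To surface the genes that *define*
each signature, weights are rescaled TF-IDF-style against the gene's best
competing signature before ranking. Hard per-cell labels come either from the
argmax signature (crude) or from K-means on the weight vectors, which uses the
whole soft-clustering profile of each cell and typically tracks reference
annotations better.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "reweight_genes",
    "top_genes",
    "hard_clusters",
    "top_signature",
    "fold_enrichment",
]

logger = logging.getLogger(__name__)


def reweight_genes(H, epsilon: float = 1e-12) -> np.ndarray:
    """Rescale signature weights by gene uniqueness.

    Entry (k, i) becomes ``H_ki * log(1 + H_ki / max_{j != k} H_ji)``: a gene
    carried by a single signature is amplified (the ratio is large), a gene
    shared across signatures is shrunk toward ``H_ki * log 2``. The competitor
    maximum is floored at ``epsilon`` so genes absent from every other
    signature get a large, finite boost; zeros map to zeros.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 2:
        raise ValueError("reweighting needs at least two signatures")
    if (H < 0).any():
        raise ValueError("signature matrix must be nonnegative")
    # per-gene top-2 values across signatures give max over competitors j != k
    order = np.sort(H, axis=0)
    top1, top2 = order[-1], order[-2]
    competitor = np.where(H >= top1[None, :], top2[None, :], top1[None, :])
    competitor = np.maximum(competitor, epsilon)
    return H * np.log1p(H / competitor)


def top_genes(reweighted, original, gene_ids=None, n: int = 10) -> pd.DataFrame:
    """Per-signature ranked gene table, ranked by rescaled weight.

    Returns a DataFrame with columns (signature, rank, gene, original_weight,
    rescaled_weight); signatures and ranks are 1-based. Ties in the rescaled
    weight break by original weight, then by gene identifier.
    """
    R = np.asarray(reweighted, dtype=float)
    O = np.asarray(original, dtype=float)
    if R.shape != O.shape:
        raise ValueError("reweighted and original matrices must share a shape")
    K, M = R.shape
    if n > M:
        raise ValueError(f"cannot rank n={n} genes out of M={M}")
    if gene_ids is None:
        gene_ids = [f"gene_{j + 1}" for j in range(M)]
    gene_ids = np.asarray(gene_ids, dtype=object)
    id_rank = np.argsort(np.argsort(gene_ids))  # lexicographic id order
    rows = []
    for k in range(K):
        order = np.lexsort((id_rank, -O[k], -R[k]))[:n]
        for r, j in enumerate(order, start=1):
            rows.append((k + 1, r, gene_ids[j], O[k, j], R[k, j]))
    return pd.DataFrame(
        rows, columns=["signature", "rank", "gene", "original_weight", "rescaled_weight"]
    )


def hard_clusters(W, n_clusters: int, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """K-means labels on the per-cell weight vectors (rows of W), 0-based.

    Best of ``n_restarts`` k-means++ runs by within-cluster sum of squares;
    deterministic given the seed.
    """
    W = np.asarray(W, dtype=float)
    if n_clusters > W.shape[0]:
        raise ValueError("more clusters than cells")
    if np.unique(W, axis=0).shape[0] == 1:
        warnings.warn("all weight vectors identical: a single effective cluster")
    km = KMeans(n_clusters=n_clusters, n_init=n_restarts, random_state=seed)
    return km.fit_predict(W)


def top_signature(W) -> np.ndarray:
    """Per-cell argmax signature (0-based); ties break to the lowest index."""
    W = np.asarray(W, dtype=float)
    return np.argmax(W, axis=1)


def fold_enrichment(W, cell_types, use_weights: bool = True) -> pd.DataFrame:
    """Fold enrichment of cell types within each signature (1 = no enrichment).

    Entry (k, t) is the share of signature k's weight mass carried by type-t
    cells divided by the overall frequency of type t. With
    ``use_weights=False`` the argmax label replaces the soft weights, i.e.
    each cell contributes its full mass to its top signature only.
    """
    W = np.asarray(W, dtype=float)
    types = np.asarray(cell_types)
    if types.shape[0] != W.shape[0]:
        raise ValueError("cell_types must label every cell")
    uniq, inv = np.unique(types, return_inverse=True)
    if not use_weights:
        onehot = np.zeros_like(W)
        onehot[np.arange(W.shape[0]), top_signature(W)] = 1.0
        W = onehot
    K = W.shape[1]
    mass = np.zeros((K, uniq.size))
    for t in range(uniq.size):
        mass[:, t] = W[inv == t].sum(axis=0)
    totals = mass.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        logger.warning("signature with zero total mass; its enrichment row is 0")
    share = np.divide(mass, totals, out=np.zeros_like(mass), where=totals > 0)
    freq = np.bincount(inv, minlength=uniq.size) / types.shape[0]
    if np.any(freq == 0):
        raise ValueError("empty cell type")
    enr = share / freq[None, :]
    return pd.DataFrame(enr, index=[f"signature_{k + 1}" for k in range(K)], columns=uniq)
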