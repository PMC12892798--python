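import numpy as np
import pytest

from neighborhood_nmf import simulate_spatial_counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_vwh(rng):
    """Seeded 2x3 toy count matrix with random positive factors, K=2."""
    V = np.array([[4.0, 0.0, 2.0], [1.0, 3.0, 0.0]])
    W = rng.uniform(0.2, 1.0, size=(2, 2))
    H = rng.uniform(0.2, 1.0, size=(2, 3))
    H /= H.sum(axis=1, keepdims=True)
    return V, W, H


@pytest.fixture(scope="session")
def small_dataset():
    """A small spatially smooth dataset used by several recovery tests."""
    return simulate_spatial_counts(N=400, M=60, K=3, phi_true=0.12, mean_depth=150, seed=7)


def gkl_loop(V, W, H):
    """Scalar-loop GKL oracle: elementwise sum of the divergence terms."""
    WH = W @ H
    total = 0.0
    for n in range(V.shape[0]):
        for m in range(V.shape[1]):
            v, wh = V[n, m], WH[n, m]
            if v > 0:
                total += v * np.log(v) - v * np.log(wh) - v
            total += wh
    return total


def update_h_loop(V, W, H):
    """Scalar-loop oracle for one H update (multiply, then row-normalize)."""
    K, M = H.shape
    N = V.shape[0]
    WH = W @ H
    out = np.zeros_like(H)
    for k in range(K):
        for m in range(M):
            acc = 0.0
            for n in range(N):
                if V[n, m] > 0:
                    acc += W[n, k] * V[n, m] / WH[n, m]
            out[k, m] = H[k, m] * acc
    for k in range(K):
        s = out[k].sum()
        if s > 0:
            out[k] /= s
    return out


def update_w_loop(V, W, H):
    """Scalar-loop oracle for one W update (no normalization)."""
    N, K = W.shape
    M = V.shape[1]
    WH = W @ H
    out = np.zeros_like(W)
    for n in range(N):
        for k in range(K):
            acc = 0.0
            for m in range(M):
                if V[n, m] > 0:
                    acc += V[n, m] / WH[n, m] * H[k, m]
            out[n, k] = W[n, k] * acc
    return out


def reweight_loop(H, eps=1e-12):
    """Scalar-loop oracle for the TF-IDF-style gene reweighting."""
    K, M = H.shape
    out = np.zeros_like(H)
    for k in range(K):
        for i in range(M):
            comp = max(max(H[j, i] for j in range(K) if j != k), eps)
            out[k, i] = H[k, i] * np.log(1 + H[k, i] / comp)
    return out
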