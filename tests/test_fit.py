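"""Tests for warm start, the smoothed iteration, AIC and rank selection."""

import numpy as np
import pytest

from neighborhood_nmf import (
    BatchPartition,
    aic,
    fit_nnmf,
    gaussian_kernel,
    gkl_divergence,
    rnorm,
    select_k,
    simulate_spatial_counts,
    slice_batches,
    smoothing_update,
    update_h,
    update_w,
    warm_start,
)

from conftest import gkl_loop


class TestWarmStart:
    def test_single_init_is_one_plain_run(self, rng):
        V = rng.poisson(3.0, size=(10, 6)).astype(float)
        pair = warm_start(V, K=2, n_init=1, n_iter=20, seed=5)
        # replicate the run by hand with the same seed stream
        r = np.random.default_rng(5)
        W = r.uniform(size=(10, 2))
        H = rnorm(r.uniform(size=(2, 6)))
        for _ in range(20):
            H = update_h(V, W, H)
            W = update_w(V, W, H)
        np.testing.assert_array_equal(pair.W, W)
        np.testing.assert_array_equal(pair.H, H)

    def test_returns_minimum_gkl_of_candidates(self, rng):
        """The chosen start attains the minimum GKL over the candidate runs."""
        V = rng.poisson(3.0, size=(12, 8)).astype(float)
        pair = warm_start(V, K=3, n_init=3, n_iter=30, seed=11)
        chosen = gkl_divergence(V, pair.W, pair.H)
        r = np.random.default_rng(11)
        finals = []
        for _ in range(3):
            W = r.uniform(size=(12, 3))
            H = rnorm(r.uniform(size=(3, 8)))
            for _ in range(30):
                H = update_h(V, W, H)
                W = update_w(V, W, H)
            finals.append(gkl_divergence(V, W, H))
        assert chosen == pytest.approx(min(finals), rel=1e-12)

    def test_rank_exceeding_dimensions_rejected(self, rng):
        with pytest.raises(ValueError):
            warm_start(rng.poisson(3.0, size=(4, 6)).astype(float), K=5)

    def test_few_initializations_warn(self, rng, caplog):
        V = rng.poisson(3.0, size=(6, 4)).astype(float)
        with caplog.at_level("WARNING"):
            warm_start(V, K=2, n_init=1, n_iter=5, seed=0)
        assert any("initializations" in r.message for r in caplog.records)


class TestSmoothingUpdate:
    def test_identity_kernel_leaves_w_unchanged(self):
        W = np.arange(12.0).reshape(4, 3)
        kern = gaussian_kernel(np.arange(4.0)[:, None] * 100, phi=1e-6)
        out = smoothing_update(W, [kern])
        np.testing.assert_allclose(out, W, atol=1e-12)

    def test_constant_field_unchanged(self, rng):
        W = np.full((10, 3), 2.5)
        kern = gaussian_kernel(rng.uniform(size=(10, 2)), phi=0.3)
        np.testing.assert_allclose(smoothing_update(W, [kern]), W, atol=1e-12)

    def test_three_cell_hand_computed_averages(self, rng):
        X = np.array([[0.0], [1.0], [2.0]])
        kern = gaussian_kernel(X, phi=1.0)
        W = rng.uniform(size=(3, 2))
        e1, e4 = np.exp(-1.0), np.exp(-4.0)
        S = np.array([[1, e1, e4], [e1, 1, e1], [e4, e1, 1]])
        expected = (S / S.sum(axis=1, keepdims=True)) @ W
        np.testing.assert_allclose(smoothing_update(W, [kern]), expected, atol=1e-12)

    def test_batched_smoothing_never_mixes_batches(self, rng):
        X = rng.uniform(size=(8, 2))
        batches = slice_batches(["a"] * 4 + ["b"] * 4)
        kernels = [gaussian_kernel(X[i:i + 4], phi=0.5) for i in (0, 4)]
        W = np.zeros((8, 1))
        W[:4] = 1.0  # mass only in slice a
        out = smoothing_update(W, kernels, batches)
        assert np.all(out[4:] == 0.0)
        np.testing.assert_allclose(out[:4].sum(), kernels[0].row_normalized.sum(axis=1).sum(), atol=1e-12)

    def test_mismatched_kernel_size_rejected(self, rng):
        kern = gaussian_kernel(rng.uniform(size=(3, 2)), phi=0.5)
        with pytest.raises(ValueError):
            smoothing_update(np.ones((5, 2)), [kern])


class TestFitNnmf:
    def test_phi_zero_reduces_to_plain_nmf(self, rng):
        """With the identity kernel the iteration is plain Poisson NMF."""
        V = rng.poisson(4.0, size=(20, 10)).astype(float)
        res = fit_nnmf(V, None, K=2, phi=0, max_iter=50, seed=3)
        pair = warm_start(V, K=2, seed=3)
        W, H = pair.W, rnorm(pair.H)
        for _ in range(res.n_iter):
            H = update_h(V, W, H)
            W = update_w(V, W, H)
        np.testing.assert_array_equal(res.W, W)
        np.testing.assert_array_equal(res.H, H)

    def test_plain_trace_monotone(self, rng):
        V = rng.poisson(4.0, size=(25, 12)).astype(float)
        res = fit_nnmf(V, None, K=3, phi=0, max_iter=200, seed=1)
        assert np.all(np.diff(res.gkl_trace) <= 1e-8)

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        a = fit_nnmf(ds.V, ds.X.X, K=3, phi=0.12, max_iter=40, seed=4)
        b = fit_nnmf(ds.V, ds.X.X, K=3, phi=0.12, max_iter=40, seed=4)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)
        np.testing.assert_array_equal(a.gkl_trace, b.gkl_trace)

    def test_single_batch_matches_unbatched_bitwise(self, small_dataset):
        ds = small_dataset
        unbatched = fit_nnmf(ds.V, ds.X.X, K=3, phi=0.12, max_iter=30, seed=2)
        single = fit_nnmf(
            ds.V, ds.X.X, K=3, phi=0.12, max_iter=30, seed=2,
            batches=BatchPartition.single(ds.V.shape[0]),
        )
        one_slice = fit_nnmf(
            ds.V, ds.X.X, K=3, phi=0.12, max_iter=30, seed=2,
            batches=slice_batches(["s1"] * ds.V.shape[0]),
        )
        np.testing.assert_array_equal(unbatched.W, single.W)
        np.testing.assert_array_equal(unbatched.H, single.H)
        np.testing.assert_array_equal(unbatched.W, one_slice.W)

    def test_final_h_row_stochastic_and_nonnegative(self, small_dataset):
        ds = small_dataset
        res = fit_nnmf(ds.V, ds.X.X, K=3, phi=0.12, max_iter=30, seed=0)
        assert (res.W >= 0).all() and (res.H >= 0).all()
        np.testing.assert_allclose(res.H.sum(axis=1), 1.0, atol=1e-10)

    def test_nonconvergence_flagged_not_raised(self, rng):
        V = rng.poisson(4.0, size=(15, 8)).astype(float)
        res = fit_nnmf(V, None, K=2, phi=0, max_iter=3, tol=1e-15, seed=0)
        assert not res.converged
        assert len(res.gkl_trace) == 4

    def test_recovers_planted_signatures(self, small_dataset):
        from neighborhood_nmf import match_signatures

        ds = small_dataset
        res = fit_nnmf(ds.V, ds.X.X, K=3, phi=ds.phi_true, seed=0)
        _, _, mean_sim = match_signatures(res.H, ds.H_true)
        assert mean_sim >= 0.9

    def test_smoothing_raises_spatial_autocorrelation(self, small_dataset):
        from neighborhood_nmf import morans_i

        ds = small_dataset
        kern = gaussian_kernel(ds.X.X, ds.phi_true)
        smooth = fit_nnmf(ds.V, ds.X.X, K=3, phi=ds.phi_true, seed=1)
        plain = fit_nnmf(ds.V, None, K=3, phi=0, seed=1)
        mi = lambda W: np.mean([morans_i(W[:, k], kern) for k in range(3)])
        assert mi(smooth.W) > mi(plain.W)


class TestAic:
    def test_perfect_fit_counts_parameters_only(self):
        W = np.array([[1.0], [2.0]])
        H = np.array([[0.2, 0.3, 0.5]])
        assert aic(W @ H, W, H) == pytest.approx(10.0, abs=1e-10)

    def test_parameter_penalty_increment(self, rng):
        """AIC(K+1) - AIC(K) differs from 2*dGKL by exactly 2(N+M)."""
        V = rng.poisson(4.0, size=(7, 5)).astype(float)
        pairs = {}
        for K in (2, 3):
            W = rng.uniform(0.2, 1.0, size=(7, K))
            H = rnorm(rng.uniform(0.2, 1.0, size=(K, 5)))
            pairs[K] = (W, H)
        d_aic = aic(V, *pairs[3]) - aic(V, *pairs[2])
        d_gkl = gkl_divergence(V, *pairs[3]) - gkl_divergence(V, *pairs[2])
        assert d_aic - 2 * d_gkl == pytest.approx(2 * (7 + 5), abs=1e-9)

    def test_composes_gkl_oracle_and_count(self, rng):
        V = rng.integers(0, 8, size=(4, 5)).astype(float)
        W = rng.uniform(0.2, 1.0, size=(4, 2))
        H = rng.uniform(0.2, 1.0, size=(2, 5))
        assert aic(V, W, H) == pytest.approx(
            2 * gkl_loop(V, W, H) + 2 * (4 * 2 + 2 * 5), abs=1e-10
        )


class TestSelectK:
    def test_single_candidate_is_best(self, small_dataset):
        ds = small_dataset
        scan = select_k(ds.V, ds.X.X, [3], phi=ds.phi_true, max_iter=20, seed=0)
        assert scan.best_K == 3 and scan.aic_values.shape == (1,)

    def test_aic_values_consistent_with_stored_fits(self, small_dataset):
        ds = small_dataset
        scan = select_k(
            ds.V, ds.X.X, [2, 3], phi=ds.phi_true, max_iter=20, seed=0, keep_fits=True
        )
        for a, res in zip(scan.aic_values, scan.fits):
            assert a == pytest.approx(aic(ds.V, res.W, res.H), rel=1e-12)
        np.testing.assert_array_equal(
            scan.n_prm_values, [400 * K + K * 60 for K in (2, 3)]
        )

    def test_parameter_count_strictly_increasing(self, small_dataset):
        ds = small_dataset
        scan = select_k(ds.V, ds.X.X, [2, 3, 4], phi=ds.phi_true, max_iter=10, seed=0)
        assert np.all(np.diff(scan.n_prm_values) > 0)

    def test_recovers_planted_rank(self):
        ds = simulate_spatial_counts(N=500, M=60, K=3, phi_true=0.12, mean_depth=150, seed=21)
        scan = select_k(ds.V, ds.X.X, [2, 3, 4, 5], phi=0.12, seed=0)
        assert scan.best_K == 3
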