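"""t-SNE core: bandwidth calibration, affinities, KL divergence, optimization."""

import numpy as np
import pytest

from codatsne.composition import closure, pairwise_distances
from codatsne.tsne import (
    TsneParams,
    calibrate_bandwidths,
    fit_tsne,
    kl_divergence,
    low_dim_affinities,
    symmetrize,
)

from conftest import random_compositions


def bisection_sigma_oracle(sq_dists, perplexity, tol=1e-12):
    """Standalone bisection on sigma^2 for one row; independent of the
    implementation under test (searches sigma^2 directly, not precision)."""
    def probs(sigma_sq):
        w = np.exp(-(sq_dists - sq_dists.min()) / (2.0 * sigma_sq))
        return w / w.sum()

    def realized(sigma_sq):
        p = probs(sigma_sq)
        p = p[p > 0]
        return 2.0 ** (-np.sum(p * np.log2(p)))

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if realized(mid) < perplexity:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            break
    return probs(np.sqrt(lo * hi))


class TestCalibrateBandwidths:
    def test_equidistant_points_give_uniform_rows(self):
        n = 6
        D = np.ones((n, n)) - np.eye(n)
        model = calibrate_bandwidths(D, perplexity=n - 1)
        off = model.cond_probs[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / (n - 1), atol=1e-8)
        np.testing.assert_allclose(model.realized_perplexities(), n - 1, atol=1e-3)

    def test_line_fixture_matches_bisection_oracle(self):
        pos = np.array([0.0, 1.0, 2.0, 10.0])
        D = np.abs(pos[:, None] - pos[None, :])
        model = calibrate_bandwidths(D, perplexity=2.0)
        mask = ~np.eye(4, dtype=bool)
        for i in range(4):
            expected = bisection_sigma_oracle(D[i][mask[i]] ** 2, 2.0)
            np.testing.assert_allclose(model.cond_probs[i][mask[i]], expected,
                                       atol=1e-6)

    def test_distance_scaling_scales_sigma_not_probs(self, rng):
        x = rng.normal(size=(10, 3))
        D = pairwise_distances(np.abs(x) + 0.1, "euclidean")
        m1 = calibrate_bandwidths(D, 5.0)
        m2 = calibrate_bandwidths(3.0 * D, 5.0)
        np.testing.assert_allclose(m2.sigma_sq, 9.0 * m1.sigma_sq, rtol=1e-4)
        np.testing.assert_allclose(m2.cond_probs, m1.cond_probs, atol=1e-8)

    @pytest.mark.parametrize("per", [5.0, 15.0, 30.0])
    def test_calibration_on_random_50_sample_matrices(self, rng, per):
        """Every realized perplexity 2^H must hit the target within 1e-3."""
        x = random_compositions(rng, 50, 30)
        D = pairwise_distances(x, "aitchison")
        model = calibrate_bandwidths(D, per)
        np.testing.assert_allclose(model.realized_perplexities(), per, atol=1e-3)
        np.testing.assert_allclose(model.cond_probs.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(np.diag(model.cond_probs) == 0)

    def test_perplexity_out_of_range(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="perplexity"):
            calibrate_bandwidths(D, 3.5)


class TestSymmetrize:
    def test_uniform_rows(self):
        n = 5
        cond = (np.ones((n, n)) - np.eye(n)) / (n - 1)
        P = symmetrize(cond)
        off = P[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / (n * (n - 1)), atol=1e-15)

    def test_sums_to_one_for_random_rows(self, rng):
        n = 8
        cond = rng.random((n, n))
        np.fill_diagonal(cond, 0.0)
        cond /= cond.sum(axis=1, keepdims=True)
        P = symmetrize(cond)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(P, P.T)

    def test_hand_computed_3x3(self):
        cond = np.array([[0.0, 0.7, 0.3],
                         [0.4, 0.0, 0.6],
                         [0.9, 0.1, 0.0]])
        P = symmetrize(cond)
        assert P[0, 1] == pytest.approx((0.7 + 0.4) / 6.0)
        assert P[0, 2] == pytest.approx((0.3 + 0.9) / 6.0)
        assert P[1, 2] == pytest.approx((0.6 + 0.1) / 6.0)


class TestLowDimAffinities:
    def test_two_points_split_evenly(self):
        Q = low_dim_affinities(np.array([[0.0, 0.0], [57.0, -3.0]]))
        assert Q[0, 1] == pytest.approx(0.5) and Q[1, 0] == pytest.approx(0.5)

    def test_equilateral_triangle_uniform(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        Q = low_dim_affinities(pts)
        off = Q[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 6.0, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        y = rng.normal(size=(5, 2))
        Q = low_dim_affinities(y)
        num = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i != j:
                    num[i, j] = 1.0 / (1.0 + np.sum((y[i] - y[j]) ** 2))
        np.testing.assert_allclose(Q, num / num.sum(), atol=1e-12)


class TestKlDivergence:
    def test_zero_when_equal(self, rng):
        n = 6
        P = rng.random((n, n))
        np.fill_diagonal(P, 0.0)
        P = symmetrize(P / P.sum(axis=1, keepdims=True))
        assert kl_divergence(P, P) == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_sum(self, rng):
        n = 5
        P = (np.ones((n, n)) - np.eye(n)) / (n * (n - 1))
        Q = low_dim_affinities(rng.normal(size=(n, 2)))
        expected = sum(
            P[i, j] * np.log(P[i, j] / Q[i, j])
            for i in range(n) for j in range(n) if i != j
        )
        assert kl_divergence(P, Q) == pytest.approx(expected, abs=1e-12)
        assert kl_divergence(P, Q) > 0  # Gibbs inequality, P != Q

    def test_degenerate_q_raises(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        Q = np.zeros((2, 2))
        with pytest.raises(ValueError, match="degenerate"):
            kl_divergence(P, Q)


class TestFitTsne:
    def test_clusters_separate_in_map(self, two_cluster_table):
        from codatsne.composition import replace_zeros
        emb, _, _ = fit_tsne(
            replace_zeros(two_cluster_table.values),
            TsneParams(perplexity=10, max_iter=500, dim=2, metric="aitchison", seed=0),
        )
        lab = two_cluster_table.labels
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(emb.coords))
        within = np.concatenate([
            D[np.ix_(lab == c, lab == c)][np.triu_indices(int(np.sum(lab == c)), 1)]
            for c in (0, 1)
        ])
        between = D[np.ix_(lab == 1, lab == 0)].ravel()
        assert between.mean() > np.percentile(within, 95)

    def test_kl_decreases(self, small_table):
        from codatsne.composition import replace_zeros
        vals = replace_zeros(small_table.values)
        _, _, trace = fit_tsne(vals, TsneParams(perplexity=6, max_iter=300, seed=1))
        assert trace.kl_per_checkpoint[-1] < trace.kl_per_checkpoint[0]
        assert all(v >= 0 for v in trace.kl_per_checkpoint)

    def test_seed_reproducibility_bit_identical(self, small_table):
        from codatsne.composition import replace_zeros
        vals = replace_zeros(small_table.values)
        p = TsneParams(perplexity=6, max_iter=200, seed=9)
        e1, _, _ = fit_tsne(vals, p)
        e2, _, _ = fit_tsne(vals, p)
        assert np.array_equal(e1.coords, e2.coords)

    def test_aitchison_P_invariant_to_row_scaling(self, small_table):
        """Scaling one raw row before closure must not change P under the
        Aitchison metric (power-of-two factor keeps float ops exact)."""
        from codatsne.composition import replace_zeros
        raw = small_table.values.copy()
        scaled = raw.copy()
        scaled[3] *= 8.0
        a = replace_zeros(closure(raw))
        b = replace_zeros(closure(scaled))
        Pa = calibrate_bandwidths(pairwise_distances(a, "aitchison"), 6).P
        Pb = calibrate_bandwidths(pairwise_distances(b, "aitchison"), 6).P
        assert np.array_equal(Pa, Pb)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_tsne(np.full((3, 5), 0.2), TsneParams(perplexity=1.5))
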