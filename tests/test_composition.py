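"""Compositional geometry: closure, zero replacement, CLR, Aitchison distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import skbio.stats.composition as skb

from codatsne.composition import (
    CompositionTable,
    aitchison_distance,
    closure,
    clr,
    clr_inverse,
    pairwise_distances,
    replace_zeros,
)

from conftest import random_compositions

positive_rows = arrays(
    np.float64, st.integers(3, 12),
    elements=st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False),
)


class TestClosure:
    def test_uniform_row(self):
        np.testing.assert_allclose(closure([[2.0, 2.0]]), [[0.5, 0.5]])

    def test_identity_on_closed_row(self):
        row = np.array([[0.5, 0.25, 0.25]])
        np.testing.assert_allclose(closure(row), row)

    def test_counts_match_division_by_row_sum(self, rng):
        counts = rng.multinomial(30_000, random_compositions(rng, 1, 20)[0])
        np.testing.assert_allclose(
            closure(counts[None, :])[0], counts / 30_000, atol=1e-15
        )

    def test_all_zero_row_names_sample(self):
        with pytest.raises(ValueError, match="badsample"):
            closure(np.array([[1.0, 1.0], [0.0, 0.0]]), ["ok", "badsample"])


class TestReplaceZeros:
    @pytest.mark.parametrize("method", ["multiplicative", "pseudocount"])
    def test_noop_on_positive_rows(self, rng, method):
        x = random_compositions(rng, 5, 8)
        out = replace_zeros(x, method=method, delta=1e-9)
        np.testing.assert_allclose(out, x, atol=1e-7 if method == "pseudocount" else 1e-12)

    def test_multiplicative_hand_value(self):
        out = replace_zeros(np.array([[0.0, 0.5, 0.5]]), "multiplicative", delta=1e-6)
        np.testing.assert_allclose(out[0], [1e-6, 0.4999995, 0.4999995], rtol=1e-9)

    def test_pseudocount_hand_value(self):
        out = replace_zeros(np.array([[0.0, 1.0, 0.0]]), "pseudocount", delta=0.01)
        np.testing.assert_allclose(out[0], [0.01 / 1.03, 1.01 / 1.03, 0.01 / 1.03])

    def test_matches_skbio_multiplicative(self, rng):
        """Independent oracle: scikit-bio's multiplicative replacement."""
        x = random_compositions(rng, 6, 10)
        x[x < 0.05] = 0.0
        x = closure(x)
        ours = replace_zeros(x, "multiplicative", delta=1e-4)
        theirs = skb.multi_replace(x, delta=1e-4)
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    @pytest.mark.parametrize("delta", [0.0, -1e-3, 0.5])
    def test_invalid_delta(self, delta):
        with pytest.raises(ValueError, match="delta"):
            replace_zeros(np.array([[0.0, 0.5, 0.5]]), delta=delta)

    def test_default_delta_below_smallest_nonzero(self):
        x = np.array([[0.0, 0.1, 0.9], [0.2, 0.3, 0.5]])
        out = replace_zeros(x)
        assert 0 < out[0, 0] < 0.1


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        np.testing.assert_allclose(clr(np.full(5, 0.2)), np.zeros(5), atol=1e-15)

    def test_derived_value(self):
        x = np.array([0.5, 0.25, 0.25])
        expected = np.log(x) - np.log(x).mean()  # ln(x_i) - mean(ln x)
        np.testing.assert_allclose(clr(x), expected)
        np.testing.assert_allclose(clr(x)[0], 0.4621, atol=1e-4)

    def test_matches_skbio(self, rng):
        x = random_compositions(rng, 4, 9)
        np.testing.assert_allclose(clr(x), skb.clr(x), atol=1e-12)

    @given(positive_rows)
    @settings(deadline=None, derandomize=True)
    def test_zero_sum_and_scale_invariance(self, row):
        out = clr(row)
        assert abs(out.sum()) < 1e-10 * max(1.0, np.abs(out).max())
        np.testing.assert_allclose(clr(3.7 * row), out, atol=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            clr(np.array([0.0, 0.5, 0.5]))

    def test_inverse_round_trip(self, rng):
        x = random_compositions(rng, 3, 6)
        np.testing.assert_allclose(clr_inverse(clr(x)), x, atol=1e-12)


class TestAitchisonDistance:
    def test_zero_on_equal_and_scaled(self, rng):
        x = random_compositions(rng, 1, 7)[0]
        assert aitchison_distance(x, x) == 0.0
        assert aitchison_distance(x, 3.0 * x) < 1e-12

    def test_derived_value(self):
        d = aitchison_distance([0.5, 0.25, 0.25], [0.25, 0.25, 0.5])
        # ||clr(x) - clr(y)|| = ln(2) * sqrt(2)
        assert d == pytest.approx(np.log(2.0) * np.sqrt(2.0), abs=1e-12)
        assert d == pytest.approx(0.9803, abs=1e-4)

    def test_clr_norm_oracle_100_pairs(self, rng):
        """d_a must equal ||clr(x) - clr(y)||_2 computed independently."""
        for _ in range(100):
            x, y = rng.gamma(1.5, size=(2, 12)) + 1e-6
            lx, ly = np.log(x), np.log(y)
            expected = np.linalg.norm(
                (lx - lx.mean()) - (ly - ly.mean())
            )
            assert aitchison_distance(x, y) == pytest.approx(expected, abs=1e-10)

    def test_permutation_invariance(self, rng):
        x, y = random_compositions(rng, 2, 9)
        perm = rng.permutation(9)
        assert aitchison_distance(x[perm], y[perm]) == pytest.approx(
            aitchison_distance(x, y), abs=1e-12
        )

    def test_scale_invariance_vs_euclidean_contrast(self, rng):
        """d_a ignores per-sample scaling; raw Euclidean distance does not."""
        x, y = rng.gamma(2.0, size=(2, 8)) + 1e-3
        c1, c2 = 3.1, 0.2
        assert aitchison_distance(c1 * x, c2 * y) == pytest.approx(
            aitchison_distance(x, y), abs=1e-10
        )
        assert np.linalg.norm(c1 * x - c2 * y) != pytest.approx(
            np.linalg.norm(x - y), rel=1e-3
        )

    def test_subcompositional_dominance(self, rng):
        """Distance on a re-closed subset of parts never exceeds the full one."""
        for _ in range(100):
            p = int(rng.integers(5, 15))
            x, y = rng.gamma(2.0, size=(2, p)) + 1e-6
            k = int(rng.integers(3, p))
            sub = rng.choice(p, size=k, replace=False)
            xs, ys = x[sub] / x[sub].sum(), y[sub] / y[sub].sum()
            assert aitchison_distance(xs, ys) <= aitchison_distance(x, y) + 1e-10

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            aitchison_distance([0.5, 0.5], [0.2, 0.3, 0.5])


class TestPairwiseDistances:
    def test_duplicate_rows_zero_distance(self, rng):
        x = random_compositions(rng, 4, 6)
        x[2] = x[0]
        D = pairwise_distances(x)
        assert D[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_elementwise_loop(self, rng):
        x = random_compositions(rng, 6, 8)
        D = pairwise_distances(x, "aitchison")
        for i in range(6):
            for j in range(6):
                assert D[i, j] == pytest.approx(
                    aitchison_distance(x[i], x[j]), abs=1e-10
                )
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_euclidean_on_clr_equals_aitchison_on_raw(self, rng):
        x = random_compositions(rng, 7, 10)
        np.testing.assert_allclose(
            pairwise_distances(clr(x), "euclidean"),
            pairwise_distances(x, "aitchison"),
            atol=1e-10,
        )


class TestCompositionTable:
    def test_rejects_duplicate_ids(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            CompositionTable(["a", "a"], ["t1", "t2"],
                             random_compositions(rng, 2, 2))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError, match="negative"):
            CompositionTable(["a", "b"], ["t1", "t2"],
                             np.array([[0.5, 0.5], [-0.1, 1.1]]))

    def test_closed_rows_sum_to_one(self, rng):
        t = CompositionTable(["a", "b"], list("xyz"),
                             rng.gamma(2.0, size=(2, 3))).closed()
        np.testing.assert_allclose(t.values.sum(axis=1), 1.0, atol=1e-9)
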