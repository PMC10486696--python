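"""Trajectory embedding, Hankel tensor construction, diagonal averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holssa.embedding import (
    GroupingScheme,
    embed_series,
    matrix_to_tensor,
    rank1_series,
    reconstruct_groups,
    tensor_to_series,
)

from oracles import diagonal_average_bruteforce


class TestEmbedSeries:
    def test_direct_indexing(self):
        em = embed_series(np.arange(1, 7), 3)
        np.testing.assert_array_equal(em.M, [[1, 2, 3], [4, 5, 6]])

    def test_remainder_dropped(self):
        em = embed_series(np.arange(7), 3)
        assert em.M.shape == (2, 3)
        assert em.source_length == 7

    def test_flatten_round_trip(self, rng):
        s = rng.normal(size=103)
        em = embed_series(s, 10)
        np.testing.assert_array_equal(em.M.ravel(), s[:100])

    @pytest.mark.parametrize("window,n", [(1, 10), (6, 10), (7, 12)])
    def test_invalid_window(self, window, n):
        with pytest.raises(ValueError):
            embed_series(np.arange(n), window)


class TestMatrixToTensor:
    def test_degenerate_depth_single_slab(self):
        em = embed_series(np.arange(12), 3)
        t = matrix_to_tensor(em, depth=em.L)
        assert t.T.shape == (1, 4, 3)
        np.testing.assert_array_equal(t.T[0], em.M)

    def test_slab_definition(self):
        em = embed_series(np.arange(8), 2)  # M is 4 x 2
        t = matrix_to_tensor(em, depth=2)
        assert t.T.shape == (3, 2, 2)
        for k in range(3):
            np.testing.assert_array_equal(t.T[k], em.M[k : k + 2])

    def test_hankel_property(self, rng):
        em = embed_series(rng.normal(size=60), 5)
        t = matrix_to_tensor(em, depth=4)
        K, w, _ = t.T.shape
        for k in range(K - 1):
            for a in range(w - 1):
                np.testing.assert_array_equal(t.T[k + 1, a], t.T[k, a + 1])

    def test_depth_out_of_range(self):
        em = embed_series(np.arange(12), 3)
        with pytest.raises(ValueError):
            matrix_to_tensor(em, depth=em.L + 1)
        with pytest.raises(ValueError):
            matrix_to_tensor(em, depth=0)


class TestTensorToSeries:
    def test_perfect_inverse(self, rng):
        s = rng.normal(size=107)
        t = matrix_to_tensor(embed_series(s, 10))
        out = tensor_to_series(t)
        np.testing.assert_allclose(out[:100], s[:100], atol=1e-12)
        np.testing.assert_array_equal(out[100:], 0)  # remainder zero-padded

    def test_constant_tensor(self):
        out = tensor_to_series(np.ones((3, 2, 4)), window=4)
        np.testing.assert_array_equal(out, np.ones(16))

    def test_matches_bruteforce_preimage_average(self, rng):
        arr = rng.normal(size=(5, 3, 4))
        np.testing.assert_allclose(
            tensor_to_series(arr, window=4),
            diagonal_average_bruteforce(arr, 4),
            atol=1e-12,
        )

    def test_rank1_fast_path_matches_bruteforce(self, rng):
        u, v, w = rng.normal(size=6), rng.normal(size=4), rng.normal(size=5)
        outer = np.einsum("k,a,b->kab", u, v, w)
        np.testing.assert_allclose(
            rank1_series(u, v, w),
            diagonal_average_bruteforce(outer, 5),
            atol=1e-12,
        )

    def test_inconsistent_shape_errors(self):
        with pytest.raises(ValueError):
            tensor_to_series(np.ones((3, 2, 4)), window=5)
        with pytest.raises(ValueError):
            tensor_to_series(np.ones((3, 4)), window=4)


class TestReconstructGroups:
    def _components(self, rng, n=4, shape=(4, 3, 5)):
        return [rng.normal(size=shape) for _ in range(n)]

    def test_group_sum_equals_total(self, rng):
        comps = self._components(rng)
        g2 = GroupingScheme(2, [0, 1, 0, 1])
        g1 = GroupingScheme(1, [0, 0, 0, 0])
        two = reconstruct_groups(comps, g2, window=5)
        one = reconstruct_groups(comps, g1, window=5)
        np.testing.assert_allclose(two[0] + two[1], one[0], atol=1e-12)

    def test_permutation_within_group_invariant(self, rng):
        comps = self._components(rng)
        g = GroupingScheme(1, [0, 0, 0, 0])
        a = reconstruct_groups(comps, g, window=5)
        b = reconstruct_groups(comps[::-1], g, window=5)
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)

    def test_empty_group_errors(self, rng):
        comps = self._components(rng, n=2)
        with pytest.raises(ValueError):
            reconstruct_groups(comps, GroupingScheme(2, [0, 0]), window=5)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    n=st.integers(min_value=20, max_value=200),
    window=st.integers(min_value=2, max_value=9),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_embed_tensorize_average_is_identity(n, window, seed):
    """embed -> tensorize -> diagonal-average recovers the series exactly."""
    if n // window < 2:
        return
    s = np.random.default_rng(seed).normal(size=n)
    t = matrix_to_tensor(embed_series(s, window))
    trunc = (n // window) * window
    np.testing.assert_allclose(tensor_to_series(t)[:trunc], s[:trunc], atol=1e-10)
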