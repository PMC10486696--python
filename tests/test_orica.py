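"""Online recursive ICA: update algebra, whitening, source recovery."""

import warnings

import numpy as np
import pytest

from holssa.orica import ORICA, demix_update, init_state, separate, whiten_update

from oracles import amari_index, match_sources, sherman_morrison_mixing_update


class TestInitState:
    def test_identity_init(self):
        st = init_state(3)
        np.testing.assert_array_equal(st.S_inv, np.eye(3))
        np.testing.assert_array_equal(st.whitener, np.eye(3))
        assert st.n_seen == 0

    def test_degenerate_args_rejected(self):
        with pytest.raises(ValueError):
            init_state(1)
        with pytest.raises(ValueError):
            init_state(3, l_r=0.0)
        with pytest.raises(ValueError):
            init_state(3, nonlinearity="relu")

    def test_deterministic(self):
        a, b = init_state(4, 0.01, "cubic"), init_state(4, 0.01, "cubic")
        np.testing.assert_array_equal(a.S_inv, b.S_inv)
        assert a.l_r == b.l_r


class TestWhitenUpdate:
    def test_stream_whitens_correlated_gaussians(self):
        rng = np.random.default_rng(3)
        A = np.array([[2.0, 0.5], [0.5, 1.0]])
        st = init_state(2, l_r=0.005)
        out = np.empty((2, 10_000))
        for t in range(10_000):
            out[:, t] = whiten_update(st, A @ rng.standard_normal(2))
            st.n_seen += 1
        emp = np.cov(out[:, 1000:])
        assert np.abs(emp - np.eye(2)).max() < 0.1

    def test_already_white_input_keeps_identity_whitener(self):
        rng = np.random.default_rng(4)
        st = init_state(3, l_r=0.005)
        for t in range(5000):
            whiten_update(st, rng.standard_normal(3))
            st.n_seen += 1
        assert np.abs(st.whitener - np.eye(3)).max() < 0.05

    def test_constant_stream_stays_finite(self):
        st = init_state(2)
        for _ in range(50):
            out = whiten_update(st, np.array([1.0, 1.0]))
            st.n_seen += 1
        assert np.all(np.isfinite(out))
        assert np.all(np.isfinite(st.whitener))


class TestDemixUpdate:
    def test_zero_sample_gives_pure_identity_term(self):
        """With a = 0 the data term vanishes and S_inv scales by (1 + lr)."""
        st = init_state(2, l_r=0.01)
        S0 = st.S_inv.copy()
        demix_update(st, np.zeros(2))
        np.testing.assert_allclose(st.S_inv, (1 + 0.01) * S0, atol=1e-15)
        assert st.n_seen == 1

    def test_single_update_matches_dense_formula(self, rng):
        st = init_state(4, l_r=0.005)
        st.S_inv = np.eye(4) + 0.1 * rng.normal(size=(4, 4))
        S_before = st.S_inv.copy()
        a = rng.standard_normal(4)
        y = S_before @ a
        expected = S_before + 0.005 * (np.eye(4) - np.outer(np.tanh(y), y)) @ S_before
        demix_update(st, a)
        assert np.abs(st.S_inv - expected).max() < 1e-12

    def test_recursive_inverse_tracks_sherman_morrison(self, rng):
        """Propagating S directly via Sherman-Morrison and inverting agrees."""
        st = init_state(3, l_r=0.005)
        S = np.eye(3)  # mixing estimate, the inverse of S_inv
        for _ in range(100):
            a = rng.standard_normal(3)
            y = st.S_inv @ a
            S = sherman_morrison_mixing_update(S, y, np.tanh(y), 0.005)
            demix_update(st, a)
        assert np.abs(np.linalg.inv(S) - st.S_inv).max() < 1e-8


class TestSeparate:
    def test_recovers_uniform_sources_with_cubic(self):
        rng = np.random.default_rng(11)
        S = rng.uniform(-1, 1, size=(2, 50_000))
        A = rng.normal(size=(2, 2))
        comp, _, _ = separate(A @ S, nonlinearity="cubic")
        assert min(match_sources(comp, S)) >= 0.95

    def test_identity_task_white_independent_input(self):
        rng = np.random.default_rng(12)
        S = rng.laplace(size=(2, 20_000))
        comp, _, _ = separate(S)
        assert min(match_sources(comp, S)) >= 0.99

    def test_gaussian_sources_warn_unidentifiable(self, caplog):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((2, 20_000))  # enough data that the
        # kurtosis estimate settles well inside the Gaussian band
        with caplog.at_level("WARNING", logger="holssa.orica"):
            separate(X, n_passes=1)
        assert any("unidentifiable" in r.getMessage() for r in caplog.records)

    def test_amari_distance_decreases_with_data(self):
        rng = np.random.default_rng(0)
        S = rng.laplace(size=(2, 50_000))
        A = rng.normal(size=(2, 2))
        X = A @ S
        idx = []
        for n in (1_000, 10_000, 50_000):
            _, mix, _ = separate(X[:, :n])
            idx.append(amari_index(np.linalg.pinv(mix) @ A))
        assert idx[2] < idx[1] < idx[0]

    def test_backprojection_identity(self):
        """mixing_est @ components reproduces the centred input exactly."""
        rng = np.random.default_rng(14)
        X = rng.laplace(size=(3, 5_000))
        comp, mix, st = separate(X, n_passes=1)
        np.testing.assert_allclose(mix @ comp, X - st.mean[:, None], atol=1e-8)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            separate(np.random.default_rng(0).normal(size=(1, 100)))


def test_estimator_transform_matches_separate(rng):
    X = rng.laplace(size=(3, 4_000))
    est = ORICA(n_passes=1).fit(X.T)
    S_est = est.transform(X.T).T
    back = est.inverse_transform(est.transform(X.T)).T
    np.testing.assert_allclose(back, X, atol=1e-6)
    assert S_est.shape == X.shape
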