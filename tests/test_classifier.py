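"""Two-phase classifier behaviour and evaluation metrics."""

import numpy as np
import pytest

from holssa.classifier import TwoPhaseClassifier, evaluate, make_phase1


def _blobs(rng, n_per_class=60, n_classes=4, sep=6.0):
    """Well-separated Gaussian blobs on a 2-D grid."""
    centers = np.array([[0, 0], [sep, 0], [0, sep], [sep, sep]])[:n_classes]
    X = np.vstack([
        c + rng.normal(scale=0.5, size=(n_per_class, 2)) for c in centers
    ])
    y = np.repeat(np.arange(n_classes), n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestPhase1:
    def test_separable_blobs_learned(self, rng):
        X, y = _blobs(rng)
        ann = make_phase1(seed=0).fit(X, y)
        assert ann.score(X, y) >= 0.95

    def test_same_seed_reproducible(self, rng):
        X, y = _blobs(rng)
        a = make_phase1(seed=3).fit(X, y)
        b = make_phase1(seed=3).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_shuffled_labels_give_chance_level(self, rng):
        X, y = _blobs(rng, n_per_class=100)
        y_shuf = rng.permutation(y)
        ann = make_phase1(seed=0).fit(X[:300], y_shuf[:300])
        acc = ann.score(X[300:], y_shuf[300:])
        assert abs(acc - 0.25) <= 0.15


class TestTwoPhase:
    def test_fit_predict_contract(self, rng):
        X, y = _blobs(rng)
        model = TwoPhaseClassifier(random_state=0).fit(X, y)
        pred = model.predict(X[:1])
        assert pred.shape == (1,)
        assert pred[0] in {0, 1, 2, 3}

    def test_batch_equals_loop_prediction(self, rng):
        X, y = _blobs(rng)
        model = TwoPhaseClassifier(random_state=0).fit(X, y)
        batch = model.predict(X[:10])
        loop = np.concatenate([model.predict(X[j : j + 1]) for j in range(10)])
        np.testing.assert_array_equal(batch, loop)

    def test_row_permutation_equivariance(self, rng):
        X, y = _blobs(rng)
        model = TwoPhaseClassifier(random_state=0).fit(X, y)
        perm = rng.permutation(20)
        np.testing.assert_array_equal(
            model.predict(X[:20])[perm], model.predict(X[:20][perm])
        )

    def test_two_phase_not_worse_than_phase1_on_separable_data(self, rng):
        X, y = _blobs(rng, n_per_class=80)
        tr, te = np.arange(0, 240), np.arange(240, 320)
        model = TwoPhaseClassifier(random_state=0).fit(X[tr], y[tr])
        p1 = make_phase1(seed=0).fit(X[tr], y[tr])
        acc2 = np.mean(model.predict(X[te]) == y[te])
        acc1 = p1.score(X[te], y[te])
        assert acc2 >= acc1 - 0.02

    def test_unfitted_predict_rejected(self, rng):
        with pytest.raises(ValueError):
            TwoPhaseClassifier().predict(rng.normal(size=(3, 2)))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            TwoPhaseClassifier().fit(X, np.zeros(20))

    def test_adaptation_weights_change_fit(self, rng):
        """Down-weighting a mislabelled block changes the boundary."""
        X, y = _blobs(rng, n_per_class=40, n_classes=2)
        y_bad = y.copy()
        bad = np.arange(10)
        y_bad[bad] = 1 - y_bad[bad]
        mask = np.zeros(len(y), dtype=bool)
        mask[bad] = True
        plain = TwoPhaseClassifier(random_state=0, adaptation_rate=1.0).fit(X, y_bad)
        down = TwoPhaseClassifier(random_state=0, adaptation_rate=0.01).fit(
            X, y_bad, new_session=mask
        )
        acc_plain = np.mean(plain.predict(X[~mask]) == y[~mask])
        acc_down = np.mean(down.predict(X[~mask]) == y[~mask])
        assert acc_down >= acc_plain


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3] * 10)
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert rep.misclassification_rate == 0.0

    def test_hand_computed_binary_confusion(self):
        """Confusion [[40,10],[10,40]]: accuracy 0.8, kappa 0.6."""
        y_true = np.repeat([0, 1], 50)
        y_pred = y_true.copy()
        y_pred[:10] = 1
        y_pred[50:60] = 0
        rep = evaluate(y_pred, y_true)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.kappa == pytest.approx(0.6)
        np.testing.assert_array_equal(rep.confusion, [[40, 10], [10, 40]])

    def test_constant_prediction_on_balanced_truth(self):
        y_true = np.repeat([0, 1, 2, 3], 25)
        y_pred = np.zeros(100, dtype=int)
        rep = evaluate(y_pred, y_true, labels=[0, 1, 2, 3])
        assert rep.accuracy == pytest.approx(0.25)
        assert rep.kappa == pytest.approx(0.0)

    def test_identities(self, rng):
        y_true = rng.integers(0, 4, size=200)
        y_pred = rng.integers(0, 4, size=200)
        rep = evaluate(y_pred, y_true)
        assert rep.accuracy + rep.misclassification_rate == 1.0
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1),
            [np.sum(y_true == c) for c in rep.classes],
        )

    def test_shuffled_labels_kappa_near_zero(self, rng):
        y_true = np.repeat([0, 1, 2, 3], 100)
        y_pred = rng.permutation(y_true)
        assert abs(evaluate(y_pred, y_true).kappa) < 0.1

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0, 1, 7], [0, 1, 2], labels=[0, 1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0, 1], [0, 1, 2])
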