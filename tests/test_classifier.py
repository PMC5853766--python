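"""The NumPy CNN: gradients, training behavior, prediction contract,
and the recording-level >=50% diagnosis rule."""

import numpy as np
import pytest

import heartsound as hs
from heartsound import nn
from heartsound.classifier import (CLASS_ORDER, ClassProbabilities, HeartSoundCNN,
                                   diagnose_recording)


class TestLayerGradients:
    """Analytic gradients vs central finite differences on tiny tensors."""

    @staticmethod
    def _num_grad(f, x, eps=1e-5):
        g = np.zeros_like(x, dtype=np.float64)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = x[i]
            x[i] = orig + eps
            fp = f()
            x[i] = orig - eps
            fm = f()
            x[i] = orig
            g[i] = (fp - fm) / (2 * eps)
        return g

    def test_conv2d_gradients(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 3, 8, 8))
        w = rng.standard_normal((4, 3, 5, 5)) * 0.1
        b = rng.standard_normal(4) * 0.1
        tgt = rng.standard_normal((2, 4, 4, 4))

        def loss():
            out, _ = nn.conv2d_forward(x, w, b)
            return np.sum(out * tgt)

        out, cache = nn.conv2d_forward(x, w, b)
        dx, dw, db = nn.conv2d_backward(tgt, cache)
        assert np.allclose(dx, self._num_grad(loss, x), atol=1e-6)
        assert np.allclose(dw, self._num_grad(loss, w), atol=1e-6)
        assert np.allclose(db, self._num_grad(loss, b), atol=1e-6)

    def test_maxpool_gradient_routes_to_argmax(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 2, 6, 6))
        tgt = rng.standard_normal((2, 2, 3, 3))

        def loss():
            out, _ = nn.maxpool2_forward(x)
            return np.sum(out * tgt)

        _, cache = nn.maxpool2_forward(x)
        dx = nn.maxpool2_backward(tgt, cache)
        assert np.allclose(dx, self._num_grad(loss, x), atol=1e-6)

    def test_softmax_cross_entropy_gradient_is_p_minus_y(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((4, 5))
        y = np.eye(5)[[0, 2, 4, 1]]
        p = nn.softmax(z)
        num = self._num_grad(lambda: nn.cross_entropy(nn.softmax(z), y) * 4, z)
        assert np.allclose(p - y, num, atol=1e-5)


class TestHeartSoundCNN:
    def test_forward_produces_five_probabilities(self, small_training_data):
        X, y = small_training_data
        m = HeartSoundCNN(epochs=0).fit(X, y)
        probs = m.predict_proba(X[:7])
        assert probs.shape == (7, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_seeded_init_is_identical(self, small_training_data):
        X, y = small_training_data
        a = HeartSoundCNN(epochs=0, random_state=5).fit(X, y)
        b = HeartSoundCNN(epochs=0, random_state=5).fit(X, y)
        assert all(np.array_equal(a.params_[k], b.params_[k]) for k in a.params_)

    def test_zero_learning_rate_leaves_parameters_unchanged(self, small_training_data):
        X, y = small_training_data
        init = HeartSoundCNN(epochs=0, random_state=3).fit(X, y)
        trained = HeartSoundCNN(epochs=2, learning_rate=0.0, random_state=3).fit(X, y)
        assert all(np.array_equal(init.params_[k], trained.params_[k])
                   for k in init.params_)

    def test_training_reduces_loss_and_separates_classes(self, small_training_data):
        X, y = small_training_data
        m = HeartSoundCNN(epochs=8, random_state=0).fit(X, y)
        assert m.loss_curve_[-1] < m.loss_curve_[0]
        assert (m.predict(X) == y).mean() >= 0.95

    def test_duplicated_dataset_same_loss_full_batch(self, small_training_data):
        X, y = small_training_data
        keep = np.concatenate([np.flatnonzero(y == c)[:8] for c in np.unique(y)])
        X, y = X[keep], y[keep]
        m1 = HeartSoundCNN(epochs=3, batch_size=40, random_state=1).fit(X, y)
        m2 = HeartSoundCNN(epochs=3, batch_size=80, random_state=1).fit(
            np.concatenate([X, X]), np.concatenate([y, y]))
        assert m1.loss_curve_[-1] == pytest.approx(m2.loss_curve_[-1], abs=5e-3)

    def test_all_zero_feature_gives_finite_probabilities(self, small_training_data):
        X, y = small_training_data
        m = HeartSoundCNN(epochs=1, random_state=0).fit(X, y)
        p = m.predict_proba(np.zeros((1, 40, 40)))
        assert np.all(np.isfinite(p)) and p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_wrong_shape_rejected(self, small_training_data):
        X, y = small_training_data
        m = HeartSoundCNN(epochs=0).fit(X, y)
        with pytest.raises(hs.ConfigurationError):
            m.predict_proba(np.zeros((1, 32, 32)))

    def test_label_length_mismatch_rejected(self, small_training_data):
        X, y = small_training_data
        with pytest.raises(hs.ConfigurationError):
            HeartSoundCNN(epochs=0).fit(X, y[:-1])

    def test_save_load_round_trip(self, small_training_data, tmp_path):
        X, y = small_training_data
        m = HeartSoundCNN(epochs=2, random_state=0).fit(X, y)
        path = tmp_path / "model.npz"
        m.save(path)
        loaded = HeartSoundCNN.load(path)
        assert np.allclose(m.predict_proba(X[:5]), loaded.predict_proba(X[:5]))
        assert loaded.get_params() == m.get_params()

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        m = HeartSoundCNN(epochs=3, random_state=9)
        c = clone(m)
        assert c.get_params() == m.get_params()


class TestDiagnoseRule:
    @staticmethod
    def _model_returning(vectors):
        class Fake:
            def predict_proba(self, feats):
                return np.asarray(vectors, dtype=float)
        return Fake()

    def test_aggregate_is_mean_of_cycles(self):
        v = [0.9, 0.025, 0.025, 0.025, 0.025]
        model = self._model_returning([v, v, v])
        d = diagnose_recording(model, [None] * 3, truth=hs.SoundClass.NORMAL)
        assert np.allclose(d.aggregate.p, v)
        assert d.predicted_class is hs.SoundClass.NORMAL
        assert d.correct_given_truth is True

    def test_exactly_fifty_percent_counts_correct(self):
        model = self._model_returning([[1, 0, 0, 0, 0], [0, 1, 0, 0, 0]])
        d = diagnose_recording(model, [None] * 2, truth=hs.SoundClass.S3)
        assert d.aggregate.p[1] == pytest.approx(0.5)
        assert d.correct_given_truth is True

    def test_below_fifty_percent_is_incorrect(self):
        model = self._model_returning([[0.51, 0.49, 0, 0, 0]])
        d = diagnose_recording(model, [None], truth=hs.SoundClass.S3)
        assert d.correct_given_truth is False

    def test_empty_features_rejected(self):
        with pytest.raises(hs.ConfigurationError):
            diagnose_recording(self._model_returning([]), [])

    def test_class_probabilities_validate_simplex(self):
        with pytest.raises(hs.ConfigurationError):
            ClassProbabilities(np.array([0.5, 0.5, 0.5, 0.0, 0.0]))
        cp = ClassProbabilities(np.array([0.2, 0.2, 0.2, 0.2, 0.2]))
        assert cp[hs.SoundClass.S4] == pytest.approx(0.2)
        assert len(CLASS_ORDER) == 5
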