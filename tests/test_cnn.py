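"""Network construction, gradients, training mechanics, and evaluation."""

import numpy as np
import pytest

import plantarkit as pk
from plantarkit.cnn import CNNSpec, Conv1DNet, softmax_cross_entropy

TINY = CNNSpec(
    filters=(4, 4, 6, 6), kernel_size=3, pool_stride=2, n_classes=3,
    epochs=1, batch_size=4,
)


def _hand_param_count(filters, k, c_in, length, n_classes, pool=2):
    """Independent layer-by-layer arithmetic for the parameter total."""
    total = 0
    chans = [c_in, *filters]
    for i in range(4):
        total += filters[i] * (chans[i] * k + 1)  # weights + bias
    out_len = length // pool // pool
    total += n_classes * (filters[-1] * out_len + 1)
    return total


class TestBuildModel:
    def test_default_architecture_parameter_count(self):
        spec = CNNSpec()
        net = pk.build_model(spec, (8, 120))
        assert net.n_parameters == _hand_param_count(
            (128, 128, 256, 256), 7, 8, 120, 6
        )

    def test_tiny_architecture_parameter_count(self):
        net = pk.build_model(TINY, (3, 12))
        assert net.n_parameters == _hand_param_count((4, 4, 6, 6), 3, 3, 12, 3)

    def test_two_pooling_stages_leave_length_30(self):
        net = pk.build_model(CNNSpec(), (8, 120))
        assert net.out_length == 30
        summary = net.describe()
        assert summary[-1]["out"] == (6,)  # softmax width = classes
        assert sum(l["params"] for l in summary) == net.n_parameters

    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            pk.build_model(CNNSpec(kernel_size=7), (8, 4))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            CNNSpec(kernel_size=6)


class TestGradients:
    def test_backward_matches_directional_derivative(self):
        """Analytic gradient agrees with a central finite difference along a
        random parameter direction (eps chosen between the ReLU-kink and
        float32-noise regimes)."""
        net = Conv1DNet(TINY, (3, 12), seed=0)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 3, 12)).astype(np.float32)
        y = np.eye(3, dtype=np.float32)[rng.integers(0, 3, 5)]
        logits, cache = net.forward(X, want_cache=True)
        _, dl = softmax_cross_entropy(logits, y)
        grads = net.backward(dl, cache)
        dirs = [rng.standard_normal(p.shape).astype(np.float32) for p in net.parameters]
        analytic = sum(float(np.vdot(g, d)) for g, d in zip(grads, dirs))
        eps = 3e-4
        for p, d in zip(net.parameters, dirs):
            p += eps * d
        lp, _ = softmax_cross_entropy(net.forward(X), y)
        for p, d in zip(net.parameters, dirs):
            p -= 2 * eps * d
        lm, _ = softmax_cross_entropy(net.forward(X), y)
        numeric = (lp - lm) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=2e-2)


def _toy_dataset(rng, n_per_class=40, noise=0.1):
    """Three well-separated sinusoid classes on 3 channels x 12 samples."""
    y = np.repeat(np.arange(3), n_per_class)
    X = np.zeros((y.size, 3, 12), dtype=np.float32)
    t = np.arange(12)
    for i, cls in enumerate(y):
        X[i, cls] = np.sin(2 * np.pi * (cls + 1) * t / 12) * (cls + 1)
    X += rng.standard_normal(X.shape).astype(np.float32) * noise
    return X, y


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        X, y = _toy_dataset(rng)
        clf = pk.GaitCNNClassifier(
            filters=(4, 4, 6, 6), kernel_size=3, epochs=30, batch_size=16,
            random_state=0,
        )
        clf.fit(X, y)
        losses = clf.history_["loss"]
        assert losses[-1] < losses[0]
        assert clf.score(X, y) > 0.9

    def test_single_epoch_history_length(self, rng):
        X, y = _toy_dataset(rng, n_per_class=10)
        clf = pk.GaitCNNClassifier(
            filters=(4, 4, 6, 6), kernel_size=3, epochs=1, random_state=0
        )
        clf.fit(X, y)
        assert len(clf.history_["loss"]) == 1
        assert len(clf.history_["lr"]) == 1

    def test_seeded_training_is_reproducible(self, rng):
        X, y = _toy_dataset(rng, n_per_class=15)
        runs = []
        for _ in range(2):
            clf = pk.GaitCNNClassifier(
                filters=(4, 4, 6, 6), kernel_size=3, epochs=5, random_state=7
            )
            clf.fit(X, y)
            runs.append(clf.history_["loss"][-1])
        assert runs[0] == runs[1]

    def test_empty_training_set_rejected(self):
        clf = pk.GaitCNNClassifier(filters=(4, 4, 6, 6), kernel_size=3)
        with pytest.raises(ValueError):
            clf.fit(np.zeros((0, 3, 12)), np.zeros(0))

    def test_standardization_statistics_from_training_only(self, rng):
        X, y = _toy_dataset(rng, n_per_class=15)
        clf = pk.GaitCNNClassifier(
            filters=(4, 4, 6, 6), kernel_size=3, epochs=1, random_state=0
        )
        clf.fit(X, y)
        np.testing.assert_allclose(clf.scaler_mean_, X.mean(axis=(0, 2)), rtol=1e-5)
        # predicting on shifted data reuses the training scaler unchanged
        before = clf.scaler_mean_.copy()
        clf.predict(X + 100.0)
        np.testing.assert_array_equal(clf.scaler_mean_, before)

    def test_model_save_load_round_trip(self, rng, tmp_path):
        X, y = _toy_dataset(rng, n_per_class=10)
        clf = pk.GaitCNNClassifier(
            filters=(4, 4, 6, 6), kernel_size=3, epochs=2, random_state=0
        )
        clf.fit(X, y)
        path = tmp_path / "model.npz"
        pk.save_model(clf, path)
        loaded = pk.load_model(path)
        np.testing.assert_array_equal(loaded.predict(X), clf.predict(X))


class TestEvaluate:
    def test_perfect_and_constant_predictors(self):
        y = np.repeat(np.arange(6), 20)
        perfect = pk.evaluate_predictions(y, y, np.arange(6))
        assert perfect.accuracy == 1.0
        np.testing.assert_array_equal(perfect.confusion, np.diag(np.full(6, 20)))
        constant = pk.evaluate_predictions(y, np.zeros_like(y), np.arange(6))
        assert constant.accuracy == pytest.approx(1 / 6)

    def test_confusion_invariants_on_random_predictions(self, rng):
        y = rng.integers(0, 6, 300)
        y_pred = rng.integers(0, 6, 300)
        rep = pk.evaluate_predictions(y, y_pred, np.arange(6))
        counts = np.bincount(y, minlength=6)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), counts)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum()
        )

    def test_unknown_label_rejected(self, rng):
        X, y = _toy_dataset(rng, n_per_class=10)
        clf = pk.GaitCNNClassifier(
            filters=(4, 4, 6, 6), kernel_size=3, epochs=1, random_state=0
        )
        clf.fit(X, y)
        with pytest.raises(ValueError):
            clf.evaluate(X, y + 10)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        V = rng.standard_normal((6, 960))
        R, strong = pk.correlation_matrix(V)
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R, R.T)
        assert np.all(np.abs(R) <= 1 + 1e-12)

    def test_matches_brute_force_pearson(self, rng):
        V = rng.standard_normal((4, 50))
        R, _ = pk.correlation_matrix(V)
        for i in range(4):
            for j in range(4):
                a, b = V[i] - V[i].mean(), V[j] - V[j].mean()
                r = float(a @ b / np.sqrt((a @ a) * (b @ b)))
                assert R[i, j] == pytest.approx(r, rel=1e-9)

    def test_orthogonal_sinusoids_near_zero(self):
        t = np.arange(120)
        V = np.stack([np.sin(2 * np.pi * k * t / 120) for k in (1, 2)])
        R, strong = pk.correlation_matrix(V)
        assert abs(R[0, 1]) < 1e-9
        assert strong == []

    def test_strong_pairs_flagged_above_0p3(self, rng):
        base = rng.standard_normal(200)
        V = np.stack([base, base + 0.3 * rng.standard_normal(200),
                      rng.standard_normal(200)])
        R, strong = pk.correlation_matrix(V)
        assert (0, 1) in {(i, j) for i, j, _ in strong}

    def test_zero_variance_rejected(self):
        V = np.vstack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError):
            pk.correlation_matrix(V)

    def test_class_mean_waveform_correlations(self):
        """Mean posture waveforms overlap substantially (many pairs beyond
        the 0.3 'strongly correlated' level) — the motivation for a learned
        classifier over raw template matching."""
        vecs = []
        for p in pk.CLASSIFICATION_POSTURES:
            vecs.append(pk.default_template(p).waveform.ravel())
        R, strong = pk.correlation_matrix(np.stack(vecs))
        assert len(strong) >= 3  # normal/fatigued pairs correlate ~1 by design
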