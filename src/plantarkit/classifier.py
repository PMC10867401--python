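"""Posture / fatigue window classification as a scikit-learn estimator.

:class:`GaitCNNClassifier` wraps the NumPy 1-D CNN in the familiar
fit/predict/score surface, so it composes with sklearn model selection
(``cross_val_score``, ``GridSearchCV``) and pipelines.  Channels are
standardized with a per-channel z-score whose statistics come from the
training set only — amplitude differences between classes (a fatigued gait is
flatter) survive because the same affine map is applied to every window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.utils.validation import check_is_fitted

from .cnn import Adam, CNNSpec, Conv1DNet, cosine_lr, softmax_cross_entropy


@dataclass
class EvalReport:
    """Test-set evaluation: overall and per-class accuracy plus confusion."""

    accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray  # rows = true class, cols = predicted
    classes: np.ndarray
    history: dict | None = None


class GaitCNNClassifier(ClassifierMixin, BaseEstimator):
    """Segmentation-assisted 1-D CNN for 8-channel pressure windows.

    Parameters mirror :class:`plantarkit.cnn.CNNSpec`; ``fit`` expects
    ``X`` of shape (n_windows, 8, 120) and integer labels ``y``.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray
        Sorted class labels.
    net_ : Conv1DNet
        The trained network.
    history_ : dict
        Per-epoch training ``loss``, ``accuracy`` and ``lr``.
    n_parameters_ : int
        Trainable parameter count.
    """

    def __init__(
        self,
        filters: tuple[int, ...] = (128, 128, 256, 256),
        kernel_size: int = 7,
        pool_stride: int = 2,
        epochs: int = 200,
        batch_size: int = 48,
        learning_rate: float = 1.0e-3,
        lr_schedule: str = "cosine",
        standardize: bool = True,
        random_state: int = 2023,
    ):
        self.filters = filters
        self.kernel_size = kernel_size
        self.pool_stride = pool_stride
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _spec(self, n_classes: int) -> CNNSpec:
        return CNNSpec(
            filters=tuple(self.filters),
            kernel_size=self.kernel_size,
            pool_stride=self.pool_stride,
            n_classes=n_classes,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            lr_schedule=self.lr_schedule,
        )

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, window_length)")
        return X

    def _apply_scaler(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self.scaler_mean_[None, :, None]) / self.scaler_std_[None, :, None]

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        spec = self._spec(n_classes)

        if self.standardize:
            self.scaler_mean_ = X.mean(axis=(0, 2)).astype(np.float32)
            std = X.std(axis=(0, 2)).astype(np.float32)
            self.scaler_std_ = np.where(std > 0, std, 1.0).astype(np.float32)
        Xs = self._apply_scaler(X)

        seed = int(self.random_state) % (2**31)
        net = Conv1DNet(spec, X.shape[1:], seed=seed)
        opt = Adam(net.parameters)
        rng = np.random.default_rng(seed)
        onehot = np.eye(n_classes, dtype=np.float32)[y_idx]

        history = {"loss": [], "accuracy": [], "lr": []}
        n = X.shape[0]
        for epoch in range(spec.epochs):
            if spec.lr_schedule == "cosine":
                lr = cosine_lr(spec.learning_rate, epoch, spec.epochs)
            else:
                lr = spec.learning_rate
            order = rng.permutation(n)
            losses, correct = [], 0
            for i in range(0, n, spec.batch_size):
                sel = order[i : i + spec.batch_size]
                logits, cache = net.forward(Xs[sel], want_cache=True)
                loss, dlogits = softmax_cross_entropy(logits, onehot[sel])
                grads = net.backward(dlogits, cache)
                opt.step(grads, lr)
                losses.append(loss * sel.size)
                correct += int((logits.argmax(axis=1) == y_idx[sel]).sum())
            history["loss"].append(float(np.sum(losses) / n))
            history["accuracy"].append(correct / n)
            history["lr"].append(float(lr))

        self.net_ = net
        self.history_ = history
        self.n_parameters_ = net.n_parameters
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    # ------------------------------------------------------------------
    def decision_function(self, X):
        check_is_fitted(self, "net_")
        X = self._apply_scaler(self._check_X(X))
        out = []
        for i in range(0, X.shape[0], 256):
            out.append(self.net_.forward(X[i : i + 256]))
        return np.concatenate(out)

    def predict_proba(self, X):
        logits = self.decision_function(X)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def evaluate(self, X, y) -> EvalReport:
        """Confusion matrix, overall and per-class accuracy on labelled data."""
        y = np.asarray(y)
        check_is_fitted(self, "net_")
        unknown = np.setdiff1d(np.unique(y), self.classes_)
        if unknown.size:
            raise ValueError(f"labels {unknown.tolist()} outside the fitted classes")
        y_pred = self.predict(X)
        return evaluate_predictions(y, y_pred, self.classes_, self.history_)


def evaluate_predictions(
    y_true, y_pred, classes, history: dict | None = None
) -> EvalReport:
    """Build an :class:`EvalReport` from labels and predictions.

    Row sums of the confusion matrix equal the per-class test counts and the
    overall accuracy is its trace over the total.
    """
    classes = np.asarray(classes)
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    row = conf.sum(axis=1)
    per_class = np.divide(
        np.diag(conf), row, out=np.zeros(len(classes), dtype=float), where=row > 0
    )
    total = conf.sum()
    return EvalReport(
        accuracy=float(np.trace(conf) / total) if total else 0.0,
        per_class_accuracy=per_class,
        confusion=conf,
        classes=classes,
        history=history,
    )


def correlation_matrix(
    class_vectors: np.ndarray, strong_threshold: float = 0.3
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Pairwise Pearson correlation of per-class mean waveforms.

    ``class_vectors`` is (n_classes, n_features) — e.g. the flattened 8 x 120
    mean cycle of each posture.  Returns the symmetric unit-diagonal matrix
    and the list of off-diagonal pairs with r above ``strong_threshold``
    ("strongly correlated" pairs that motivate a learned classifier over raw
    waveform matching).
    """
    V = np.asarray(class_vectors, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("need at least two class vectors")
    if np.any(V.std(axis=1) == 0):
        raise ValueError("zero-variance class vector")
    R = np.corrcoef(V)
    strong = [
        (i, j, float(R[i, j]))
        for i in range(R.shape[0])
        for j in range(i + 1, R.shape[0])
        if R[i, j] > strong_threshold
    ]
    return R, strong


# ----------------------------------------------------------------------
def save_model(clf: GaitCNNClassifier, path: str | Path) -> None:
    """Persist a fitted classifier as ``<path>`` (.npz) + ``<path>.json`` meta."""
    check_is_fitted(clf, "net_")
    path = Path(path)
    arrays = {f"param_{i}": p for i, p in enumerate(clf.net_.parameters)}
    arrays["classes"] = clf.classes_
    if clf.standardize:
        arrays["scaler_mean"] = clf.scaler_mean_
        arrays["scaler_std"] = clf.scaler_std_
    np.savez(path, **arrays)
    meta = {
        "params": clf.get_params(),
        "input_shape": list(clf.net_.input_shape),
        "history": clf.history_,
    }
    meta["params"]["filters"] = list(meta["params"]["filters"])
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh)


def load_model(path: str | Path) -> GaitCNNClassifier:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    params = meta["params"]
    params["filters"] = tuple(params["filters"])
    clf = GaitCNNClassifier(**params)
    data = np.load(path)
    clf.classes_ = data["classes"]
    spec = clf._spec(clf.classes_.size)
    net = Conv1DNet(spec, tuple(meta["input_shape"]), seed=0)
    net.set_weights([data[f"param_{i}"] for i in range(len(net.parameters))])
    clf.net_ = net
    if clf.standardize:
        clf.scaler_mean_ = data["scaler_mean"]
        clf.scaler_std_ = data["scaler_std"]
    clf.history_ = meta["history"]
    clf.n_parameters_ = net.n_parameters
    clf.n_features_in_ = int(np.prod(meta["input_shape"]))
    return clf
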