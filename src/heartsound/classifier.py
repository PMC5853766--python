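"""Five-class heart-sound CNN and the recording-level diagnosis rule.

Architecture: 40x40 spectrogram input -> conv (8 kernels, 5x5) -> ReLU ->
2x2 max pool -> conv (16 kernels, 5x5) -> ReLU -> 2x2 max pool -> dense
(128 units, ReLU) -> 5-node readout, trained with softmax cross-entropy
and Adam at learning rate 0.001. With valid convolutions the spatial path
is 40 -> 36 -> 18 -> 14 -> 7, giving a 784-dimensional flattened map.

The classifier is per-cycle; a whole recording is diagnosed by averaging
its per-cycle probability vectors, and the diagnosis counts as correct
when the probability assigned to the true category is at least 50%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .core import SoundClass
from .errors import ConfigurationError
from .features import SpectrogramFeature

__all__ = ["HeartSoundCNN", "ClassProbabilities", "RecordingDiagnosis",
           "diagnose_recording", "CLASS_ORDER"]

#: canonical label order of the probability vector
CLASS_ORDER = (SoundClass.NORMAL, SoundClass.S3, SoundClass.S4,
               SoundClass.SYSTOLIC_MURMUR, SoundClass.DIASTOLIC_MURMUR)

_INPUT_SIZE = 40


@dataclass(frozen=True)
class ClassProbabilities:
    """A 5-way probability vector over the diagnostic categories."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (5,):
            raise ConfigurationError("ClassProbabilities needs exactly 5 entries")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ConfigurationError("probabilities must be >= 0 and sum to 1")

    def __getitem__(self, cls: SoundClass) -> float:
        return float(self.p[CLASS_ORDER.index(cls)])

    @property
    def predicted_class(self) -> SoundClass:
        return CLASS_ORDER[int(np.argmax(self.p))]


@dataclass(frozen=True)
class RecordingDiagnosis:
    """Per-cycle probabilities plus their mean and the resulting call."""

    per_cycle: tuple[ClassProbabilities, ...]
    aggregate: ClassProbabilities
    predicted_class: SoundClass
    correct_given_truth: bool | None = None
    truth: SoundClass | None = None

    def to_dict(self) -> dict:
        return {
            "n_cycles": len(self.per_cycle),
            "aggregate": {c.value: round(float(p), 6)
                          for c, p in zip(CLASS_ORDER, self.aggregate.p)},
            "predicted_class": self.predicted_class.value,
            "truth": self.truth.value if self.truth else None,
            "correct_given_truth": self.correct_given_truth,
        }


def _as_matrix(X) -> np.ndarray:
    """Coerce features / arrays to a float32 (n, 1, 40, 40) batch."""
    if isinstance(X, (list, tuple)):
        if len(X) and isinstance(X[0], SpectrogramFeature):
            X = np.stack([f.matrix for f in X])
        else:
            X = np.asarray(X)
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    if X.ndim == 3:
        X = X[:, None, :, :]
    if X.shape[1:] != (1, _INPUT_SIZE, _INPUT_SIZE):
        raise ConfigurationError(
            f"expected (n, {_INPUT_SIZE}, {_INPUT_SIZE}) features, got {X.shape}"
        )
    return X


class HeartSoundCNN(ClassifierMixin, BaseEstimator):
    """Small CNN classifier over 40x40 cycle spectrograms (NumPy backend).

    Follows the sklearn estimator protocol: ``fit(X, y)`` with X of shape
    (n, 40, 40) (or a list of :class:`SpectrogramFeature`) and y of class
    labels; ``predict_proba`` / ``predict`` after fitting. Training is
    fully deterministic given ``random_state``.

    Parameters
    ----------
    kernel_size : side of the square convolution kernels (5 in the
        reference architecture).
    n_kernels1, n_kernels2 : filters in the first and second conv block.
    dense_units : width of the fully connected layer.
    learning_rate : Adam step size.
    batch_size, epochs : minibatch SGD schedule.
    validation_fraction : held-out fraction (stratified) logged per epoch;
        0 disables the split.
    random_state : seed for init, shuffling and the validation split.
    """

    def __init__(self, kernel_size: int = 5, n_kernels1: int = 8, n_kernels2: int = 16,
                 dense_units: int = 128, learning_rate: float = 1e-3,
                 batch_size: int = 32, epochs: int = 30,
                 validation_fraction: float = 0.0, random_state: int = 0):
        self.kernel_size = kernel_size
        self.n_kernels1 = n_kernels1
        self.n_kernels2 = n_kernels2
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ build
    def _check_config(self) -> None:
        if self.kernel_size != 5:
            raise ConfigurationError("kernel_size must be 5 (5x5 kernels)")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if min(self.n_kernels1, self.n_kernels2, self.dense_units) < 1:
            raise ConfigurationError("layer widths must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("batch_size must be >= 1 and epochs >= 0")

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        k = self.kernel_size
        f1, f2, d = self.n_kernels1, self.n_kernels2, self.dense_units
        side = (_INPUT_SIZE - k + 1) // 2  # after conv1+pool
        side = (side - k + 1) // 2         # after conv2+pool
        flat = f2 * side * side
        self._flat_side_ = side

        def he(shape, fan_in):
            return rng.normal(0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        return {
            "w1": he((f1, 1, k, k), k * k),
            "b1": np.zeros(f1, dtype=np.float32),
            "w2": he((f2, f1, k, k), f1 * k * k),
            "b2": np.zeros(f2, dtype=np.float32),
            "w3": he((flat, d), flat),
            "b3": np.zeros(d, dtype=np.float32),
            "w4": he((d, 5), d),
            "b4": np.zeros(5, dtype=np.float32),
        }

    def _forward(self, x: np.ndarray, params: dict, want_cache: bool = False):
        p = params
        c1, cache1 = nn.conv2d_forward(x, p["w1"], p["b1"])
        a1 = nn.relu(c1)
        p1, pc1 = nn.maxpool2_forward(a1)
        c2, cache2 = nn.conv2d_forward(p1, p["w2"], p["b2"])
        a2 = nn.relu(c2)
        p2, pc2 = nn.maxpool2_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = nn.relu(z3)
        logits = a3 @ p["w4"] + p["b4"]
        if not want_cache:
            return logits
        return logits, (c1, cache1, pc1, p1, c2, cache2, pc2, p2, flat, z3, a3)

    def _backward(self, dlogits: np.ndarray, x: np.ndarray, params: dict, cache):
        c1, cache1, pc1, p1, c2, cache2, pc2, p2, flat, z3, a3 = cache
        p = params
        grads: dict[str, np.ndarray] = {}
        grads["w4"] = a3.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["w4"].T
        dz3 = nn.relu_backward(da3, z3)
        grads["w3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = nn.maxpool2_backward(dp2, pc2)
        dc2 = nn.relu_backward(da2, c2)
        dp1, grads["w2"], grads["b2"] = nn.conv2d_backward(dc2, cache2)
        da1 = nn.maxpool2_backward(dp1, pc1)
        dc1 = nn.relu_backward(da1, c1)
        _, grads["w1"], grads["b1"] = nn.conv2d_backward(dc1, cache1, need_dx=False)
        return grads

    # -------------------------------------------------------------------- fit
    def fit(self, X, y):
        self._check_config()
        X = _as_matrix(X)
        y = np.asarray([SoundClass(v).value if not isinstance(v, SoundClass) else v.value
                        for v in np.ravel(y)])
        if len(y) != len(X):
            raise ConfigurationError(
                f"feature/label length mismatch: {len(X)} features, {len(y)} labels"
            )
        self.classes_ = np.array([c.value for c in CLASS_ORDER if c.value in set(y)])
        if len(self.classes_) < 2:
            raise ConfigurationError("training data must contain at least 2 classes")
        # fixed 5-slot output indexed by CLASS_ORDER; absent classes stay unused
        label_idx = np.array([[c.value for c in CLASS_ORDER].index(v) for v in y])

        rng = np.random.default_rng(self.random_state)
        params = self._init_params(rng)

        if self.validation_fraction > 0:
            idx_tr, idx_va = train_test_split(
                np.arange(len(X)), test_size=self.validation_fraction,
                stratify=label_idx, random_state=self.random_state)
        else:
            idx_tr, idx_va = np.arange(len(X)), np.array([], dtype=int)
        Xtr, ytr = X[idx_tr], label_idx[idx_tr]
        Xva, yva = X[idx_va], label_idx[idx_va]

        onehot = np.zeros((len(ytr), 5), dtype=np.float32)
        onehot[np.arange(len(ytr)), ytr] = 1.0

        adam = nn.AdamState(params, lr=self.learning_rate)
        self.loss_curve_, self.accuracy_curve_, self.val_accuracy_curve_ = [], [], []
        n = len(Xtr)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, hits = [], 0
            for lo in range(0, n, self.batch_size):
                sel = order[lo: lo + self.batch_size]
                xb, yb = Xtr[sel], onehot[sel]
                logits, cache = self._forward(xb, params, want_cache=True)
                probs = nn.softmax(logits)
                losses.append(nn.cross_entropy(probs, yb) * len(sel))
                hits += int((probs.argmax(1) == ytr[sel]).sum())
                if self.learning_rate > 0:
                    dlogits = ((probs - yb) / len(sel)).astype(np.float32)
                    grads = self._backward(dlogits, xb, params, cache)
                    adam.step(params, grads)
            self.loss_curve_.append(sum(losses) / n)
            self.accuracy_curve_.append(hits / n)
            if len(Xva):
                pv = nn.softmax(self._forward(Xva, params))
                self.val_accuracy_curve_.append(float((pv.argmax(1) == yva).mean()))
        self.params_ = params
        self.n_features_in_ = _INPUT_SIZE * _INPUT_SIZE
        return self

    # ---------------------------------------------------------------- predict
    def _proba5(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = _as_matrix(X)
        out = []
        for lo in range(0, len(X), 256):
            out.append(nn.softmax(self._forward(X[lo: lo + 256], self.params_)))
        return np.concatenate(out) if out else np.zeros((0, 5))

    def predict_proba(self, X) -> np.ndarray:
        """Probabilities over all five categories, in CLASS_ORDER."""
        return self._proba5(X)

    def predict(self, X) -> np.ndarray:
        probs = self._proba5(X)
        return np.array([CLASS_ORDER[i].value for i in probs.argmax(axis=1)])

    def predict_cycle(self, feature: SpectrogramFeature) -> ClassProbabilities:
        return ClassProbabilities(self._proba5([feature])[0].astype(float))

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        check_is_fitted(self, "params_")
        cfg = json.dumps(self.get_params())
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 __classes__=self.classes_, **self.params_)

    @classmethod
    def load(cls, path) -> "HeartSoundCNN":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(bytes(z["__config__"]).decode())
            model = cls(**cfg)
            model.classes_ = z["__classes__"]
            model.params_ = {k: z[k] for k in z.files
                             if k not in ("__config__", "__classes__")}
        model.n_features_in_ = _INPUT_SIZE * _INPUT_SIZE
        return model


def diagnose_recording(model: HeartSoundCNN, features: list[SpectrogramFeature],
                       truth: SoundClass | None = None) -> RecordingDiagnosis:
    """Diagnose a whole recording from its per-cycle features.

    The aggregate is the arithmetic mean of per-cycle probability vectors;
    when the true category is supplied, the diagnosis is correct iff the
    aggregate probability of the truth is at least 50%.
    """
    if not features:
        raise ConfigurationError("cannot diagnose a recording with no features")
    probs = model.predict_proba(features)
    agg = probs.mean(axis=0)
    agg = agg / agg.sum()
    aggregate = ClassProbabilities(agg.astype(float))
    correct = None
    if truth is not None:
        truth = SoundClass(truth)
        correct = bool(aggregate[truth] >= 0.5)
    return RecordingDiagnosis(
        per_cycle=tuple(ClassProbabilities(p.astype(float)) for p in probs),
        aggregate=aggregate,
        predicted_class=aggregate.predicted_class,
        correct_given_truth=correct,
        truth=truth,
    )
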