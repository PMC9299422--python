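"""Step 1: the residual CNN segment encoder, as a scikit-learn estimator.

``SegmentEncoderClassifier`` scores single 7-s spectrogram segments for pAF
(``predict_proba``) and exposes the penultimate latent vector
(``transform``) that the patient-level model aggregates.  Training is
binary cross-entropy with Adam, patient-wise validation splitting to avoid
leakage, and early stopping on validation loss.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, SmallResNet, bce_with_logits, sigmoid

__all__ = ["SegmentEncoderClassifier", "score_segments",
           "save_encoder", "load_encoder"]


class SegmentEncoderClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Residual CNN over (3, F, T) log-magnitude STFT spectrograms.

    Parameters
    ----------
    n_blocks : int, default 3
        Number of residual blocks; must equal ``len(channels)``.
    channels : tuple of int, default (16, 32, 64)
        Channel width of each block; stride-2 downsampling between blocks.
    kernel_size : int, default 3
    latent_dim : int, default 32
        Dimension of the exposed latent vector.
    learning_rate : float, default 1e-4
    batch_size : int, default 1024
        Reducible for desk-scale runs; the large default follows common GPU
        practice for this architecture.
    max_epochs : int, default 30
    patience : int, default 5
        Early-stopping patience on validation loss.
    validation_fraction : float, default 0.2
        Fraction of patients (if ``groups`` passed to ``fit``) or segments
        held out for validation.
    class_weight : None or 'balanced', default None
        Inverse-prevalence loss weighting for imbalanced cohorts.
    random_state : int, default 0

    Attributes
    ----------
    model_ : SmallResNet
    classes_ : ndarray of shape (2,)
    loss_curve_, val_loss_curve_ : list of float, per epoch
    best_epoch_ : int
    """

    def __init__(self, n_blocks=3, channels=(16, 32, 64), kernel_size=3,
                 latent_dim=32, learning_rate=1e-4, batch_size=1024,
                 max_epochs=30, patience=5, validation_fraction=0.2,
                 class_weight=None, random_state=0):
        self.n_blocks = n_blocks
        self.channels = channels
        self.kernel_size = kernel_size
        self.latent_dim = latent_dim
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.class_weight = class_weight
        self.random_state = random_state

    def _validate_params_(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if len(self.channels) != self.n_blocks:
            raise ValueError("len(channels) must equal n_blocks")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def _build(self, in_channels):
        return SmallResNet(
            in_channels=in_channels,
            channels=tuple(self.channels),
            kernel_size=self.kernel_size,
            latent_dim=self.latent_dim,
            seed=self.random_state,
        )

    def fit(self, X, y, groups=None, sample_weight=None):
        """Train on spectrograms ``X`` of shape (n, 3, F, T), labels ``y``.

        ``groups`` (patient ids) makes the validation split patient-wise,
        which is required for honest early stopping in this application.
        """
        self._validate_params_()
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y).astype(int).ravel()
        if X.ndim != 4:
            raise ValueError("X must be 4-D: (n, channels, freq, time)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")

        rng = np.random.default_rng(self.random_state)
        idx = np.arange(len(y))
        if groups is not None:
            groups = np.asarray(groups)
            splitter = GroupShuffleSplit(
                n_splits=1, test_size=self.validation_fraction,
                random_state=self.random_state)
            tr, va = next(splitter.split(idx, y, groups))
            # patient-wise splits can strand one class; fall back if so
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                tr, va = train_test_split(
                    idx, test_size=self.validation_fraction, stratify=y,
                    random_state=self.random_state)
        else:
            tr, va = train_test_split(
                idx, test_size=self.validation_fraction, stratify=y,
                random_state=self.random_state)

        w = np.ones(len(y))
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
        elif self.class_weight == "balanced":
            prev = y.mean()
            w = np.where(y == 1, 0.5 / max(prev, 1e-9),
                         0.5 / max(1 - prev, 1e-9))

        model = self._build(X.shape[1])
        opt = Adam(model.params(), lr=self.learning_rate)
        self.loss_curve_, self.val_loss_curve_ = [], []
        best_val, best_state, best_epoch = np.inf, None, -1
        bad_epochs = 0
        bs = int(self.batch_size)

        for epoch in range(self.max_epochs):
            order = rng.permutation(tr)
            epoch_loss, n_batches = 0.0, 0
            for b0 in range(0, len(order), bs):
                batch = order[b0:b0 + bs]
                model.zero_grad()
                logits, _ = model.forward(X[batch], training=True)
                loss, dlog = bce_with_logits(logits, y[batch], w[batch])
                model.backward(dlog)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            self.loss_curve_.append(epoch_loss / max(n_batches, 1))

            val_logits = self._forward_eval(model, X[va])[0]
            val_loss, _ = bce_with_logits(val_logits, y[va], w[va])
            self.val_loss_curve_.append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val, best_epoch = val_loss, epoch
                best_state = copy.deepcopy(model.state_arrays())
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > self.patience:
                    break

        if best_state is not None:
            model.load_state_arrays(best_state)
        self.model_ = model
        self.best_epoch_ = best_epoch
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        self._input_shape_ = X.shape[1:]
        return self

    @staticmethod
    def _forward_eval(model, X, batch=512):
        logits, latents = [], []
        for b0 in range(0, len(X), batch):
            lo, la = model.forward(X[b0:b0 + batch], training=False)
            logits.append(lo)
            latents.append(la)
        if not logits:
            return (np.empty(0),
                    np.empty((0, model.latent_dim)))
        return np.concatenate(logits), np.vstack(latents)

    def _check_X(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != self._input_shape_:
            raise ValueError(
                f"expected input of shape (n, {self._input_shape_}); "
                f"got {X.shape}")
        return X

    def decision_function(self, X):
        return self._forward_eval(self.model_, self._check_X(X))[0]

    def predict_proba(self, X):
        p = sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)

    def transform(self, X):
        """Latent embedding of each segment, shape (n, latent_dim)."""
        return self._forward_eval(self.model_, self._check_X(X))[1]


def score_segments(estimator: SegmentEncoderClassifier, X: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Order-preserving (probabilities, latents) for a batch of spectrograms."""
    X = estimator._check_X(X)
    logits, latents = estimator._forward_eval(estimator.model_, X)
    return sigmoid(logits), latents


def save_encoder(estimator: SegmentEncoderClassifier, path) -> None:
    """Persist a fitted encoder to a single .npz file with config embedded."""
    import json

    check_is_fitted(estimator, "model_")
    meta = {
        "params": estimator.get_params(),
        "input_shape": list(estimator._input_shape_),
        "best_epoch": int(estimator.best_epoch_),
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **estimator.model_.state_arrays(),
    )


def load_encoder(path) -> SegmentEncoderClassifier:
    """Load an encoder saved by :func:`save_encoder`."""
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    params = meta["params"]
    params["channels"] = tuple(params["channels"])
    est = SegmentEncoderClassifier(**params)
    est._validate_params_()
    shape = tuple(meta["input_shape"])
    est._input_shape_ = shape
    est.n_features_in_ = int(np.prod(shape))
    est.classes_ = np.array([0, 1])
    est.best_epoch_ = meta["best_epoch"]
    est.model_ = est._build(shape[0])
    est.model_.load_state_arrays(state)
    return est
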