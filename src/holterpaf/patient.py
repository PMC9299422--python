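"""Step 2: temporal aggregation of segment latents + gradient boosting.

A patient's variable-length, time-ordered sequence of segment scores and
latent vectors is pooled into a fixed-length feature vector by dividing the
recording span into ``n_bins`` equal clock-time bins (default 24, one per
hour of a 24-h exam) and summarising each bin, plus a global summary block.
A LightGBM binary classifier then maps the vector to a patient-level pAF
probability.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "aggregate_latents",
    "feature_length",
    "PatientBoostedClassifier",
]


def feature_length(n_bins: int, latent_dim: int) -> int:
    """Length of the patient feature vector: B*(latent_dim+3) + 5."""
    return n_bins * (latent_dim + 3) + 5


def aggregate_latents(
    probabilities: np.ndarray,
    latents: np.ndarray,
    start_times: list[datetime],
    span_start: datetime,
    span_end: datetime,
    n_bins: int = 24,
    contains_sve: np.ndarray | None = None,
    latent_dim: int | None = None,
) -> np.ndarray:
    """Pool one patient's segment scores into a fixed-length vector.

    Per temporal bin: [mean latent (latent_dim), mean probability, segment
    count, bin-empty flag]; global block: [mean, max, SD of probabilities,
    fraction of SVE-containing segments, total count].  Deterministic and
    insensitive to input ordering (bins are defined by timestamps).  With
    zero segments every bin is empty-flagged and the global block is zeros —
    still a valid input to ``predict``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    probabilities = np.asarray(probabilities, dtype=float).ravel()
    latents = np.asarray(latents, dtype=float)
    n = probabilities.shape[0]
    if latent_dim is None:
        if latents.ndim != 2:
            raise ValueError("latent_dim required when no latents are given")
        latent_dim = latents.shape[1]
    if n and latents.shape != (n, latent_dim):
        raise ValueError("latents must be (n_segments, latent_dim)")
    if len(start_times) != n:
        raise ValueError("start_times length mismatch")

    total_s = max((span_end - span_start).total_seconds(), 1e-9)
    offsets = np.array(
        [(t - span_start).total_seconds() for t in start_times], dtype=float)
    bins = np.clip((offsets / total_s * n_bins).astype(int), 0, n_bins - 1)

    features: list[float] = []
    for b in range(n_bins):
        in_bin = bins == b if n else np.zeros(0, dtype=bool)
        cnt = int(in_bin.sum())
        if cnt:
            features.extend(latents[in_bin].mean(axis=0))
            features.append(float(probabilities[in_bin].mean()))
            features.append(float(cnt))
            features.append(0.0)
        else:
            features.extend([0.0] * latent_dim)
            features.extend([0.0, 0.0, 1.0])

    if n:
        sve_frac = (float(np.asarray(contains_sve, dtype=bool).mean())
                    if contains_sve is not None else 0.0)
        features.extend([
            float(probabilities.mean()),
            float(probabilities.max()),
            float(probabilities.std()),
            sve_frac,
            float(n),
        ])
    else:
        features.extend([0.0, 0.0, 0.0, 0.0, 0.0])

    vec = np.asarray(features, dtype=float)
    assert vec.shape[0] == feature_length(n_bins, latent_dim)
    return vec


_SEARCH_SPACE = {
    "n_estimators": [100, 200, 400],
    "learning_rate": [0.02, 0.05, 0.1],
    "num_leaves": [7, 15, 31],
    "min_child_samples": [3, 5, 10],
    "colsample_bytree": [0.7, 0.9, 1.0],
}


class PatientBoostedClassifier(ClassifierMixin, BaseEstimator):
    """LightGBM binary classifier over patient feature vectors.

    Fixed defaults sized for small cohorts; ``n_search > 0`` enables a
    seeded random search over a small grid with an inner stratified CV,
    standing in for heavier hyper-parameter tuners.
    """

    def __init__(self, n_estimators=200, learning_rate=0.05, num_leaves=15,
                 min_child_samples=3, colsample_bytree=0.9, subsample=1.0,
                 n_search=0, random_state=0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.num_leaves = num_leaves
        self.min_child_samples = min_child_samples
        self.colsample_bytree = colsample_bytree
        self.subsample = subsample
        self.n_search = n_search
        self.random_state = random_state

    def _make(self, **over):
        params = dict(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            num_leaves=self.num_leaves,
            min_child_samples=self.min_child_samples,
            colsample_bytree=self.colsample_bytree,
            subsample=self.subsample,
        )
        params.update(over)
        return LGBMClassifier(
            objective="binary",
            random_state=self.random_state,
            deterministic=True,
            n_jobs=1,
            verbose=-1,
            min_data_in_bin=1,  # cohorts are small; default binning can
            **params,           # otherwise collapse features to one bin
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_patients, n_features)")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        if np.min(np.bincount(y)) < 2:
            raise ValueError("need at least 2 patients per class")

        if self.n_search > 0:
            self._random_search(X, y)
        else:
            self.model_ = self._make().fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _random_search(self, X, y):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(self.random_state)
        keys = sorted(_SEARCH_SPACE)
        n_splits = min(3, int(np.min(np.bincount(y))))
        best_auc, best_params = -np.inf, {}
        candidates = [{}] + [
            {k: _SEARCH_SPACE[k][rng.integers(len(_SEARCH_SPACE[k]))]
             for k in keys}
            for _ in range(self.n_search)
        ]
        for cand in candidates:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                  random_state=self.random_state)
            aucs = []
            for tr, va in skf.split(X, y):
                if len(np.unique(y[va])) < 2:
                    continue
                m = self._make(**cand).fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[va], m.predict_proba(X[va])[:, 1]))
            score = float(np.mean(aucs)) if aucs else -np.inf
            if score > best_auc:
                best_auc, best_params = score, cand
        self.best_params_ = best_params
        self.best_score_ = best_auc
        self.model_ = self._make(**best_params).fit(X, y)

    def _check_X(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return X

    def predict_proba(self, X):
        import warnings

        with warnings.catch_warnings():
            # LightGBM assigns default feature names at fit; plain ndarray
            # prediction then triggers a spurious sklearn name-check warning
            warnings.filterwarnings(
                "ignore", message=".*does not have valid feature names.*")
            return self.model_.predict_proba(self._check_X(X))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
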