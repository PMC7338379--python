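"""Estimators for spheroid viability classification.

`SpheroidCNNClassifier` wraps the convolutional network in a scikit-learn
estimator: ``fit(X, y)`` on a stack of single-channel rasters, with optional
real-time augmentation of training batches, and ``predict`` /
``predict_proba`` on clean images. `EdgeContrastBaseline` is the
interpretable counterpart — a shallow decision rule on classical morphometry
features (edge contrast, fragment count) — used to confirm that the image
classes carry learnable signal before any network is trained.

Both compose with scikit-learn model selection (``clone``, ``get_params`` /
``set_params``, ``cross_val_score``).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .architecture import build_model, default_model_spec
from .augment import AugmentationConfig, augment_batch
from .morphometry import compute_features, segment_spheroid

__all__ = ["SpheroidCNNClassifier", "EdgeContrastBaseline"]


def _as_image_stack(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 4 and X.shape[-1] == 1:
        X = X[..., 0]
    if X.ndim != 3:
        raise ValueError(f"expected (n, h, w) image stack, got shape {X.shape}")
    if X.size and (X.min() < -1e-6 or X.max() > 1.0 + 1e-6):
        raise ValueError("image intensities must lie in [0, 1]")
    return X


class SpheroidCNNClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional viability classifier (3x3 conv stack, dense head).

    Parameters
    ----------
    epochs : int
        Training epochs; each epoch visits every training image once.
    batch_size : int
        Minibatch size for the Adam updates.
    learning_rate : float
        Adam step size.
    dropout : float
        Dropout rate after the 128-unit dense layer.
    augmentation : AugmentationConfig or None
        If given, training batches are augmented on the fly (fresh random
        draws each epoch); validation/predict inputs are never augmented.
    random_state : int
        Seed for weight init, shuffling, dropout and augmentation.

    Attributes
    ----------
    classes_ : ndarray of class labels (sorted).
    model_ : the underlying network.
    n_parameters_ : total trainable parameters.
    history_ : dict with per-epoch ``acc`` (and ``val_acc`` when validation
        data is passed to ``fit``).
    """

    def __init__(
        self,
        epochs: int = 10,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        dropout: float = 0.5,
        augmentation: Optional[AugmentationConfig] = None,
        random_state: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.augmentation = augmentation
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = _as_image_stack(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty training set")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")

        h, w = X.shape[1:]
        spec = default_model_spec(
            input_shape=(h, w, 1),
            n_classes=len(self.classes_),
            dropout_rate=self.dropout,
        )
        ss = np.random.SeedSequence(self.random_state)
        net_seed, shuffle_seed, aug_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        ]
        self.model_ = build_model(
            spec, seed=net_seed, learning_rate=self.learning_rate
        )
        self.n_parameters_ = self.model_.n_parameters
        self.model_spec_ = spec

        if X_val is not None:
            X_val = _as_image_stack(X_val)
            y_val_idx = np.searchsorted(self.classes_, np.asarray(y_val))

        rng = np.random.default_rng(shuffle_seed)
        history: dict[str, list[float]] = {"acc": [], "loss": []}
        if X_val is not None:
            history["val_acc"] = []
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_acc, epoch_loss, seen = 0.0, 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx]
                if self.augmentation is not None:
                    xb = augment_batch(
                        xb, self.augmentation, seed=aug_seed + epoch * 100_003 + start
                    )
                loss, acc = self.model_.train_batch(xb, y_idx[idx])
                epoch_acc += acc * len(idx)
                epoch_loss += loss * len(idx)
                seen += len(idx)
            history["acc"].append(epoch_acc / seen)
            history["loss"].append(epoch_loss / seen)
            if X_val is not None:
                val_pred = self.model_.predict_proba(X_val).argmax(axis=1)
                history["val_acc"].append(float(np.mean(val_pred == y_val_idx)))
        self.history_ = history
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _as_image_stack(X)
        if X.shape[0] == 0:
            return np.zeros((0, len(self.classes_)))
        return self.model_.predict_proba(X, batch_size=self.batch_size)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]


class EdgeContrastBaseline(BaseEstimator, ClassifierMixin):
    """Threshold rule on morphometry features (edge contrast + fragment count).

    A depth-limited decision tree on up to three interpretable features —
    boundary edge contrast, connected-component count and solidity — which
    for three ordered phenotype classes reduces to two learned thresholds on
    the dominant feature. Serves as the classical baseline the CNN must beat
    and as a guard that the simulated classes are separable by the phenotype
    the simulator claims to encode.
    """

    def __init__(self, features: tuple = ("edge_contrast", "n_components"), max_depth: int = 2, random_state: int = 0):
        self.features = features
        self.max_depth = max_depth
        self.random_state = random_state

    def _featurize(self, X) -> np.ndarray:
        X = _as_image_stack(X)
        rows = []
        for img in X:
            feats = compute_features(img, segment_spheroid(img))
            rows.append([getattr(feats, f) for f in self.features])
        return np.asarray(rows, dtype=float)

    def fit(self, X, y):
        F = self._featurize(X)
        self.tree_ = DecisionTreeClassifier(
            max_depth=self.max_depth, random_state=self.random_state
        ).fit(F, y)
        self.classes_ = self.tree_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        return self.tree_.predict(self._featurize(X))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        return self.tree_.predict_proba(self._featurize(X))
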