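"""Backpropagation neural-network classifier over the feature matrix.

The predictor is a feed-forward network trained by error
backpropagation on the standardized input feature matrix (IFM), with
the binary site labels as the output matrix (OM).  Default capacity —
one hidden layer of 100 logistic units, learning rate 0.01, up to 2000
epochs — is sized so the ~900-sample, 194-feature benchmark problem
trains in minutes on one CPU and can interpolate its training set.

Feature columns span several orders of magnitude (moment coefficients
vs. raw residue codes), so each column is standardized to zero mean and
unit variance on the training rows before training; the scaler is part
of the fitted model and is re-used, never re-fit, at prediction time.

Trained weights are carried by the estimator itself (the forward pass
is evaluated in-package), which keeps serialization a plain JSON file
embedding the config, the scaler, the weights, and the feature-layout
version.  A layout-version mismatch at prediction time is an error —
never a silently reordered feature vector.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .features import LAYOUT_VERSION

_ACTIVATIONS = {
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
    "identity": lambda x: x,
}


def fit_scaler(X: np.ndarray) -> StandardScaler:
    """Fit per-column standardization on training rows only.

    Constant columns are mapped to zero (unit divisor convention).
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit the scaler")
    return StandardScaler().fit(X)


def apply_scaler(X: np.ndarray, scaler: StandardScaler) -> np.ndarray:
    return scaler.transform(np.asarray(X, dtype=float))


class CrotonylationClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward backpropagation classifier for Kcr site windows.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Widths of the hidden layers (at least one).
    activation : {'logistic', 'tanh', 'relu'}
        Hidden-layer activation; the output unit is always logistic.
    learning_rate : float
        Initial learning rate of the (adam) backpropagation optimizer.
    max_epochs : int
        Hard cap on training epochs.
    convergence_tol : float
        Training stops early once the loss improves by less than this
        for ``n_iter_no_change`` consecutive epochs.
    n_iter_no_change : int
        Patience of the early-stopping rule above.
    class_weight : None or 'balanced'
        'balanced' duplicates minority-class rows (deterministically,
        from ``random_state``) to even the class counts before
        training; the default keeps the native class ratio.
    random_state : int or None
        Seed for weight initialization and minibatch shuffling; with a
        fixed seed, config and data the fit is exactly reproducible.

    Attributes
    ----------
    scaler_ : StandardScaler
        Per-column standardization fit on the training rows.
    coefs_, intercepts_ : list of ndarray
        Layer weights/biases chaining n_features -> ... -> 1.
    loss_curve_ : list of float
        Training loss per epoch.
    layout_version_ : str
        Feature-layout identifier the model was trained against.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (100,),
        activation: str = "logistic",
        learning_rate: float = 0.01,
        max_epochs: int = 2000,
        convergence_tol: float = 1e-7,
        n_iter_no_change: int = 50,
        class_weight: str | None = None,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.convergence_tol = convergence_tol
        self.n_iter_no_change = n_iter_no_change
        self.class_weight = class_weight
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_params_(self) -> None:
        if not self.hidden_layer_sizes or any(
            int(w) <= 0 for w in self.hidden_layer_sizes
        ):
            raise ValueError("hidden_layer_sizes must hold positive widths")
        if self.activation not in ("logistic", "tanh", "relu"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        for name in ("learning_rate", "max_epochs", "convergence_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.class_weight not in (None, "balanced"):
            raise ValueError("class_weight must be None or 'balanced'")

    def _balance(self, X: np.ndarray, y: np.ndarray):
        """Duplicate minority rows until classes are even (deterministic)."""
        rng = np.random.default_rng(self.random_state)
        counts = {c: int((y == c).sum()) for c in (0, 1)}
        minority = min(counts, key=counts.get)
        deficit = abs(counts[0] - counts[1])
        if deficit == 0:
            return X, y
        pool = np.flatnonzero(y == minority)
        extra = rng.choice(pool, size=deficit, replace=True)
        idx = np.concatenate([np.arange(y.size), extra])
        return X[idx], y[idx]

    def fit(self, X, y, layout_version: str | None = None):
        """Train by backpropagation on standardized features.

        Raises on single-class input and on a divergent (non-finite)
        training loss.
        """
        self._validate_params_()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one label per row")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError(
                f"need both classes present, got labels {np.unique(y)}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite entries")

        self.scaler_ = fit_scaler(X)
        Xs = self.scaler_.transform(X)
        if self.class_weight == "balanced":
            Xs, y = self._balance(Xs, y)

        mlp = MLPClassifier(
            hidden_layer_sizes=tuple(int(w) for w in self.hidden_layer_sizes),
            activation=self.activation,
            solver="adam",
            learning_rate_init=self.learning_rate,
            max_iter=self.max_epochs,
            tol=self.convergence_tol,
            n_iter_no_change=self.n_iter_no_change,
            random_state=self.random_state,
        )
        mlp.fit(Xs, y)
        if not np.all(np.isfinite(mlp.loss_curve_)):
            raise RuntimeError(
                "training diverged: non-finite loss at epoch "
                f"{int(np.argmax(~np.isfinite(mlp.loss_curve_)))}"
            )
        self.coefs_ = [w.copy() for w in mlp.coefs_]
        self.intercepts_ = [b.copy() for b in mlp.intercepts_]
        self.loss_curve_ = list(map(float, mlp.loss_curve_))
        self.n_epochs_ = int(mlp.n_iter_)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.layout_version_ = (
            layout_version if layout_version is not None else LAYOUT_VERSION
        )
        return self

    # ------------------------------------------------------------------
    def _forward(self, Xs: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.activation]
        h = Xs
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            h = act(h @ W + b)
        out = h @ self.coefs_[-1] + self.intercepts_[-1]
        return _ACTIVATIONS["logistic"](out).ravel()

    def _check_input(self, X, layout_version: str | None) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        if layout_version is not None and layout_version != self.layout_version_:
            raise ValueError(
                f"feature layout {layout_version!r} does not match the "
                f"model's {self.layout_version_!r}"
            )
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def predict_score(self, X, layout_version: str | None = None) -> np.ndarray:
        """Site probability score in [0, 1] per sample."""
        X = self._check_input(X, layout_version)
        return self._forward(self.scaler_.transform(X))

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_score(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X, layout_version: str | None = None) -> np.ndarray:
        """Binary labels at the 0.5 score threshold."""
        return (self.predict_score(X, layout_version) >= 0.5).astype(int)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize config, scaler, weights and layout version to JSON."""
        check_is_fitted(self, "coefs_")
        payload = {
            "format": "icrotok-model-v1",
            "layout_version": self.layout_version_,
            "config": {
                **self.get_params(),
                "hidden_layer_sizes": list(self.hidden_layer_sizes),
            },
            "scaler": {
                "mean": self.scaler_.mean_.tolist(),
                "scale": self.scaler_.scale_.tolist(),
            },
            "coefs": [w.tolist() for w in self.coefs_],
            "intercepts": [b.tolist() for b in self.intercepts_],
            "loss_curve": self.loss_curve_,
            "n_epochs": self.n_epochs_,
            "n_features_in": self.n_features_in_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CrotonylationClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "icrotok-model-v1":
            raise ValueError(f"unrecognized model file {path}")
        config = dict(payload["config"])
        config["hidden_layer_sizes"] = tuple(config["hidden_layer_sizes"])
        model = cls(**config)
        scaler = StandardScaler()
        scaler.mean_ = np.array(payload["scaler"]["mean"])
        scaler.scale_ = np.array(payload["scaler"]["scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.size
        model.scaler_ = scaler
        model.coefs_ = [np.array(w) for w in payload["coefs"]]
        model.intercepts_ = [np.array(b) for b in payload["intercepts"]]
        model.loss_curve_ = list(payload["loss_curve"])
        model.n_epochs_ = int(payload["n_epochs"])
        model.n_features_in_ = int(payload["n_features_in"])
        model.layout_version_ = payload["layout_version"]
        model.classes_ = np.array([0, 1])
        return model


def train(X, y, random_state: int | None = None, **config) -> CrotonylationClassifier:
    """Functional wrapper: fit a classifier with the default capacity."""
    return CrotonylationClassifier(random_state=random_state, **config).fit(X, y)
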