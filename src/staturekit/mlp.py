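"""Adult-height regression: a one-hidden-layer perceptron with a banded loss.

The network is 6 inputs -> ``hidden_units`` ReLU units -> 1 linear output
and is trained by plain full-batch gradient descent under the banded
squared loss

    loss = (1/n) * sum_i max(0, |d_i - y_i| - band)^2

with ``band`` = 0.5 cm by default.  Residuals inside the band cost nothing
— repeat stadiometer measurements of the same child differ by about half a
centimetre, so chasing them is fitting noise — while larger residuals are
penalised like ordinary squared error.  The hinge is squared, so the loss
is C^1 everywhere including the band boundary, and ``band = 0`` recovers
mean squared error exactly.

Stock library MLP regressors only offer fixed loss functions, so the
forward/backward pass is written out here; it is a few lines of linear
algebra and keeps the loss exact.

Design choices the training recipe depends on (none dictated by the
architecture itself): inputs are z-scored per feature, hidden weights use
seeded He-uniform initialisation, and the target is z-scored internally —
the network's raw output is mapped back to cm inside the forward pass, so
the loss and its gradient are always evaluated in cm while gradient
descent at the small constant learning rate operates on unit-scale
quantities.  With raw centimetre targets the same learning rate would
need tens of thousands of iterations just to reach the cohort mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MLPConfig",
    "DEFAULT_ITERATIONS",
    "band_loss",
    "band_loss_gradient",
    "BandedMLPRegressor",
    "split_train_validation",
    "train_adult_height_model",
]

#: Iteration counts at which the per-sex networks converge in full training.
DEFAULT_ITERATIONS = {"M": 46000, "F": 48500}


@dataclass
class MLPConfig:
    """Training hyper-parameters for :class:`BandedMLPRegressor`."""

    hidden_units: int = 100
    learning_rate: float = 5e-5
    iterations: int = 46000
    band: float = 0.5
    seed: int = 0
    standardize_inputs: bool = True
    momentum: float = 0.0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.band < 0:
            raise ValueError("band must be >= 0")


def _as_vectors(y, d):
    y = np.asarray(y, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    if y.size != d.size:
        raise ValueError("prediction and target vectors differ in length")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, d


def band_loss(y, d, band: float = 0.5) -> float:
    """Mean of ``max(0, |d_i - y_i| - band)^2`` over the batch (cm^2).

    Zero iff every residual lies within ``band`` in absolute value.
    """
    y, d = _as_vectors(y, d)
    excess = np.maximum(0.0, np.abs(d - y) - band)
    return float(np.mean(excess ** 2))


def band_loss_gradient(y, d, band: float = 0.5) -> np.ndarray:
    """Gradient of :func:`band_loss` with respect to the predictions ``y``.

    Element i is ``(2/n) * sign(y_i - d_i) * max(0, |y_i - d_i| - band)``;
    identically zero inside the band.
    """
    y, d = _as_vectors(y, d)
    r = y - d
    return (2.0 / y.size) * np.sign(r) * np.maximum(0.0, np.abs(r) - band)


class BandedMLPRegressor(BaseEstimator, RegressorMixin):
    """One-hidden-layer ReLU perceptron trained under the banded loss.

    Parameters mirror :class:`MLPConfig`; ``random_state`` seeds both the
    weight initialisation, making training fully deterministic for a given
    (data, parameters, seed) triple.

    Fitted attributes
    -----------------
    coefs_ : list of ndarray
        ``[W1 (n_features, hidden), W2 (hidden, 1)]``.
    intercepts_ : list of ndarray
        ``[b1 (hidden,), b2 (1,)]``.
    feature_means_, feature_scales_ : ndarray
        Per-feature z-scoring state (identity when ``standardize=False``).
    target_mean_, target_scale_ : float
        Target z-scoring state; the forward pass returns
        ``raw_output * target_scale_ + target_mean_`` (cm).
    loss_ : float
        Final training loss (cm^2).
    loss_curve_ : list of (iteration, loss)
        Loss sampled every ``log_every`` iterations plus start and end.
    """

    def __init__(self, hidden_units: int = 100, learning_rate: float = 5e-5,
                 iterations: int = 46000, band: float = 0.5,
                 random_state: int = 0, standardize: bool = True,
                 momentum: float = 0.0, log_every: int = 1000):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.iterations = iterations
        self.band = band
        self.random_state = random_state
        self.standardize = standardize
        self.momentum = momentum
        self.log_every = log_every

    # -- internals --------------------------------------------------------
    def _forward(self, Xs):
        Z = Xs @ self.coefs_[0] + self.intercepts_[0]
        H = np.maximum(Z, 0.0)
        u = (H @ self.coefs_[1]).ravel() + self.intercepts_[1][0]
        return Z, H, u * self.target_scale_ + self.target_mean_

    def fit(self, X, y) -> "BandedMLPRegressor":
        X = np.asarray(X, dtype=float)
        d = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if X.shape[0] != d.size:
            raise ValueError("X and y disagree on sample count")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(d))):
            raise ValueError("training data contains non-finite values")
        MLPConfig(hidden_units=self.hidden_units,
                  learning_rate=self.learning_rate,
                  iterations=self.iterations, band=self.band,
                  seed=self.random_state,
                  standardize_inputs=self.standardize,
                  momentum=self.momentum)  # validates ranges

        n, p = X.shape
        if self.standardize:
            self.feature_means_ = X.mean(axis=0)
            scales = X.std(axis=0)
            scales[scales == 0.0] = 1.0
            self.feature_scales_ = scales
        else:
            self.feature_means_ = np.zeros(p)
            self.feature_scales_ = np.ones(p)
        if self.standardize:
            self.target_mean_ = float(d.mean())
            sd = float(d.std())
            self.target_scale_ = sd if sd > 0 else 1.0
        else:
            self.target_mean_ = 0.0
            self.target_scale_ = 1.0
        Xs = (X - self.feature_means_) / self.feature_scales_

        rng = np.random.default_rng(self.random_state)
        h = self.hidden_units
        W1 = rng.uniform(-1.0, 1.0, size=(p, h)) * np.sqrt(6.0 / p)
        b1 = np.zeros(h)
        W2 = rng.uniform(-1.0, 1.0, size=(h, 1)) * np.sqrt(6.0 / h)
        b2 = np.zeros(1)  # raw output 0 = the cohort mean in cm

        vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
        vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)
        lr, mom = self.learning_rate, self.momentum
        t_scale, t_mean = self.target_scale_, self.target_mean_

        self.coefs_ = [W1, W2]
        self.intercepts_ = [b1, b2]
        _, _, yhat = self._forward(Xs)
        self.loss_curve_ = [(0, band_loss(yhat, d, self.band))]

        for it in range(1, self.iterations + 1):
            Z = Xs @ W1 + b1
            H = np.maximum(Z, 0.0)
            yhat = ((H @ W2).ravel() + b2[0]) * t_scale + t_mean
            # loss gradient in cm, chained through the target scaling
            g = band_loss_gradient(yhat, d, self.band) * t_scale  # (n,)
            gW2 = H.T @ g[:, None]                              # (h, 1)
            gb2 = np.array([g.sum()])
            back = (g[:, None] * W2.T) * (Z > 0.0)              # (n, h)
            gW1 = Xs.T @ back
            gb1 = back.sum(axis=0)
            if mom > 0.0:
                vW1 = mom * vW1 + gW1; vb1 = mom * vb1 + gb1
                vW2 = mom * vW2 + gW2; vb2 = mom * vb2 + gb2
                W1 -= lr * vW1; b1 -= lr * vb1
                W2 -= lr * vW2; b2 -= lr * vb2
            else:
                W1 -= lr * gW1; b1 -= lr * gb1
                W2 -= lr * gW2; b2 -= lr * gb2
            if it % self.log_every == 0 or it == self.iterations:
                yy = ((np.maximum(Xs @ W1 + b1, 0.0) @ W2).ravel()
                      + b2[0]) * t_scale + t_mean
                loss = band_loss(yy, d, self.band)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss at iteration {it})")
                self.loss_curve_.append((it, loss))

        self.coefs_ = [W1, W2]
        self.intercepts_ = [b1, b2]
        self.loss_ = self.loss_curve_[-1][1]
        self.n_features_in_ = p
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        scalar_row = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        Xs = (X - self.feature_means_) / self.feature_scales_
        _, _, y = self._forward(Xs)
        return y[0] if scalar_row else y

    def permute_features(self, perm) -> "BandedMLPRegressor":
        """Return an equivalent model acting on permuted feature columns.

        Reordering input features while reordering the first-layer weights
        and the scaling state the same way leaves the function unchanged.
        """
        check_is_fitted(self, "coefs_")
        perm = np.asarray(perm, dtype=int)
        other = BandedMLPRegressor(**self.get_params())
        other.coefs_ = [self.coefs_[0][perm].copy(), self.coefs_[1].copy()]
        other.intercepts_ = [ic.copy() for ic in self.intercepts_]
        other.feature_means_ = self.feature_means_[perm].copy()
        other.feature_scales_ = self.feature_scales_[perm].copy()
        other.target_mean_ = self.target_mean_
        other.target_scale_ = self.target_scale_
        other.loss_ = getattr(self, "loss_", None)
        other.loss_curve_ = list(getattr(self, "loss_curve_", []))
        other.n_features_in_ = self.n_features_in_
        return other

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "coefs_")
        return {
            "params": self.get_params(),
            "W1": self.coefs_[0].tolist(),
            "b1": self.intercepts_[0].tolist(),
            "W2": self.coefs_[1].tolist(),
            "b2": self.intercepts_[1].tolist(),
            "feature_means": self.feature_means_.tolist(),
            "feature_scales": self.feature_scales_.tolist(),
            "target_mean": self.target_mean_,
            "target_scale": self.target_scale_,
            "loss": self.loss_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandedMLPRegressor":
        model = cls(**d["params"])
        model.coefs_ = [np.asarray(d["W1"], float), np.asarray(d["W2"], float)]
        model.intercepts_ = [np.asarray(d["b1"], float),
                             np.asarray(d["b2"], float)]
        model.feature_means_ = np.asarray(d["feature_means"], float)
        model.feature_scales_ = np.asarray(d["feature_scales"], float)
        model.target_mean_ = float(d["target_mean"])
        model.target_scale_ = float(d["target_scale"])
        model.loss_ = d.get("loss")
        model.n_features_in_ = model.coefs_[0].shape[0]
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "BandedMLPRegressor":
        return cls.from_dict(json.loads(Path(path).read_text()))


def split_train_validation(records, ratio: float = 0.75, seed: int = 0):
    """Seeded shuffle-and-split into (train, validation).

    ``ratio`` is the training fraction; the validation count is
    ``floor(n * (1 - ratio))`` so a 3:1 split of 615 records yields
    462 train / 153 validation.  Accepts sequences or DataFrames and
    returns the same kind.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    is_frame = isinstance(records, pd.DataFrame)
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_val = int(n * (1.0 - ratio))
    n_val = max(1, min(n - 1, n_val))
    order = np.random.default_rng(seed).permutation(n)
    train_idx, val_idx = order[: n - n_val], order[n - n_val:]
    if is_frame:
        return records.iloc[train_idx], records.iloc[val_idx]
    records = list(records)
    return ([records[i] for i in train_idx], [records[i] for i in val_idx])


def train_adult_height_model(X, y, sex: str = "M",
                             config: MLPConfig | None = None,
                             **overrides) -> BandedMLPRegressor:
    """Convenience wrapper: fit a :class:`BandedMLPRegressor` for one sex."""
    if config is None:
        config = MLPConfig(iterations=DEFAULT_ITERATIONS.get(sex, 46000))
    kw = asdict(config)
    kw.update(overrides)
    model = BandedMLPRegressor(
        hidden_units=kw["hidden_units"], learning_rate=kw["learning_rate"],
        iterations=kw["iterations"], band=kw["band"],
        random_state=kw["seed"], standardize=kw["standardize_inputs"],
        momentum=kw["momentum"])
    return model.fit(X, y)
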