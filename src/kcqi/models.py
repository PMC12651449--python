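"""Regression backends (PLSR, random forest, 1D-CNN) and evaluation metrics.

All three models are scikit-learn estimators with ``fit(X, y)`` /
``predict(X)``.  Performance is summarized by the chemometric triple

    R^2   = 1 - SS_res / SS_tot            (against the evaluated set's mean)
    RMSE  = sqrt(mean squared residual)
    RPD   = SD(reference y) / RMSE         (population SD; prediction set)

where RPD >= 2 conventionally marks a usable quantitative model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .nn import CNN1DNet

__all__ = [
    "PLSRegressorCV",
    "make_random_forest",
    "CNN1DRegressor",
    "EvalMetrics",
    "evaluate",
    "FitResult",
    "fit_plsr",
    "fit_rf",
    "fit_cnn1d",
]


class PLSRegressorCV(BaseEstimator, RegressorMixin):
    """PLS regression with the number of latent variables chosen by
    cross-validated RMSE (argmin over 1..max_components; ties to the
    smallest count)."""

    def __init__(self, max_components: int = 20, cv_folds: int = 10,
                 random_state: int = 0):
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        folds = min(self.cv_folds, n)
        amax = max(1, min(self.max_components, p,
                          n - int(np.ceil(n / folds)) - 1))
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=self.random_state)
        press = np.zeros(amax)
        with warnings.catch_warnings():
            # exhausted y-residuals at high LV counts are expected during CV
            warnings.filterwarnings("ignore", message="y residual is constant")
            for tr, te in kf.split(X):
                for a in range(1, amax + 1):
                    pls = PLSRegression(n_components=a, scale=False)
                    pls.fit(X[tr], y[tr])
                    press[a - 1] += np.sum(
                        (y[te] - pls.predict(X[te]).ravel()) ** 2
                    )
        rmsecv = np.sqrt(press / n)
        # smallest LV count whose CV error ties the minimum
        best = int(np.argmax(rmsecv <= rmsecv.min() * (1 + 1e-10)))
        self.n_components_ = best + 1
        self.rmsecv_ = rmsecv
        self.pls_ = PLSRegression(n_components=self.n_components_, scale=False)
        self.pls_.fit(X, y)
        self.coef_ = np.asarray(self.pls_.coef_).reshape(-1)
        return self

    def predict(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel()


def make_random_forest(n_trees: int = 100, min_leaf: int = 8,
                       random_state: int = 0) -> RandomForestRegressor:
    """Random-forest regressor with the study's ensemble settings
    (100 trees, minimum leaf size 8)."""
    return RandomForestRegressor(
        n_estimators=n_trees, min_samples_leaf=min_leaf,
        random_state=random_state,
    )


class CNN1DRegressor(BaseEstimator, RegressorMixin):
    """1-D convolutional network for spectra -> scalar regression.

    Topology: Conv(16) -> BN -> ReLU -> Conv(32) -> BN -> ReLU ->
    Dropout(0.2) -> FC -> scalar; loss is the half mean-square error; the
    optimizer is Adam.  Inputs are standardized per band and the target is
    standardized, both with calibration statistics; the parameters of the
    epoch with the lowest calibration RMSE are restored after training.

    Training batches receive additive Gaussian spectral jitter of SD
    ``augment_noise`` (on the standardized-band scale) — the usual
    augmentation for spectra->property networks, which keeps the model from
    memorizing the reference noise of individual calibration fruits;
    evaluation is always jitter- and dropout-free.

    ``history_`` records per-epoch half-MSE loss and RMSE, both in original
    target units and both computed in evaluation mode (loss = RMSE^2 / 2 by
    definition).
    """

    def __init__(self, channels=(16, 32), kernel_size: int = 3,
                 dropout: float = 0.2, learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 200,
                 augment_noise: float = 0.5, random_state: int = 0):
        self.channels = channels
        self.kernel_size = kernel_size
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.augment_noise = augment_noise
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        self.x_mean_ = X.mean(axis=0)
        self.x_sd_ = X.std(axis=0)
        self.x_sd_[self.x_sd_ == 0] = 1.0
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std()) or 1.0
        Xs = (X - self.x_mean_) / self.x_sd_
        ys = (y - self.y_mean_) / self.y_sd_

        net = CNN1DNet(p, self.channels, self.kernel_size, self.dropout,
                       seed=self.random_state)
        rng = np.random.default_rng([self.random_state, 977])
        losses, rmses = [], []
        best_rmse, best_state, best_epoch = np.inf, None, 0
        bs = min(self.batch_size, n)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb = Xs[idx]
                if self.augment_noise > 0:
                    xb = xb + rng.normal(0.0, self.augment_noise, xb.shape)
                pred = net.forward(xb, train=True, rng=rng)
                gy = (pred - ys[idx]) / idx.size  # d(half-MSE)/d pred
                net.backward(gy)
                net.adam_step(lr=self.learning_rate)
            # evaluation-mode pass over the calibration set, original units
            pred_cal = net.forward(Xs, train=False) * self.y_sd_ + self.y_mean_
            rmse = float(np.sqrt(np.mean((pred_cal - y) ** 2)))
            rmses.append(rmse)
            losses.append(0.5 * rmse**2)
            if rmse < best_rmse:
                best_rmse, best_state, best_epoch = rmse, net.state(), epoch
        if best_state is not None:
            net.load_state(best_state)
        self.net_ = net
        self.best_epoch_ = best_epoch
        self.history_ = pd.DataFrame(
            {"epoch": np.arange(1, len(rmses) + 1),
             "loss": losses, "rmse": rmses}
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_sd_
        out = np.empty(len(Xs))
        # chunked eval keeps memory bounded for pixel-wise prediction
        for s in range(0, len(Xs), 4096):
            out[s:s + 4096] = self.net_.forward(Xs[s:s + 4096], train=False)
        return out * self.y_sd_ + self.y_mean_


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    """R^2 / RMSE / RPD of one model on one sample set."""

    r2: float
    rmse: float
    rpd: float | None = None

    def as_dict(self) -> dict:
        d = {"r2": self.r2, "rmse": self.rmse}
        if self.rpd is not None:
            d["rpd"] = self.rpd
        return d


def evaluate(model, X, y, with_rpd: bool = False) -> EvalMetrics:
    """Metrics of ``model`` on (X, y); R^2 against the evaluated set's own
    mean, population-SD RPD.  A perfect fit reports rpd = inf."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(model.predict(X)).ravel()
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    rpd = None
    if with_rpd:
        sd = float(y.std())
        rpd = float(np.inf) if rmse == 0 else sd / rmse
    return EvalMetrics(r2=r2, rmse=rmse, rpd=rpd)


@dataclass
class FitResult:
    """A trained model plus its calibration metrics and training history."""

    model: object
    metrics_calibration: EvalMetrics
    history: pd.DataFrame | None = None


def fit_plsr(X_cal, y_cal, max_components: int = 20, cv_folds: int = 10,
             random_state: int = 0) -> FitResult:
    m = PLSRegressorCV(max_components, cv_folds, random_state).fit(X_cal, y_cal)
    return FitResult(m, evaluate(m, X_cal, y_cal))


def fit_rf(X_cal, y_cal, n_trees: int = 100, min_leaf: int = 8,
           random_state: int = 0) -> FitResult:
    m = make_random_forest(n_trees, min_leaf, random_state).fit(
        X_cal, np.asarray(y_cal, dtype=float).ravel()
    )
    return FitResult(m, evaluate(m, X_cal, y_cal))


def fit_cnn1d(X_cal, y_cal, random_state: int = 0, **kwargs) -> FitResult:
    m = CNN1DRegressor(random_state=random_state, **kwargs).fit(X_cal, y_cal)
    return FitResult(m, evaluate(m, X_cal, y_cal), history=m.history_)
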