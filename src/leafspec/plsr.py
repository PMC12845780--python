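"""NIPALS partial least squares regression and accuracy metrics.

PLS1 via NIPALS deflation: components are extracted as weight vectors
w ∝ X'y on the deflated blocks, giving mutually orthogonal score vectors;
the fitted model collapses to a single coefficient vector in the original
feature space, so predict(X) = (X − x̄)·β + ȳ.

Accuracy follows the chemometric conventions used throughout this package:

    R²   = 1 − RSS/TSS            (computed per split; may be negative)
    RMSE = sqrt(Σ(ŷ − y)²/n)
    RPD  = 1/sqrt(1 − R²)         (+inf at R² = 1)
    RSS  = Σ(ŷ − y)²

This RPD is the R²-derived deviation ratio (1.4–2.5 acceptable, > 2.5
strong); the conventional SD(y)/RMSE ratio is reported alongside as
``rpd_sd`` since the two differ once predictions are biased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "PLSRModel",
    "PredictionPairs",
    "ModelReport",
    "fit_plsr",
    "choose_components",
    "evaluate",
    "evaluate_model",
]


@dataclass
class PLSRModel:
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A) X-block weights
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A) training score vectors
    n_components: int
    coefficients: np.ndarray  # (p,) regression vector, original feature space

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coefficients + self.y_mean

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "x_mean": self.x_mean.tolist(),
                    "y_mean": self.y_mean,
                    "coefficients": self.coefficients.tolist(),
                    "n_components": self.n_components,
                },
                fh,
            )


@dataclass
class PredictionPairs:
    """Measured/predicted trait values for one split."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if self.y_true.shape != self.y_pred.shape:
            raise ValueError("y_true and y_pred lengths differ")
        if self.y_true.size < 2:
            raise ValueError("need at least 2 prediction pairs")


@dataclass
class ModelReport:
    r2: float
    rmse: float
    rpd: float
    rss: float
    n: int
    split: str = ""
    rpd_sd: float = np.nan

    def as_row(self) -> dict:
        return {
            "split": self.split,
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "rss": self.rss,
            "rpd": self.rpd,
            "rpd_sd": self.rpd_sd,
        }


def fit_plsr(X, y, n_components: int) -> PLSRModel:
    """Fit univariate-response PLS by NIPALS deflation.

    Requires 2 <= n_samples, non-constant y, and
    n_components <= min(n_samples - 1, n_features).  With the full
    component budget on full-rank data the fit reproduces OLS.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n or n < 2:
        raise ValueError("X and y sample counts must match and exceed 1")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components must lie in [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    a_used = 0
    for a in range(n_components):
        w = E.T @ f
        wn = np.linalg.norm(w)
        if wn <= 1e-14 * max(1.0, np.abs(f).max()):
            break  # residual response orthogonal to X block
        w /= wn
        t = E @ w
        tt = t @ t
        if tt <= 0:
            break
        p_a = E.T @ t / tt
        q_a = f @ t / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        a_used += 1
    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    # β = W (PᵀW)⁻¹ q maps centred X to centred ŷ
    beta = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        n_components=a_used,
        coefficients=beta,
    )


def choose_components(X, y, folds: int = 5, a_max: int = 12, seed: int = 0) -> int:
    """Seeded k-fold cross-validation pick of the PLS component count.

    Returns argmin RMSECV over 1..a_max (capped by the training geometry);
    ties resolve to the smaller count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if a_max < 1:
        raise ValueError("a_max must be at least 1")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    n = X.shape[0]
    kf = KFold(n_splits=min(folds, n), shuffle=True, random_state=seed)
    cap = 0
    press = None
    for train_idx, val_idx in kf.split(X):
        a_cap = min(a_max, len(train_idx) - 1, X.shape[1])
        model = fit_plsr(X[train_idx], y[train_idx], a_cap)
        cap = max(cap, model.n_components)
        # score every component count from one fit by truncating the expansion
        W, P, q = model.weights, model.x_loadings, model.y_loadings
        Ev = X[val_idx] - model.x_mean
        if press is None:
            press = np.full(a_max, 0.0)
            counted = np.zeros(a_max, dtype=int)
        pred = np.full(len(val_idx), model.y_mean)
        Edef = Ev.copy()
        for a in range(model.n_components):
            t = Edef @ W[:, a]
            pred = pred + q[a] * t
            Edef = Edef - np.outer(t, P[:, a])
            press[a] += float(np.sum((pred - y[val_idx]) ** 2))
            counted[a] += len(val_idx)
    usable = counted == counted.max()
    rmsecv = np.sqrt(np.where(usable, press, np.inf) / np.maximum(counted, 1))
    return int(np.argmin(rmsecv)) + 1  # argmin returns the first (smallest) tie


def evaluate(pairs: PredictionPairs, split: str = "", with_sd_ratio: bool = True) -> ModelReport:
    """Model report (R², RMSE, RPD, RSS) for one set of prediction pairs."""
    y, yhat = pairs.y_true, pairs.y_pred
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero variance in measured values")
    rss = float(np.sum((yhat - y) ** 2))
    r2 = 1.0 - rss / tss
    rmse = float(np.sqrt(rss / n))
    rpd = float("inf") if r2 >= 1.0 else 1.0 / np.sqrt(1.0 - r2)
    rpd_sd = np.nan
    if with_sd_ratio:
        sd = float(np.std(y, ddof=1))
        rpd_sd = float("inf") if rmse == 0 else sd / rmse
    return ModelReport(r2=r2, rmse=rmse, rpd=float(rpd), rss=rss, n=n, split=split, rpd_sd=rpd_sd)


def evaluate_model(model: PLSRModel, X, y, split: str = "") -> ModelReport:
    return evaluate(PredictionPairs(y, model.predict(X)), split=split)
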