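"""Support-vector regression of the AHI from selected features.

An epsilon-insensitive SVR with Gaussian kernel
``k(a, b) = exp(-||a - b||^2 / (2 sigma^2))`` maps the selected,
z-scored feature vector of a recording to an AHI estimate.  The
regularisation constant C and kernel width sigma are tuned by
leave-one-out cross-validation on the training split, maximising the
intraclass correlation between reference and cross-validated estimated
AHI; the tuned model is then refit on the whole training split.

Note the kernel parameterisation: the literature quotes the Gaussian
*width* sigma, while the solver expects ``gamma = 1 / (2 sigma^2)`` —
the conversion lives in exactly one place here to avoid the classic
sigma-vs-gamma drift.  Targets are left on the raw AHI scale and
negative predictions are clamped to zero (an AHI is a rate).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .evaluation import icc_agreement
from .features import FeatureTable

__all__ = [
    "HyperParams",
    "ScreeningModel",
    "hyperparameter_grid",
    "tune",
    "fit",
    "predict",
]

DEFAULT_EPSILON = 0.1

C_GRID = tuple(10.0**k for k in range(-3, 5))
SIGMA_COARSE = tuple(10.0**k for k in range(-2, 4))
#: finer sigma values around 1e2 where agreement typically peaks
SIGMA_REFINED = (20.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 500.0)


@dataclass(frozen=True)
class HyperParams:
    """SVR hyperparameters on the conventional (C, sigma, epsilon) scale."""

    C: float
    sigma: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.C <= 0 or self.sigma <= 0 or self.epsilon < 0:
            raise ValueError("need C > 0, sigma > 0, epsilon >= 0")

    @property
    def gamma(self) -> float:
        """The solver-facing kernel coefficient, 1 / (2 sigma^2)."""
        return 1.0 / (2.0 * self.sigma**2)


def hyperparameter_grid(epsilon: float = DEFAULT_EPSILON) -> list[HyperParams]:
    """The assessed (C, sigma) grid: 8 C values x 13 distinct sigma values."""
    sigmas = sorted(set(SIGMA_COARSE) | set(SIGMA_REFINED))
    return [HyperParams(C=c, sigma=s, epsilon=epsilon) for c in C_GRID for s in sigmas]


def _make_svr(hp: HyperParams) -> SVR:
    return SVR(kernel="rbf", C=hp.C, gamma=hp.gamma, epsilon=hp.epsilon)


@dataclass
class ScreeningModel:
    """A trained AHI estimator: feature list, scaling constants and SVR state."""

    selected_features: list[str]
    center: np.ndarray
    scale: np.ndarray
    hp: HyperParams
    svr: SVR
    training_icc: float | None = None

    def transform(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in rows.columns]
        if missing:
            raise ValueError(f"rows lack required features: {missing}")
        X = rows[self.selected_features].to_numpy(dtype=float)
        return (X - self.center) / self.scale

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "hp": {"C": self.hp.C, "sigma": self.hp.sigma, "epsilon": self.hp.epsilon},
            "training_icc": self.training_icc,
            "svr": {
                "support_vectors": self.svr.support_vectors_.tolist(),
                "dual_coef": self.svr.dual_coef_.tolist(),
                "intercept": self.svr.intercept_.tolist(),
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "_LoadedModel":
        with open(path) as fh:
            payload = json.load(fh)
        return _LoadedModel(payload)


class _LoadedModel:
    """A deserialised model evaluating the kernel expansion directly."""

    def __init__(self, payload: dict) -> None:
        self.selected_features = payload["selected_features"]
        self.center = np.asarray(payload["center"], dtype=float)
        self.scale = np.asarray(payload["scale"], dtype=float)
        self.hp = HyperParams(**payload["hp"])
        self.training_icc = payload.get("training_icc")
        self._sv = np.asarray(payload["svr"]["support_vectors"], dtype=float)
        self._dual = np.asarray(payload["svr"]["dual_coef"], dtype=float).ravel()
        self._intercept = float(np.asarray(payload["svr"]["intercept"]).ravel()[0])

    transform = ScreeningModel.transform

    def decision(self, Z: np.ndarray) -> np.ndarray:
        d2 = ((Z[:, None, :] - self._sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.hp.gamma * d2) @ self._dual + self._intercept


def _loo_predictions(X: np.ndarray, y: np.ndarray, hp: HyperParams) -> np.ndarray:
    n = y.size
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = _make_svr(hp)
        model.fit(X[mask], y[mask])
        preds[i] = model.predict(X[i : i + 1])[0]
        mask[i] = True
    return np.maximum(preds, 0.0)


def tune(
    train: FeatureTable,
    selected: list[str],
    grid: list[HyperParams] | None = None,
) -> tuple[HyperParams, float]:
    """Pick the grid point maximising leave-one-out ICC on the training split.

    Ties are resolved toward the smaller C, then the smaller sigma.
    Standardisation constants come from the full training X (targets of
    held-out rows are never seen by the fold models).
    """
    if len(train) < 3:
        raise ValueError("need at least 3 training rows")
    y = train.y.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("training target is constant")
    if grid is None:
        grid = hyperparameter_grid()
    X, _, _ = _standardise(train.X[selected].to_numpy(dtype=float))
    best_hp = None
    best_icc = -np.inf
    for hp in sorted(set(grid), key=lambda h: (h.C, h.sigma, h.epsilon)):
        icc = icc_agreement(y, _loo_predictions(X, y, hp))
        if icc > best_icc:
            best_icc = icc
            best_hp = hp
    return best_hp, float(best_icc)


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return (X - center) / scale, center, scale


def fit(
    train: FeatureTable,
    selected: list[str],
    hp: HyperParams,
    training_icc: float | None = None,
) -> ScreeningModel:
    """Train the final model on the whole training split."""
    X_raw = train.X[selected].to_numpy(dtype=float)
    constant = X_raw.std(axis=0) == 0.0
    if constant.any():
        dropped = [f for f, c in zip(selected, constant) if c]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        selected = [f for f, c in zip(selected, constant) if not c]
        X_raw = X_raw[:, ~constant]
    if not selected:
        raise ValueError("no non-constant features to fit on")
    Z, center, scale = _standardise(X_raw)
    svr = _make_svr(hp)
    svr.fit(Z, train.y.to_numpy(dtype=float))
    return ScreeningModel(
        selected_features=list(selected),
        center=center,
        scale=scale,
        hp=hp,
        svr=svr,
        training_icc=training_icc,
    )


def predict(model, rows) -> np.ndarray:
    """Estimate the AHI for feature rows; negative raw outputs clamp to 0."""
    if isinstance(rows, FeatureTable):
        rows = rows.X
    Z = model.transform(rows)
    if isinstance(model, ScreeningModel):
        raw = model.svr.predict(Z)
    else:
        raw = model.decision(Z)
    return np.maximum(raw, 0.0)
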