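"""Regression and ensemble screening baselines.

These models rank the candidate dataset combinations before the
recurrent downscaler is trained: ordinary/ridge/lasso linear regression
and the three tree ensembles (random forest, gradient boosting, extreme
gradient boosting) with the reference hyperparameters — 100 trees,
learning rate 0.1 for the boosted models, bootstrap sampling for the
forest, random seed 42.  Standard library estimators are used behind
this surface; features are z-scored on the training split for the
regularized regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .dataset import SampleSet

__all__ = ["RegressionSpec", "EnsembleSpec", "fit_regression", "fit_ensemble", "predict_table"]

REGRESSION_KINDS = ("linear", "ridge", "lasso")
ENSEMBLE_KINDS = ("RF", "GB", "XGB")


@dataclass
class RegressionSpec:
    """Fitted linear-family model: coefficients on the original feature scale."""

    kind: str
    intercept: float
    coef: np.ndarray
    lam: float
    estimator: Any = field(repr=False, default=None)


@dataclass
class EnsembleSpec:
    """Tree-ensemble settings pinned to the reference configuration."""

    kind: str
    n_trees: int = 100
    learning_rate: float = 0.1  # GB/XGB only
    seed: int = 42
    estimator: Any = field(repr=False, default=None)


def _design(samples: SampleSet | np.ndarray) -> np.ndarray:
    return samples.features() if isinstance(samples, SampleSet) else np.asarray(samples, float)


def fit_regression(
    samples: SampleSet,
    kind: str = "linear",
    lam: float = 1.0,
) -> RegressionSpec:
    """Least-squares fit, optionally with an L2 (ridge) or L1 (lasso) penalty.

    Ridge and lasso operate on z-scored features (statistics from the
    training data); the reported coefficients are mapped back to the
    original feature scale so predictions are scale-free.
    """
    if kind not in REGRESSION_KINDS:
        raise ValueError(f"kind must be one of {REGRESSION_KINDS}")
    if lam < 0:
        raise ValueError("regularization strength must be non-negative")
    X = _design(samples)
    y = samples.y
    if kind == "linear":
        est = LinearRegression()
        est.fit(X, y)
        return RegressionSpec(kind, float(est.intercept_), est.coef_.copy(), 0.0, est)
    inner = Ridge(alpha=lam) if kind == "ridge" else Lasso(alpha=lam, max_iter=50000)
    est = Pipeline([("scale", StandardScaler()), ("reg", inner)])
    est.fit(X, y)
    scaler, reg = est.named_steps["scale"], est.named_steps["reg"]
    coef = reg.coef_ / scaler.scale_
    intercept = float(reg.intercept_ - np.sum(reg.coef_ * scaler.mean_ / scaler.scale_))
    return RegressionSpec(kind, intercept, coef, lam, est)


def fit_ensemble(samples: SampleSet, kind: str = "RF", seed: int = 42) -> EnsembleSpec:
    """Fit a tree ensemble with the reference hyperparameters.

    Random forest averages 100 bootstrap trees; the boosted variants add
    100 stages at learning rate 0.1.  Everything not pinned here stays at
    the library default.
    """
    if kind not in ENSEMBLE_KINDS:
        raise ValueError(f"kind must be one of {ENSEMBLE_KINDS}")
    X = _design(samples)
    if len(X) < 10:
        raise ValueError("ensembles need at least 10 samples")
    if kind == "RF":
        est = RandomForestRegressor(n_estimators=100, bootstrap=True, random_state=seed)
    elif kind == "GB":
        est = GradientBoostingRegressor(n_estimators=100, learning_rate=0.1, random_state=seed)
    else:
        est = XGBRegressor(n_estimators=100, learning_rate=0.1, random_state=seed,
                           verbosity=0, n_jobs=1)
    est.fit(X, samples.y)
    spec = EnsembleSpec(kind, 100, 0.1 if kind != "RF" else np.nan, seed, est)
    return spec


def predict_table(model: RegressionSpec | EnsembleSpec, samples: SampleSet | np.ndarray) -> np.ndarray:
    """One prediction per row; accepts village sample sets or flat feature tables."""
    X = _design(samples)
    if X.size == 0:
        return np.empty(0)
    est = model.estimator
    expected = getattr(est, "n_features_in_", None)
    if expected is None and hasattr(est, "named_steps"):
        expected = est.named_steps["scale"].n_features_in_
    if expected is not None and X.shape[1] != expected:
        raise ValueError(f"feature layout mismatch: got {X.shape[1]}, expected {expected}")
    return np.asarray(est.predict(X), dtype=float)
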