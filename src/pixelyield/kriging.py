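"""Residual kriging: the geostatistical half of the hybrid downscaler.

After a model's pixel predictions are aggregated back to villages, the
per-village residuals e_i = y_i - yhat_i carry whatever spatially
structured bias the model missed.  This module estimates their empirical
semivariogram, fits one of four closed-form variogram models, selects the
model by leave-one-out cross-validated ordinary kriging, interpolates the
residuals to the pixel grid, and adds the kriged residual surface back to
the prediction.

Ordinary kriging solves, per prediction location s0,

    sum_j lambda_j * gamma(s_i - s_j) + mu = gamma(s_i - s0),   i = 1..n
    sum_j lambda_j = 1

with the Lagrange multiplier mu enforcing unbiasedness.  With a zero
nugget the predictor is exact at the data points; with a positive nugget
it smooths (the right-hand side uses the nugget as the limit of gamma at
vanishing separation, while gamma(0) = 0 on the diagonal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .regions import VillageMap

__all__ = [
    "VariogramModel",
    "ResidualField",
    "compute_residuals",
    "empirical_semivariogram",
    "fit_variogram",
    "select_variogram_cv",
    "ordinary_kriging",
    "krige_residual_surface",
    "correct_yield_surface",
    "VARIOGRAM_TYPES",
]

# candidate order is also the deterministic tie-break order in CV selection
VARIOGRAM_TYPES = ("linear", "spherical", "gaussian", "exponential")


@dataclass(frozen=True)
class VariogramModel:
    """Closed-form semivariogram gamma(h).

    ``sill`` is the partial sill (structured variance above the nugget);
    for the unbounded linear model it is the slope per metre and ``range_``
    is ignored.  gamma(0) = 0 by definition; the nugget is the limit of
    gamma as h -> 0+.
    """

    type: str
    nugget: float
    sill: float
    range_: float = np.nan

    def __post_init__(self) -> None:
        if self.type not in VARIOGRAM_TYPES:
            raise ValueError(f"unknown variogram type {self.type!r}")
        if self.nugget < 0 or self.sill < 0:
            raise ValueError("nugget and sill must be non-negative")
        if self.type != "linear" and not self.range_ > 0:
            raise ValueError("range must be positive")

    def __call__(self, h: np.ndarray, *, at_zero: str = "zero") -> np.ndarray:
        """Evaluate gamma(h).

        ``at_zero="zero"`` returns 0 at h = 0 (data-to-data diagonal);
        ``at_zero="limit"`` returns the nugget there (prediction RHS),
        which produces the smoothing behaviour at data points.
        """
        h = np.asarray(h, dtype=float)
        g = self.nugget + _structure(self.type, h, self.sill, self.range_)
        zero = h == 0
        if at_zero == "zero":
            g = np.where(zero, 0.0, g)
        else:
            g = np.where(zero, self.nugget, g)
        return g

    def correlation(self, h: np.ndarray) -> np.ndarray:
        """Normalized covariance of the structured part, C(h)/sill."""
        if self.type == "linear":
            raise ValueError("linear variogram has no finite sill / covariance")
        if self.sill == 0:
            return np.where(np.asarray(h) == 0, 1.0, 0.0)
        return 1.0 - _structure(self.type, np.asarray(h, dtype=float), 1.0, self.range_)


def _structure(vtype: str, h: np.ndarray, sill: float, range_: float) -> np.ndarray:
    if vtype == "linear":
        return sill * h  # sill plays the role of the slope
    u = h / range_
    if vtype == "spherical":
        u = np.minimum(u, 1.0)
        return sill * (1.5 * u - 0.5 * u ** 3)
    if vtype == "gaussian":
        return sill * (1.0 - np.exp(-(u ** 2)))
    if vtype == "exponential":
        return sill * (1.0 - np.exp(-u))
    raise ValueError(vtype)


@dataclass
class ResidualField:
    """Village residuals located at centroids (projected metres)."""

    points: np.ndarray   # (n, 2)
    values: np.ndarray   # (n,) quintal/ha
    village_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.points) != len(self.values):
            raise ValueError("points/values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("residuals must be finite")

    def __len__(self) -> int:
        return len(self.values)


def compute_residuals(
    villages: VillageMap,
    predicted: pd.DataFrame | np.ndarray,
    observed: np.ndarray | None = None,
    subset: np.ndarray | None = None,
) -> ResidualField:
    """Residuals e_i = y_i - yhat_i at village centroids.

    ``predicted`` is either an array aligned with ``villages`` or a frame
    with ``village_id`` and ``mean`` columns (the output of
    :func:`~pixelyield.recurrent.aggregate_to_admin`); unmatched IDs are an
    error.  ``observed`` defaults to the village map's yields; ``subset``
    optionally restricts to a boolean mask over villages (e.g. the
    training split).
    """
    obs = villages.observed_yield if observed is None else np.asarray(observed, float)
    if isinstance(predicted, pd.DataFrame):
        lookup = dict(zip(predicted["village_id"], predicted["mean"]))
        missing = [v for v in villages.village_id if v not in lookup]
        if missing:
            raise ValueError(f"predictions missing for villages {missing[:5]}")
        pred = np.array([lookup[v] for v in villages.village_id], dtype=float)
    else:
        pred = np.asarray(predicted, dtype=float)
        if len(pred) != len(villages):
            raise ValueError("prediction array length mismatch")
    keep = np.isfinite(obs) & np.isfinite(pred)
    if subset is not None:
        keep &= np.asarray(subset, dtype=bool)
    return ResidualField(
        villages.centroids[keep], (obs - pred)[keep], villages.village_id[keep]
    )


def empirical_semivariogram(
    field: ResidualField,
    n_lags: int = 15,
    max_dist: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram gamma_hat(h).

    gamma_hat(h) = 1/(2 N(h)) * sum over pairs at distance ~h of the
    squared residual difference.  Default ``max_dist`` is half the maximum
    pairwise distance; with ``max_dist`` covering all pairs the pair
    counts sum to n(n-1)/2.

    Returns ``(lag_centres, gamma_hat, pair_counts)``; empty bins carry
    NaN semivariance.
    """
    if len(field) < 2:
        raise ValueError("need at least two points")
    d = pdist(field.points)
    if d.max() == 0:
        raise ValueError("all points are coincident")
    if max_dist is None:
        max_dist = 0.5 * d.max()
    sq = 0.5 * pdist(field.values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_lags)
    idx[np.isclose(d, max_dist)] = n_lags - 1
    valid = idx < n_lags
    counts = np.bincount(idx[valid], minlength=n_lags)
    sums = np.bincount(idx[valid], weights=sq[valid], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, gamma, counts


def fit_variogram(
    lags: np.ndarray,
    gamma: np.ndarray,
    counts: np.ndarray,
    vtype: str,
) -> VariogramModel:
    """Weighted least-squares fit of one variogram model to binned values.

    Bins are weighted by their pair counts.  Initial values: nugget 0,
    partial sill = mean semivariance, range = one third of the largest
    lag.  If the nonlinear fit fails to converge the linear model is
    fitted instead (flagged via a warning), since it always has a
    closed-form weighted solution.
    """
    lags = np.asarray(lags, float)
    gamma = np.asarray(gamma, float)
    counts = np.asarray(counts, float)
    ok = (counts > 0) & np.isfinite(gamma)
    if ok.sum() < 3:
        raise ValueError("need at least three non-empty lag bins")
    x, g, w = lags[ok], gamma[ok], counts[ok]

    if vtype == "linear":
        return _fit_linear(x, g, w)
    f = lambda h, nug, psill, rng: nug + _structure(vtype, h, psill, rng)
    p0 = [0.0, max(float(np.mean(g)), 1e-12), max(float(x.max()) / 3.0, 1e-9)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                f, x, g, p0=p0, sigma=1.0 / np.sqrt(w),
                bounds=([0, 0, 1e-12], [np.inf, np.inf, np.inf]), maxfev=20000,
            )
    except (RuntimeError, ValueError):
        warnings.warn(f"{vtype} variogram fit did not converge; falling back to linear")
        return _fit_linear(x, g, w)
    return VariogramModel(vtype, float(popt[0]), float(popt[1]), float(popt[2]))


def _fit_linear(x: np.ndarray, g: np.ndarray, w: np.ndarray) -> VariogramModel:
    # weighted least squares for gamma = nugget + slope*h, both >= 0
    A = np.column_stack([np.ones_like(x), x]) * np.sqrt(w)[:, None]
    b = g * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    nugget, slope = max(coef[0], 0.0), max(coef[1], 0.0)
    return VariogramModel("linear", float(nugget), float(slope))


def fit_variogram_to_field(
    field: ResidualField,
    vtype: str,
    n_lags: int = 15,
    max_dist: float | None = None,
) -> VariogramModel:
    """Convenience: empirical semivariogram then model fit."""
    lags, gamma, counts = empirical_semivariogram(field, n_lags, max_dist)
    return fit_variogram(lags, gamma, counts, vtype)


def _augmented_system(points: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = len(points)
    G = model(squareform(pdist(points)), at_zero="zero")
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = G
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def ordinary_kriging(
    points: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
    max_global: int = 1000,
    n_neighbors: int = 64,
    return_weights: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging of point data to arbitrary target locations.

    Uses all data points in a single factorized system up to
    ``max_global`` points, otherwise a moving neighbourhood of the
    ``n_neighbors`` nearest points per target.  With
    ``return_weights=True`` additionally returns the per-target kriging
    weight sums (an unbiasedness audit; they equal 1 up to round-off).
    """
    points = np.asarray(points, float).reshape(-1, 2)
    values = np.asarray(values, float)
    targets = np.asarray(targets, float).reshape(-1, 2)
    n = len(points)
    if n < 3:
        raise ValueError("kriging needs at least three points")
    if len(np.unique(points, axis=0)) != n:
        raise np.linalg.LinAlgError("duplicate point locations make the system singular")

    if n <= max_global:
        A = _augmented_system(points, model)
        try:
            lu = lu_factor(A)
        except np.linalg.LinAlgError:
            raise
        rhs = np.empty((n + 1, len(targets)))
        rhs[:n] = model(cdist(points, targets), at_zero="limit")
        rhs[n] = 1.0
        sol = lu_solve(lu, rhs)
        lam = sol[:n]
        preds = lam.T @ values
        wsum = lam.sum(axis=0)
    else:
        tree = cKDTree(points)
        _, nbr = tree.query(targets, k=n_neighbors)
        preds = np.empty(len(targets))
        wsum = np.empty(len(targets))
        for t in range(len(targets)):
            ii = nbr[t]
            A = _augmented_system(points[ii], model)
            rhs = np.empty(n_neighbors + 1)
            rhs[:n_neighbors] = model(
                np.linalg.norm(points[ii] - targets[t], axis=1), at_zero="limit"
            )
            rhs[n_neighbors] = 1.0
            sol = np.linalg.solve(A, rhs)
            preds[t] = sol[:n_neighbors] @ values[ii]
            wsum[t] = sol[:n_neighbors].sum()
    if return_weights:
        return preds, wsum
    return preds


def select_variogram_cv(
    field: ResidualField,
    candidates: Sequence[str] = VARIOGRAM_TYPES,
    n_lags: int = 15,
    max_dist: float | None = None,
) -> tuple[str, dict[str, float], dict[str, VariogramModel]]:
    """Choose the variogram model by leave-one-out kriging cross-validation.

    Each candidate model is fitted to the full empirical semivariogram,
    then every point is predicted by ordinary kriging from the remaining
    points; the candidate with the smallest CV-RMSE wins, ties broken by
    the fixed candidate order.  Candidates whose kriging system is
    singular are disqualified (RMSE inf).

    Returns ``(selected_type, cv_rmse_by_type, fitted_models)``.
    """
    if len(field) < 10:
        raise ValueError("variogram cross-validation needs at least 10 points")
    lags, gamma, counts = empirical_semivariogram(field, n_lags, max_dist)
    rmses: dict[str, float] = {}
    models: dict[str, VariogramModel] = {}
    n = len(field)
    for vtype in candidates:
        try:
            model = fit_variogram(lags, gamma, counts, vtype)
        except (ValueError, np.linalg.LinAlgError):
            rmses[vtype] = np.inf
            continue
        models[vtype] = model
        errs = np.empty(n)
        try:
            for i in range(n):
                keep = np.arange(n) != i
                pred = ordinary_kriging(
                    field.points[keep], field.values[keep], model,
                    field.points[i][None, :],
                )
                errs[i] = field.values[i] - pred[0]
            rmses[vtype] = float(np.sqrt(np.mean(errs ** 2)))
        except np.linalg.LinAlgError:
            rmses[vtype] = np.inf
    if all(np.isinf(v) for v in rmses.values()):
        raise np.linalg.LinAlgError("every candidate variogram gave a singular system")
    selected = min(candidates, key=lambda t: (rmses.get(t, np.inf), candidates.index(t)))
    return selected, rmses, models


def krige_residual_surface(
    field: ResidualField,
    model: VariogramModel,
    shape: tuple[int, int],
    resolution: float,
    origin: tuple[float, float],
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Krige the residual field onto a pixel grid.

    Returns the residual raster (NaN outside ``mask`` if given) and an
    audit dict with the worst deviation of the weight sums from 1.
    """
    rows, cols = shape
    x0, y0 = origin
    xs = x0 + (np.arange(cols) + 0.5) * resolution
    ys = y0 - (np.arange(rows) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        tx, ty = gx[mask], gy[mask]
    else:
        tx, ty = gx.ravel(), gy.ravel()
    preds, wsum = ordinary_kriging(
        field.points, field.values, model, np.column_stack([tx, ty]),
        return_weights=True,
    )
    out = np.full(shape, np.nan)
    if mask is not None:
        out[mask] = preds
    else:
        out.ravel()[:] = preds
    audit = {"max_weight_sum_error": float(np.abs(wsum - 1.0).max()), "n_targets": len(preds)}
    return out, audit


def correct_yield_surface(
    predicted: np.ndarray,
    residual: np.ndarray,
    floor_at_zero: bool = False,
) -> np.ndarray:
    """Add the kriged residual surface back: y*(s) = yhat(s) + e_krig(s).

    Nodata (NaN) in either input propagates.  ``floor_at_zero`` clips
    negative corrected yields to 0 (off by default).
    """
    predicted = np.asarray(predicted, float)
    residual = np.asarray(residual, float)
    if predicted.shape != residual.shape:
        raise ValueError("prediction and residual grids are misaligned")
    out = predicted + residual
    if floor_at_zero:
        out = np.where(np.isnan(out), np.nan, np.maximum(out, 0.0))
    return out
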