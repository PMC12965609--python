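"""Traditional benchmark allocators: NDVI weighting, percentile scaling, kriging-only.

These are the covariate-light baselines the hybrid downscaler is compared
against.  The weight-based method splits an administrative unit's
reported production P across pixels proportionally to NDVI; the
percentile method linearly rescales NDVI into the unit's observed yield
span using its 95th/5th NDVI percentiles (note: a pure slope, no
intercept term, so zero NDVI maps to zero yield); and the kriging-only
method interpolates village yields from centroids without any covariate,
an area-to-point surrogate working at centroid support.
"""

from __future__ import annotations

import numpy as np

from .kriging import VariogramModel, fit_variogram_to_field, ordinary_kriging, ResidualField, select_variogram_cv
from .regions import VillageMap

__all__ = ["ndvi_map", "weight_based_disagg", "percentile_based_disagg", "atpk_disagg"]


def ndvi_map(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index (NIR - Red)/(NIR + Red).

    Nodata where either band is nodata or the denominator vanishes.
    """
    nir = np.asarray(nir, float)
    red = np.asarray(red, float)
    if nir.shape != red.shape:
        raise ValueError("NIR and Red grids are mismatched")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir - red) / denom
    out[denom == 0] = np.nan
    return out


def weight_based_disagg(
    ndvi: np.ndarray,
    production: float,
    unit_pixels: np.ndarray,
) -> np.ndarray:
    """Allocate a unit's production P across pixels proportionally to NDVI.

    allocation_p = NDVI_p / sum(NDVI) * P over the unit's pixels, so the
    allocations conserve P exactly.  A non-positive NDVI sum makes the
    share undefined; the unit is flagged with an error rather than
    falling back to a uniform split.

    Parameters
    ----------
    ndvi
        NDVI raster.
    production
        Reported production of the administrative unit (quintal).
    unit_pixels
        Boolean raster selecting the unit's (masked) pixels.

    Returns
    -------
    Raster of per-pixel allocations, NaN outside the unit.
    """
    ndvi = np.asarray(ndvi, float)
    unit_pixels = np.asarray(unit_pixels, bool)
    vals = ndvi[unit_pixels]
    if len(vals) == 0 or np.isnan(vals).any():
        raise ValueError("unit has no eligible pixels or NDVI nodata inside the unit")
    total = vals.sum()
    if total <= 0:
        raise ValueError("non-positive NDVI sum over the unit; allocation undefined")
    out = np.full(ndvi.shape, np.nan)
    out[unit_pixels] = vals / total * production
    return out


def percentile_based_disagg(
    ndvi: np.ndarray,
    max_yield: float,
    min_yield: float,
    unit_pixels: np.ndarray | None = None,
    percentiles: tuple[float, float] = (95.0, 5.0),
) -> np.ndarray:
    """Scale NDVI linearly into the unit's yield span.

    yield_p = (Maxyield - Minyield) / (MaxNDVI95 - MinNDVI5) * NDVI_p,
    with the 95th/5th NDVI percentiles computed from the unit's own NDVI
    distribution.  The formula is a pure slope through the origin (no
    Minyield offset), so the output is homogeneous in NDVI.
    """
    ndvi = np.asarray(ndvi, float)
    sel = np.ones(ndvi.shape, bool) if unit_pixels is None else np.asarray(unit_pixels, bool)
    vals = ndvi[sel & ~np.isnan(ndvi)]
    if len(vals) == 0:
        raise ValueError("no eligible NDVI pixels in the unit")
    hi, lo = np.percentile(vals, percentiles[0]), np.percentile(vals, percentiles[1])
    if np.isclose(hi, lo):
        raise ValueError("degenerate NDVI distribution: 95th and 5th percentiles coincide")
    slope = (max_yield - min_yield) / (hi - lo)
    out = np.full(ndvi.shape, np.nan)
    out[sel] = slope * ndvi[sel]
    return out


def atpk_disagg(
    villages: VillageMap,
    shape: tuple[int, int],
    resolution: float,
    origin: tuple[float, float],
    variogram: VariogramModel | None = None,
    n_lags: int = 15,
) -> np.ndarray:
    """Kriging-only disaggregation of village yields to the pixel grid.

    Village yields are treated as point observations at the polygon
    centroids and interpolated by ordinary kriging (a centroid surrogate
    for area-to-point kriging).  If no variogram is given, the best of
    the four candidate models is selected by leave-one-out
    cross-validation on the village yields themselves.
    """
    obs = villages.observed_yield
    keep = np.isfinite(obs)
    if keep.sum() < 3:
        raise ValueError("kriging needs at least three villages with yields")
    field = ResidualField(villages.centroids[keep], obs[keep])
    if variogram is None:
        if keep.sum() >= 10:
            selected, _, models = select_variogram_cv(field)
            variogram = models[selected]
        else:
            variogram = fit_variogram_to_field(field, "linear", n_lags=min(n_lags, keep.sum() - 1))
    rows, cols = shape
    x0, y0 = origin
    xs = x0 + (np.arange(cols) + 0.5) * resolution
    ys = y0 - (np.arange(rows) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    preds = ordinary_kriging(
        field.points, field.values, variogram,
        np.column_stack([gx.ravel(), gy.ravel()]),
    )
    return preds.reshape(shape)
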