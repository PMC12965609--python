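"""Administrative village polygons and zonal statistics.

A :class:`VillageMap` holds the village polygons (projected metres), their
block membership, centroids and the observed village yields (quintal/ha;
NaN where the statistic is missing).  :func:`zonal_aggregate` averages a
raster over the crop-masked pixels whose centres fall inside each polygon
— the pixel-centre inclusion rule standard for zonal statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape, mapping

from .raster import RasterStack

__all__ = ["VillageMap", "zonal_aggregate"]


@dataclass
class VillageMap:
    """Villages with geometry, block membership and observed yields."""

    village_id: np.ndarray            # unique string IDs
    block_id: np.ndarray              # one block per village
    polygons: list                    # shapely geometries, projected metres
    observed_yield: np.ndarray        # quintal/ha, NaN = not reported
    area_ha: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.village_id = np.asarray(self.village_id, dtype=object)
        self.block_id = np.asarray(self.block_id, dtype=object)
        self.observed_yield = np.asarray(self.observed_yield, dtype=float)
        n = len(self.village_id)
        if len(set(self.village_id)) != n:
            raise ValueError("village IDs are not unique")
        if not (len(self.block_id) == len(self.polygons) == len(self.observed_yield) == n):
            raise ValueError("field lengths disagree")
        if self.area_ha is None:
            self.area_ha = np.array([g.area for g in self.polygons]) / 1e4
        self.area_ha = np.asarray(self.area_ha, dtype=float)

    def __len__(self) -> int:
        return len(self.village_id)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of polygon centroids in projected metres."""
        return np.array([[g.centroid.x, g.centroid.y] for g in self.polygons])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "village_id": self.village_id,
                "block_id": self.block_id,
                "yield_q_ha": self.observed_yield,
                "area_ha": self.area_ha,
            }
        )

    # -- persistence ---------------------------------------------------

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for i in range(len(self)):
            y = self.observed_yield[i]
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(self.polygons[i]),
                    "properties": {
                        "village_id": str(self.village_id[i]),
                        "block_id": str(self.block_id[i]),
                        "yield_q_ha": None if np.isnan(y) else float(y),
                        "area_ha": float(self.area_ha[i]),
                    },
                }
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def from_geojson(cls, path: str | Path) -> "VillageMap":
        data = json.loads(Path(path).read_text())
        vid, bid, polys, yields, areas = [], [], [], [], []
        for feat in data["features"]:
            props = feat["properties"]
            vid.append(props["village_id"])
            bid.append(props["block_id"])
            polys.append(shapely_shape(feat["geometry"]))
            y = props.get("yield_q_ha")
            yields.append(np.nan if y is None else float(y))
            areas.append(props.get("area_ha"))
        area_arr = None if any(a is None for a in areas) else np.array(areas, dtype=float)
        return cls(np.array(vid, dtype=object), np.array(bid, dtype=object), polys,
                   np.array(yields, dtype=float), area_arr)


def zonal_aggregate(
    raster: np.ndarray | RasterStack,
    villages: VillageMap,
    mask: np.ndarray | None = None,
    *,
    resolution: float | None = None,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Mean of a raster layer over the masked pixels inside each village.

    Only pixels whose centres are covered by the polygon, pass the crop
    mask, and are not nodata contribute.  Villages with zero eligible
    pixels are flagged (``pixel_count`` 0, ``mean`` NaN) rather than
    silently reported as zero.

    Parameters
    ----------
    raster
        A single-layer :class:`RasterStack`, or a 2-D array together with
        ``resolution`` and ``origin``.
    villages
        The administrative polygons.
    mask
        Optional boolean crop mask on the same grid; ``None`` keeps all.

    Returns
    -------
    DataFrame with columns ``village_id, mean, pixel_count``.
    """
    if isinstance(raster, RasterStack):
        if raster.n_layers != 1:
            raise ValueError("zonal_aggregate expects a single layer")
        arr = raster.layer(0)
        resolution, origin = raster.resolution, raster.origin
    else:
        arr = np.asarray(raster, dtype=float)
        if resolution is None or origin is None:
            raise ValueError("resolution and origin required with a bare array")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValueError("mask is not aligned to the raster grid")
    stack = RasterStack(arr, resolution, origin)
    xs, ys = stack.pixel_centres()
    eligible = ~np.isnan(arr)
    if mask is not None:
        eligible &= mask

    means = np.full(len(villages), np.nan)
    counts = np.zeros(len(villages), dtype=int)
    ex, ey, ev = xs[eligible], ys[eligible], arr[eligible]
    for i, poly in enumerate(villages.polygons):
        minx, miny, maxx, maxy = poly.bounds
        near = (ex >= minx) & (ex <= maxx) & (ey >= miny) & (ey <= maxy)
        if not near.any():
            continue
        inside = shapely.intersects_xy(poly, ex[near], ey[near])
        counts[i] = int(inside.sum())
        if counts[i]:
            means[i] = float(ev[near][inside].mean())
    return pd.DataFrame(
        {"village_id": villages.village_id, "mean": means, "pixel_count": counts}
    )


def village_pixel_index(
    villages: VillageMap,
    shape: tuple[int, int],
    resolution: float,
    origin: tuple[float, float],
) -> np.ndarray:
    """Label raster mapping each pixel centre to a village index (-1 outside).

    Membership is by pixel-centre inclusion; where polygons share a
    boundary through a pixel centre the lowest village index wins, so the
    assignment is deterministic and disjoint.
    """
    rows, cols = shape
    x0, y0 = origin
    xs = x0 + (np.arange(cols) + 0.5) * resolution
    ys = y0 - (np.arange(rows) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    labels = np.full(shape, -1, dtype=int)
    fx, fy = gx.ravel(), gy.ravel()
    for i, poly in enumerate(villages.polygons):
        minx, miny, maxx, maxy = poly.bounds
        near = (fx >= minx) & (fx <= maxx) & (fy >= miny) & (fy <= maxy)
        near &= labels.ravel() == -1
        if not near.any():
            continue
        idx = np.flatnonzero(near)
        shapely.prepare(poly)  # in-place; speeds up repeated point tests
        inside = shapely.intersects_xy(poly, fx[idx], fy[idx])
        labels.ravel()[idx[inside]] = i
    return labels


def zonal_aggregate_stack(
    stack: RasterStack,
    villages: VillageMap,
    mask: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Masked village means of every layer in a stack at once.

    Pixel-to-village membership (the expensive point-in-polygon step) is
    computed once and reused across layers; pass ``labels`` from
    :func:`village_pixel_index` to reuse it across stacks.  Returns an
    ``(n_villages, n_layers)`` array with NaN where a village has no
    eligible pixel.
    """
    if labels is None:
        labels = village_pixel_index(villages, stack.shape, stack.resolution, stack.origin)
    n = len(villages)
    out = np.full((n, stack.n_layers), np.nan)
    for k in range(stack.n_layers):
        arr = stack.layer(k)
        eligible = (labels >= 0) & ~np.isnan(arr)
        if mask is not None:
            eligible &= mask
        lab = labels[eligible]
        counts = np.bincount(lab, minlength=n)
        sums = np.bincount(lab, weights=arr[eligible], minlength=n)
        with np.errstate(invalid="ignore"):
            out[:, k] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out
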