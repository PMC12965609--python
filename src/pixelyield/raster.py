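"""Gridded covariate stacks and plain-text raster I/O.

Rasters are kept in memory as ``float64`` arrays with NaN marking nodata.
On disk each layer is an ESRI ASCII grid (``.asc``), a plain-text format
readable by any GIS; a JSON sidecar manifest records the layer order
(source, feature name, time step) so a stack can be round-tripped.

Coordinates are planar projected metres.  The grid origin is the top-left
corner; the centre of cell ``(row, col)`` sits at
``(x0 + (col + 0.5) * res, y0 - (row + 0.5) * res)``.  Each cell owns the
half-open square ``[x, x + res) x (y - res, y]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LayerInfo",
    "RasterStack",
    "monthly_composite",
    "read_ascii_grid",
    "write_ascii_grid",
]

_SOURCES = ("optical", "radar", "weather", "soil", "mask")


@dataclass(frozen=True)
class LayerInfo:
    """Identity of one layer in a stack: where it came from and when."""

    source: str   # one of optical / radar / weather / soil / mask
    feature: str  # e.g. "B8", "VV", "air_temp"
    time: int     # time step within the source's sequence; -1 for static

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise ValueError(f"unknown layer source {self.source!r}")


@dataclass
class RasterStack:
    """A stack of co-registered raster layers on one projected grid.

    Parameters
    ----------
    values
        Array of shape ``(rows, cols, n_layers)``; NaN encodes nodata.
    resolution
        Cell size in metres per pixel (square cells).
    origin
        Projected ``(x, y)`` of the top-left grid corner.
    layers
        One :class:`LayerInfo` per layer, in array order.
    """

    values: np.ndarray
    resolution: float
    origin: tuple[float, float]
    layers: list[LayerInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must be (rows, cols, n_layers)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.layers and len(self.layers) != self.values.shape[2]:
            raise ValueError("layer index length does not match n_layers")
        for src in _SOURCES:
            times = [li.time for li in self.layers if li.source == src and li.time >= 0]
            if times != sorted(times):
                raise ValueError(f"time steps for source {src!r} are not ordered")

    # -- basic geometry ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected x and y coordinates of every cell centre (2-D arrays)."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.resolution
        ys = y0 - (np.arange(rows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def same_grid(self, other: "RasterStack") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.resolution, other.resolution)
            and np.allclose(self.origin, other.origin)
        )

    # -- layer access --------------------------------------------------

    def layer(self, index: int) -> np.ndarray:
        return self.values[:, :, index]

    def select(self, source: str | None = None, feature: str | None = None) -> "RasterStack":
        """Sub-stack of layers matching ``source`` and/or ``feature``."""
        idx = [
            i
            for i, li in enumerate(self.layers)
            if (source is None or li.source == source)
            and (feature is None or li.feature == feature)
        ]
        if not idx:
            raise KeyError(f"no layers match source={source!r} feature={feature!r}")
        return RasterStack(
            self.values[:, :, idx],
            self.resolution,
            self.origin,
            [self.layers[i] for i in idx],
        )

    def time_series(self, source: str) -> np.ndarray:
        """Layers of one temporal source as ``(rows, cols, T, F)``.

        Feature order follows first appearance; time steps must be complete
        for every feature.
        """
        sub = self.select(source=source)
        feats: list[str] = []
        for li in sub.layers:
            if li.feature not in feats:
                feats.append(li.feature)
        times = sorted({li.time for li in sub.layers})
        rows, cols = self.shape
        out = np.full((rows, cols, len(times), len(feats)), np.nan)
        for i, li in enumerate(sub.layers):
            out[:, :, times.index(li.time), feats.index(li.feature)] = sub.values[:, :, i]
        if np.isnan(out).all(axis=(0, 1)).any():
            raise ValueError(f"incomplete time/feature grid for source {source!r}")
        return out

    # -- persistence ---------------------------------------------------

    def write(self, directory: str | Path, prefix: str = "layer") -> Path:
        """Write one ``.asc`` per layer plus a JSON manifest; returns manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for i in range(self.n_layers):
            li = self.layers[i] if self.layers else LayerInfo("optical", f"f{i}", 0)
            name = f"{prefix}_{i:03d}_{li.source}_{li.feature}_t{li.time}.asc"
            write_ascii_grid(directory / name, self.layer(i), self.resolution, self.origin)
            entries.append(
                {"file": name, "source": li.source, "feature": li.feature, "time": li.time}
            )
        manifest = directory / f"{prefix}_manifest.json"
        manifest.write_text(
            json.dumps(
                {
                    "resolution": self.resolution,
                    "origin": list(self.origin),
                    "layers": entries,
                },
                indent=1,
            )
        )
        return manifest

    @classmethod
    def read(cls, manifest_path: str | Path) -> "RasterStack":
        manifest_path = Path(manifest_path)
        meta = json.loads(manifest_path.read_text())
        arrays, infos = [], []
        for entry in meta["layers"]:
            arr, res, origin = read_ascii_grid(manifest_path.parent / entry["file"])
            arrays.append(arr)
            infos.append(LayerInfo(entry["source"], entry["feature"], entry["time"]))
        return cls(np.stack(arrays, axis=-1), meta["resolution"], tuple(meta["origin"]), infos)


def monthly_composite(scenes: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel mean of repeat acquisitions within a month, ignoring nodata.

    A pixel is nodata in the composite only if it is nodata in *every*
    scene; otherwise the mean is taken over the valid acquisitions.

    Parameters
    ----------
    scenes
        Non-empty sequence of 2-D arrays on the same grid (NaN = nodata).
    """
    if len(scenes) == 0:
        raise ValueError("monthly_composite needs at least one scene")
    arrs = [np.asarray(s, dtype=float) for s in scenes]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError("scenes are on mismatched grids")
    stack = np.stack(arrs, axis=0)
    all_missing = np.isnan(stack).all(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(
            all_missing, np.nan,
            np.nansum(np.nan_to_num(stack), axis=0) / np.maximum((~np.isnan(stack)).sum(axis=0), 1),
        )
    return out


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    resolution: float,
    origin: tuple[float, float],
    nodata: float = -9999.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (NaN mapped to ``nodata``)."""
    array = np.asarray(array, dtype=float)
    rows, cols = array.shape
    x0, y0 = origin
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {y0 - rows * resolution!r}\n"
        f"cellsize {resolution!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    body = np.where(np.isnan(array), nodata, array)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid; returns ``(array, resolution, top_left_origin)``."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # headers may omit NODATA_value
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(rows, cols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    res = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + rows * res)
    return data, res, origin
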