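"""Synthetic landscapes with known pixel-level yield truth.

Real village yield statistics never come with pixel ground truth, so every
downstream stage is exercised on simulated scenes instead: a latent pixel
yield surface built from spatially autocorrelated drivers plus a
structured Gaussian-random-field component that the covariates do *not*
explain (the regional bias residual kriging is meant to remove), noisy
covariate layers informative of the drivers, weather surfaces held
constant over coarse blocks (mimicking reanalysis-resolution weather
shared by many villages), a patchy crop mask, a Voronoi partition into
villages grouped into blocks, and village mean yields — the only observed
yield quantity — computed over masked pixels with observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely import unary_union
from shapely.geometry import box

from .kriging import VariogramModel
from .raster import LayerInfo, RasterStack
from .regions import VillageMap

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "gaussian_random_field",
    "generate_scene",
    "inject_regional_bias",
    "aggregate_truth",
]

BAND_FEATURES = ("blue", "green", "red", "nir", "swir", "vv", "vh")
WEATHER_FEATURES = ("air_temp", "soil_temp", "solar_rad", "evaporation", "precip", "lai")
SOIL_FEATURES = (
    "bulk_density", "cec", "coarse_frag", "clay", "sand",
    "silt", "nitrogen", "org_carbon", "ph", "soc_density",
)


@dataclass(frozen=True)
class SceneConfig:
    """Generator settings; the defaults define the reference study conditions.

    Yields are in quintal/ha.  The structured-residual variogram governs
    the regional bias left after the covariates: an exponential model
    with partial sill 4 (q/ha)^2 and a 3 km range on a 10 km x 10 km
    scene gives village-scale residual clustering several villages wide.
    """

    rows: int = 100
    cols: int = 100
    resolution: float = 100.0        # metres per pixel
    n_villages: int = 60
    blocks_grid: tuple[int, int] = (2, 2)  # quadrant grouping of villages
    # structured residual (regional bias) variogram
    variogram_type: str = "exponential"
    sill: float = 4.0                # (q/ha)^2 partial sill
    range_m: float = 3000.0
    nugget: float = 0.0
    # yield surface composition
    intercept: float = 45.0          # q/ha, wheat-like level
    loadings: tuple[float, float, float] = (3.0, 2.0, 1.0)  # fertility, moisture, weather
    driver_ranges_m: tuple[float, float] = (1000.0, 500.0)
    # covariates
    t1: int = 3                      # band time steps
    t2: int = 5                      # weather time steps
    covariate_noise_sd: float = 0.3
    weather_block_px: int = 50
    mask_coverage: float = 0.7
    obs_noise_sd: float = 1.0        # q/ha observation noise on village yields
    seed: int = 0

    def __post_init__(self) -> None:
        if self.range_m <= 0 or min(self.driver_ranges_m) <= 0:
            raise ValueError("variogram ranges must be positive")
        if not 0 < self.mask_coverage <= 1:
            raise ValueError("mask coverage must lie in (0, 1]")
        if self.n_villages > self.rows * self.cols:
            raise ValueError("more villages than pixels")


@dataclass
class SyntheticScene:
    """A generated landscape: pixel truth plus everything a model may see."""

    truth: np.ndarray                # (rows, cols) pixel yield, q/ha
    covariates: RasterStack          # bands + weather + soil layers
    crop_mask: np.ndarray            # boolean (rows, cols)
    villages: VillageMap             # observed (noisy, aggregated) yields
    village_labels: np.ndarray       # pixel -> village index
    config: SceneConfig
    bias: np.ndarray | None = None   # structured residual component of truth

    @property
    def resolution(self) -> float:
        return self.covariates.resolution

    @property
    def origin(self) -> tuple[float, float]:
        return self.covariates.origin

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape


def gaussian_random_field(
    shape: tuple[int, int],
    model: VariogramModel,
    resolution: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate a zero-mean stationary Gaussian random field on a grid.

    Uses circulant embedding on a doubled torus: the target covariance
    C(h) = sill * corr(h) is laid out with wrap-around distances, its FFT
    gives the embedding spectrum (tiny negative eigenvalues from
    imperfect embeddability are clipped), and white noise is coloured by
    convolution.  A nugget adds independent white noise on top.  The
    unbounded linear variogram has no finite sill and is rejected.
    """
    if model.type == "linear":
        raise ValueError("cannot simulate from an unbounded (linear) variogram")
    rng = np.random.default_rng(rng)
    rows, cols = shape
    if model.sill == 0:
        out = np.zeros(shape)
    else:
        # pad the torus well past the correlation range so that clipping
        # the few negative embedding eigenvalues loses negligible variance
        range_px = model.range_ / resolution
        pad = max(2 * rows, 2 * cols, int(8 * range_px))
        m = n = min(int(2 ** np.ceil(np.log2(pad))), 4096)
        di = np.minimum(np.arange(m), m - np.arange(m)) * resolution
        dj = np.minimum(np.arange(n), n - np.arange(n)) * resolution
        dist = np.hypot(di[:, None], dj[None, :])
        cov = model.sill * model.correlation(dist)
        lam = np.clip(np.fft.fft2(cov).real, 0.0, None)
        eps = rng.standard_normal((m, n))
        fld = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(eps)).real
        out = fld[:rows, :cols]
    if model.nugget > 0:
        out = out + rng.normal(0.0, np.sqrt(model.nugget), shape)
    return out


def _block_constant(shape: tuple[int, int], block_px: int, values_per_block: np.ndarray) -> np.ndarray:
    """Expand per-block values to a pixel grid, constant within each block."""
    rows, cols = shape
    bi = np.arange(rows) // block_px
    bj = np.arange(cols) // block_px
    return values_per_block[bi[:, None], bj[None, :]]


def _voronoi_villages(
    config: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list, np.ndarray]:
    """Sample village seeds, label pixels by nearest seed, build polygons.

    Returns ``(labels, seeds, polygons, block_ids)``.  Polygons are exact
    unions of the member pixel cells, so polygon membership by pixel
    centre coincides with the label raster.
    """
    rows, cols, res = config.rows, config.cols, config.resolution
    x0, y0 = 0.0, rows * res
    xs = x0 + (np.arange(cols) + 0.5) * res
    ys = y0 - (np.arange(rows) + 0.5) * res
    gx, gy = np.meshgrid(xs, ys)
    centres = np.column_stack([gx.ravel(), gy.ravel()])

    for _ in range(100):
        seeds = np.column_stack(
            [rng.uniform(0, cols * res, config.n_villages),
             rng.uniform(0, rows * res, config.n_villages)]
        )
        labels = cKDTree(seeds).query(centres)[1].reshape(rows, cols)
        if len(np.unique(labels)) == config.n_villages:
            break
    else:
        raise RuntimeError("could not place all villages on the grid")

    polygons = []
    for v in range(config.n_villages):
        rr, cc = np.nonzero(labels == v)
        cells = [
            box(x0 + c * res, y0 - (r + 1) * res, x0 + (c + 1) * res, y0 - r * res)
            for r, c in zip(rr, cc)
        ]
        polygons.append(unary_union(cells))

    nbx, nby = config.blocks_grid
    bx = np.minimum((seeds[:, 0] / (cols * res) * nbx).astype(int), nbx - 1)
    by = np.minimum((seeds[:, 1] / (rows * res) * nby).astype(int), nby - 1)
    block_ids = np.array([f"B{j * nbx + i:02d}" for i, j in zip(bx, by)], dtype=object)
    return labels, seeds, polygons, block_ids


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate one synthetic landscape under ``config``.

    The pixel truth is
    ``intercept + l1*fertility + l2*moisture + l3*weather + bias``
    where fertility and moisture are unit-variance exponential random
    fields, weather is a block-constant standard-normal field, and bias
    is the structured residual field drawn from the configured variogram.
    Band layers carry seasonally-weighted mixes of the drivers plus
    independent noise; weather layers are exactly block-constant; soil
    layers are static fields partially correlated with fertility.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.rows, config.cols)
    res = config.resolution
    origin = (0.0, config.rows * res)

    def unit_field(range_m: float) -> np.ndarray:
        f = gaussian_random_field(
            shape, VariogramModel("exponential", 0.0, 1.0, range_m), res, rng
        )
        sd = f.std()
        return f / sd if sd > 0 else f

    fertility = unit_field(config.driver_ranges_m[0])
    moisture = unit_field(config.driver_ranges_m[1])

    # block-constant weather driver (reanalysis-scale coarseness)
    nbr = -(-config.rows // config.weather_block_px)
    nbc = -(-config.cols // config.weather_block_px)
    weather_driver = _block_constant(shape, config.weather_block_px,
                                     rng.standard_normal((nbr, nbc)))

    bias = gaussian_random_field(
        shape,
        VariogramModel(config.variogram_type, config.nugget, config.sill, config.range_m),
        res, rng,
    )
    l1, l2, l3 = config.loadings
    truth = config.intercept + l1 * fertility + l2 * moisture + l3 * weather_driver + bias

    layers, infos = [], []
    # temporal bands: seasonal profile over T1 steps, per-feature driver mix
    season = np.linspace(0.6, 1.2, config.t1)
    f_mix = rng.uniform(0.6, 1.4, len(BAND_FEATURES))
    m_mix = rng.uniform(-0.5, 0.5, len(BAND_FEATURES))
    # reflectance-like baselines per band (NIR well above Red, as over
    # vegetation) so band ratios like NDVI are positive and well defined;
    # models z-score their inputs, so the offsets are inert for learning
    band_level = {"blue": 3.0, "green": 4.0, "red": 4.0, "nir": 8.0,
                  "swir": 5.0, "vv": 3.0, "vh": 3.0}
    for t in range(config.t1):
        for f, name in enumerate(BAND_FEATURES):
            layer = season[t] * (f_mix[f] * fertility + m_mix[f] * moisture)
            layer = layer + rng.normal(0.0, config.covariate_noise_sd, shape)
            layers.append(band_level[name] + layer)
            src = "radar" if name in ("vv", "vh") else "optical"
            infos.append(LayerInfo(src, name, t))
    # temporal weather: every layer is a deterministic mix of two latent
    # block drivers (the yield-relevant one plus a nuisance), mirroring the
    # strong cross-feature correlation of reanalysis weather; layers are
    # exactly block-constant, so many villages share identical values
    w_profile = np.linspace(0.8, 1.2, config.t2)
    nuisance = _block_constant(shape, config.weather_block_px,
                               rng.standard_normal((nbr, nbc)))
    w_mix = rng.uniform(0.5, 1.0, len(WEATHER_FEATURES))
    w_mix[0] = 1.0
    n_mix = rng.uniform(-0.5, 0.5, len(WEATHER_FEATURES))
    n_mix[0] = 0.0
    for t in range(config.t2):
        for f, name in enumerate(WEATHER_FEATURES):
            layers.append(w_profile[t] * (w_mix[f] * weather_driver + n_mix[f] * nuisance))
            infos.append(LayerInfo("weather", name, t))
    # static soil, partially correlated with fertility
    soil_base = 0.5 * fertility + 0.5 * unit_field(config.driver_ranges_m[0])
    for name in SOIL_FEATURES:
        g = rng.uniform(0.3, 1.0)
        layers.append(g * soil_base + rng.normal(0.0, config.covariate_noise_sd, shape))
        infos.append(LayerInfo("soil", name, -1))
    covariates = RasterStack(np.stack(layers, axis=-1), res, origin, infos)

    if config.mask_coverage >= 1.0:
        crop_mask = np.ones(shape, dtype=bool)
    else:
        patchiness = unit_field(500.0)
        crop_mask = patchiness > np.quantile(patchiness, 1.0 - config.mask_coverage)

    labels, seeds, polygons, block_ids = _voronoi_villages(config, rng)

    observed = np.full(config.n_villages, np.nan)
    eligible = crop_mask
    for v in range(config.n_villages):
        sel = (labels == v) & eligible
        if sel.any():
            observed[v] = truth[sel].mean()
    noise = rng.normal(0.0, config.obs_noise_sd, config.n_villages)
    if config.obs_noise_sd > 0:
        observed = observed + noise

    villages = VillageMap(
        np.array([f"V{v:03d}" for v in range(config.n_villages)], dtype=object),
        block_ids, polygons, observed,
    )
    return SyntheticScene(truth, covariates, crop_mask, villages, labels, config, bias)


def inject_regional_bias(
    scene: SyntheticScene,
    model: VariogramModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> SyntheticScene:
    """Add a smooth regional bias field to a scene's truth and yields.

    Draws an independent random field from ``model`` (default: the
    scene's configured structured-residual variogram), adds it to the
    pixel truth, and shifts each village's observed yield by the field's
    masked village mean — emulating a regional effect the covariates do
    not carry.  A model trained before the injection cannot have
    absorbed it, which makes this the controlled experiment for residual
    kriging: the injected component shows up intact in the village
    residuals and should be removed by the correction.
    """
    cfg = scene.config
    if model is None:
        model = VariogramModel(cfg.variogram_type, cfg.nugget, cfg.sill, cfg.range_m)
    b = gaussian_random_field(scene.shape, model, scene.resolution, rng)
    observed = scene.villages.observed_yield.copy()
    for v in range(len(scene.villages)):
        sel = (scene.village_labels == v) & scene.crop_mask
        if sel.any():
            observed[v] = observed[v] + b[sel].mean()
    villages = VillageMap(
        scene.villages.village_id.copy(), scene.villages.block_id.copy(),
        scene.villages.polygons, observed, scene.villages.area_ha.copy(),
    )
    bias = b if scene.bias is None else scene.bias + b
    return SyntheticScene(
        scene.truth + b, scene.covariates, scene.crop_mask, villages,
        scene.village_labels, cfg, bias,
    )


def write_scene(scene: SyntheticScene, directory) -> None:
    """Persist a scene as plain-text artifacts (ASCII grids, GeoJSON, CSV)."""
    import dataclasses
    import json
    from pathlib import Path

    from .raster import write_ascii_grid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scene.covariates.write(directory, prefix="cov")
    write_ascii_grid(directory / "truth.asc", scene.truth, scene.resolution, scene.origin)
    write_ascii_grid(
        directory / "crop_mask.asc", scene.crop_mask.astype(float),
        scene.resolution, scene.origin,
    )
    scene.villages.to_geojson(directory / "villages.geojson")
    scene.villages.table().to_csv(directory / "village_yields.csv", index=False)
    cfg = dataclasses.asdict(scene.config)
    cfg["blocks_grid"] = list(cfg["blocks_grid"])
    cfg["loadings"] = list(cfg["loadings"])
    cfg["driver_ranges_m"] = list(cfg["driver_ranges_m"])
    (directory / "scene_config.json").write_text(json.dumps(cfg, indent=1))


def read_scene(directory) -> SyntheticScene:
    """Load a scene written by :func:`write_scene`."""
    import json
    from pathlib import Path

    from .raster import read_ascii_grid
    from .regions import village_pixel_index

    directory = Path(directory)
    covariates = RasterStack.read(directory / "cov_manifest.json")
    truth, _, _ = read_ascii_grid(directory / "truth.asc")
    mask, _, _ = read_ascii_grid(directory / "crop_mask.asc")
    villages = VillageMap.from_geojson(directory / "villages.geojson")
    cfg = json.loads((directory / "scene_config.json").read_text())
    cfg["blocks_grid"] = tuple(cfg["blocks_grid"])
    cfg["loadings"] = tuple(cfg["loadings"])
    cfg["driver_ranges_m"] = tuple(cfg["driver_ranges_m"])
    config = SceneConfig(**cfg)
    labels = village_pixel_index(
        villages, covariates.shape, covariates.resolution, covariates.origin
    )
    return SyntheticScene(truth, covariates, mask > 0.5, villages, labels, config)


def aggregate_truth(scene: SyntheticScene) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Exact noise-free village and block means of the truth raster.

    Serves as the oracle for parameter-recovery tests.  Block means are
    pixel-count-weighted (i.e. computed directly over member pixels).
    """
    import pandas as pd

    n = len(scene.villages)
    masked = scene.crop_mask
    means = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for v in range(n):
        sel = (scene.village_labels == v) & masked
        counts[v] = int(sel.sum())
        if counts[v]:
            means[v] = scene.truth[sel].mean()
    vdf = pd.DataFrame(
        {
            "village_id": scene.villages.village_id,
            "block_id": scene.villages.block_id,
            "true_mean": means,
            "pixel_count": counts,
        }
    )
    ok = vdf["pixel_count"] > 0
    bdf = (
        vdf[ok]
        .assign(wsum=lambda d: d.true_mean * d.pixel_count)
        .groupby("block_id", as_index=False)
        .agg(pixel_count=("pixel_count", "sum"), wsum=("wsum", "sum"))
    )
    bdf["true_mean"] = bdf["wsum"] / bdf["pixel_count"]
    return vdf, bdf[["block_id", "true_mean", "pixel_count"]]
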