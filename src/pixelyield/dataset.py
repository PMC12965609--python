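"""Village-level analytical dataset: feature combinations, imputation, split.

Per-village covariates come in three groups: temporal satellite bands
(T1 time steps x F1 features, e.g. five optical + two radar bands over
three months), temporal weather (T2 x F2), and static soil properties.
Seven named combinations of these groups are screened before the
downscaling model is trained.  Missing village yields are imputed with
their block mean before the seed-reproducible 80:20 train/validation
split, so the same partition serves every model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import VillageMap

__all__ = ["COMBINATIONS", "SampleSet", "assemble_samples", "feature_count"]

# combination id -> (bands, weather, soil) group inclusion
COMBINATIONS: dict[str, tuple[bool, bool, bool]] = {
    "all-features": (True, True, True),
    "band-weather": (True, True, False),
    "band-soil": (True, False, True),
    "soil-weather": (False, True, True),
    "band-only": (True, False, False),
    "weather-only": (False, True, False),
    "soil-only": (False, False, True),
}


def feature_count(combination: str, t1: int = 3, f1: int = 7, t2: int = 5,
                  f2: int = 6, f3: int = 10) -> int:
    """Flattened feature dimension of a combination (default group sizes)."""
    use_b, use_w, use_s = _combo(combination)
    return use_b * t1 * f1 + use_w * t2 * f2 + use_s * f3


def _combo(combination: str) -> tuple[bool, bool, bool]:
    try:
        return COMBINATIONS[combination]
    except KeyError:
        raise ValueError(
            f"unknown combination {combination!r}; expected one of {sorted(COMBINATIONS)}"
        ) from None


@dataclass
class SampleSet:
    """Assembled per-village samples with grouped features and split labels."""

    village_id: np.ndarray
    bands: np.ndarray      # (n, T1, F1); empty second axis if excluded
    weather: np.ndarray    # (n, T2, F2)
    soil: np.ndarray       # (n, F3)
    static: np.ndarray     # (n, F3_static) static branch input (crop indicator)
    y: np.ndarray          # quintal/ha, no missing values
    split: np.ndarray      # "train" / "val"
    combination: str
    n_imputed: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.village_id)
        for name in ("bands", "weather", "soil", "static", "y", "split"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.isnan(self.y).any():
            raise ValueError("assembled samples contain missing yields")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == "train"

    @property
    def val_mask(self) -> np.ndarray:
        return self.split == "val"

    def features(self) -> np.ndarray:
        """Flat (n, p) design matrix in bands-weather-soil column order."""
        parts = []
        if self.bands.size:
            parts.append(self.bands.reshape(len(self), -1))
        if self.weather.size:
            parts.append(self.weather.reshape(len(self), -1))
        if self.soil.size:
            parts.append(self.soil)
        if not parts:
            raise ValueError("sample set has no features")
        return np.concatenate(parts, axis=1)

    def subset(self, mask: np.ndarray) -> "SampleSet":
        return SampleSet(
            self.village_id[mask], self.bands[mask], self.weather[mask],
            self.soil[mask], self.static[mask], self.y[mask], self.split[mask],
            self.combination,
        )


def impute_block_means(villages: VillageMap) -> tuple[np.ndarray, np.ndarray, int]:
    """Fill missing village yields with their block mean.

    Returns ``(yields, keep_mask, n_imputed)``.  Villages belonging to a
    block with no reported yield at all cannot be imputed and are dropped
    (``keep_mask`` False).
    """
    y = villages.observed_yield.copy()
    keep = np.ones(len(y), dtype=bool)
    n_imputed = 0
    df = pd.DataFrame({"block": villages.block_id, "y": y})
    block_means = df.groupby("block")["y"].mean()
    for i in range(len(y)):
        if np.isnan(y[i]):
            bm = block_means.get(villages.block_id[i], np.nan)
            if np.isnan(bm):
                keep[i] = False
            else:
                y[i] = bm
                n_imputed += 1
    return y, keep, n_imputed


def train_val_split(n: int, split_fraction: float, seed: int) -> np.ndarray:
    """Seed-reproducible random split; train count = floor(fraction * n)."""
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(split_fraction * n))
    split = np.full(n, "val", dtype=object)
    split[order[:n_train]] = "train"
    return split


def assemble_samples(
    villages: VillageMap,
    bands: np.ndarray,
    weather: np.ndarray,
    soil: np.ndarray,
    combination: str = "band-weather",
    split_fraction: float = 0.8,
    seed: int = 0,
    static: np.ndarray | None = None,
) -> SampleSet:
    """Build the analytical sample set for one dataset combination.

    Parameters
    ----------
    villages
        Village map; missing yields are imputed with block means first.
    bands, weather, soil
        Per-village zonal aggregates with shapes ``(n, T1, F1)``,
        ``(n, T2, F2)`` and ``(n, F3)``.
    combination
        Which covariate groups enter the feature set.
    static
        Optional ``(n, k)`` static branch input for the recurrent model;
        defaults to a crop-indicator column of ones.
    seed
        Fixes the random train/validation partition.

    Villages with an unimputable yield or any missing feature in the
    active groups are dropped (counted in ``n_dropped``), so the returned
    set has no missing entries.
    """
    use_b, use_w, use_s = _combo(combination)
    n = len(villages)
    bands = np.asarray(bands, dtype=float).reshape(n, *np.shape(bands)[1:])
    weather = np.asarray(weather, dtype=float)
    soil = np.asarray(soil, dtype=float)
    if static is None:
        static = np.ones((n, 1))
    static = np.asarray(static, dtype=float)

    y, keep, n_imputed = impute_block_means(villages)
    active = []
    if use_b:
        active.append(bands.reshape(n, -1))
    if use_w:
        active.append(weather.reshape(n, -1))
    if use_s:
        active.append(soil.reshape(n, -1))
    feat_ok = ~np.isnan(np.concatenate(active + [static], axis=1)).any(axis=1)
    keep &= feat_ok
    n_dropped = int((~keep).sum())

    idx = np.flatnonzero(keep)
    split = train_val_split(len(idx), split_fraction, seed)
    return SampleSet(
        village_id=villages.village_id[idx],
        bands=bands[idx] if use_b else np.empty((len(idx), 0, 0)),
        weather=weather[idx] if use_w else np.empty((len(idx), 0, 0)),
        soil=soil[idx] if use_s else np.empty((len(idx), 0)),
        static=static[idx],
        y=y[idx],
        split=split,
        combination=combination,
        n_imputed=n_imputed,
        n_dropped=n_dropped,
    )
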