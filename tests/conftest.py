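"""Shared fixtures: small synthetic scenes and printed validation tables."""

from pathlib import Path

import pandas as pd
import pytest

from pixelyield import SceneConfig, generate_scene

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_scene():
    """A fast 40x40 scene with 12 villages for unit-level checks."""
    return generate_scene(
        SceneConfig(rows=40, cols=40, n_villages=12, weather_block_px=20, seed=11)
    )


@pytest.fixture(scope="session")
def noiseless_scene():
    """Full coverage, no observation noise: aggregation identities are exact."""
    return generate_scene(
        SceneConfig(
            rows=30, cols=30, n_villages=8, weather_block_px=15,
            mask_coverage=1.0, obs_noise_sd=0.0, seed=5,
        )
    )


@pytest.fixture(scope="session")
def learnable_scene():
    """Strong covariate signal, little unexplained structure or noise."""
    return generate_scene(
        SceneConfig(
            rows=50, cols=50, n_villages=30, weather_block_px=25,
            sill=0.04, obs_noise_sd=0.05, covariate_noise_sd=0.05, seed=21,
        )
    )


@pytest.fixture(scope="session")
def wheat_blocks():
    return pd.read_csv(DATA_DIR / "block_yields_wheat.csv")


@pytest.fixture(scope="session")
def mustard_blocks():
    return pd.read_csv(DATA_DIR / "block_yields_mustard.csv")
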