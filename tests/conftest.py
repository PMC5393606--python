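"""Shared fixtures: small synthetic scenes and climate records."""

import numpy as np
import pandas as pd
import pytest

import ecosite as es
from ecosite.classify import SampleSet


@pytest.fixture(scope="session")
def decade_climate():
    """Ten years of baseline monsoon precipitation."""
    return es.simulate_precipitation(
        "1989-01-01", "1999-12-31", [("1989-01-01", "1999-12-31", 1.0)], seed=42
    )


@pytest.fixture(scope="session")
def wet_dry_climate():
    """Five wet years followed by five dry years."""
    return es.simulate_precipitation(
        "1989-01-01",
        "1999-12-31",
        [("1989-01-01", "1994-12-31", 2.0), ("1995-01-01", "1999-12-31", 0.6)],
        seed=7,
    )


@pytest.fixture(scope="session")
def decade_grid():
    return es.build_time_grid("1990-01-05", "1999-12-20", 16)


@pytest.fixture(scope="session")
def small_scene(wet_dry_climate, decade_grid):
    """Noise-free reference-state mosaic with ground truth."""
    config = es.paper_like_config(10, 10, layout="reference", noise_sd=0.0, seed=5)
    stack, truth = es.simulate_scene(config, wet_dry_climate, decade_grid)
    return config, stack, truth


@pytest.fixture(scope="session")
def mixture_scene(wet_dry_climate, decade_grid):
    """Noise-free full state-and-transition mosaic."""
    config = es.paper_like_config(14, 10, layout="state_mixture", noise_sd=0.0, seed=5)
    stack, truth = es.simulate_scene(config, wet_dry_climate, decade_grid)
    return config, stack, truth


def bind_samples(frame: pd.DataFrame, transform) -> SampleSet:
    """Attach (row, col) pixel indices to a draw_samples frame."""
    frame = frame.copy()
    frame["row"], frame["col"] = transform.rowcol(frame["x"].values, frame["y"].values)
    return SampleSet(frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
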