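"""Shared fixtures: small grids and synthetic sessions generated at test time."""

import numpy as np
import pytest

from ecognet.grid import GridSet, make_grid
from ecognet.synth import EffectSpec, SynthConfig, simulate_session


@pytest.fixture(scope="session")
def small_grid() -> GridSet:
    """A single 4x4 array (16 channels)."""
    return GridSet([make_grid(4, 4, 2.5, "A")])


@pytest.fixture(scope="session")
def two_array_grid() -> GridSet:
    """Two small arrays sharing a global channel numbering (12 + 9 channels)."""
    return GridSet([make_grid(3, 4, 2.5, "L"), make_grid(3, 3, 2.5, "R")])


@pytest.fixture(scope="session")
def stock_grid() -> GridSet:
    """The emulated recording layout: 8x16 + 8x8 (192 channels)."""
    return GridSet([make_grid(8, 16, 2.5, "TC"), make_grid(8, 8, 2.5, "dmPFC")])


@pytest.fixture(scope="session")
def effect_epochs(small_grid):
    """Session with a planted gamma-band category effect on a 2x2 block
    (channels 5, 6, 9, 10), strong enough for near-perfect decoding."""
    eff = EffectSpec(channels=[5, 6, 9, 10], band=(40, 80), window=(0.3, 1.0),
                     amplitude=2.0,
                     category_gain={"animate": 2.5, "inanimate": 1.0},
                     shared=False)
    cfg = SynthConfig(grid=small_grid, n_trials=120, epoch_window=(-0.7, 1.5),
                      effects=[eff], seed=11)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def null_epochs(small_grid):
    """Pure-noise session (no effects, no couplings)."""
    cfg = SynthConfig(grid=small_grid, n_trials=80, epoch_window=(-0.7, 1.5),
                      seed=21)
    return simulate_session(cfg)
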