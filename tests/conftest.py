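"""Shared fixtures: a small photon-transport table and forward model.

The session-scoped grid is deliberately coarse (4×4 nodes, 2·10⁴ photons)
— enough for physically sensible path-length statistics in unit tests
while keeping the suite fast.  The full desk-scale pipeline lives in the
acceptance tests, which build their own stack.
"""

import numpy as np
import pytest

from melsci.config import Config
from melsci.pipeline import ForwardModel
from melsci.photon_mc import run_mc_grid


def small_config() -> Config:
    cfg = Config()
    cfg.mc.grid_t_epi = (0.05, 0.14, 0.3, 0.8)
    cfg.mc.grid_musp = (0.3, 0.8, 1.6, 3.5)
    cfg.mc.n_photons = 20_000
    return cfg


@pytest.fixture(scope="session")
def cfg_small() -> Config:
    return small_config()


@pytest.fixture(scope="session")
def mc_table(cfg_small):
    return run_mc_grid(cfg_small.mc, seed=11)


@pytest.fixture(scope="session")
def fm_small(mc_table, cfg_small) -> ForwardModel:
    return ForwardModel(mc_table, cfg_small)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
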