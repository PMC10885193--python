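"""Shared fixtures: small, fast simulation setups."""

from __future__ import annotations

import numpy as np
import pytest

from iscatrack import BlobParams, SimulationConfig, uniform_surface


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A light configuration for rendering tests (short, quiet movie)."""
    return SimulationConfig(n_frames=40, arrival_rate=0.0, noise_sigma=0.0, seed=7)


@pytest.fixture
def small_surface(small_cfg):
    return uniform_surface((small_cfg.n_px, small_cfg.n_px))


def make_cfg(**kwargs) -> SimulationConfig:
    """Convenience constructor used across test modules."""
    return SimulationConfig(**kwargs)


def single_scatterer_cfg(**kwargs) -> SimulationConfig:
    base = dict(
        n_frames=40,
        arrival_rate=0.0,
        noise_sigma=0.0,
        seed=7,
        blob=BlobParams(n_scatterers=1),
    )
    base.update(kwargs)
    return SimulationConfig(**base)
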