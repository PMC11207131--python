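"""Shared fixtures: small deterministic synthetic movies.

Everything is generated at test time by the package's own simulator; no data
files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from fucciflow import SimConfig
from fucciflow.fucci_sim import render_channels, simulate_monolayer


def small_config(**overrides) -> SimConfig:
    """A fast, well-spaced, noise-free monolayer for stage tests."""
    defaults = dict(
        fov_size_px=256, n_frames=30, n_cells_init=30,
        motility_speed=0.5, persistence=0.7, drift=(0.0, 0.0),
        repulsion_radius=20.0,
        phase_durations={"red": 15, "yellow": 5, "green": 12, "colorless": 3},
        phase_duration_cv=0.2, nucleus_sigma_px=3.0,
        peak_intensity={"red": 2000.0, "green": 2000.0},
        background=100.0, noise_sd=0.0, division_enabled=False,
        init_phase="random", rng_seed=7,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_records():
    cfg = small_config()
    return cfg, simulate_monolayer(cfg)


@pytest.fixture(scope="session")
def rendered_movie(sim_records):
    cfg, records = sim_records
    red, green = render_channels(records, cfg)
    return cfg, records, red, green


def gaussian_spot(shape, center_xy, sigma, amplitude, background=0.0):
    """Analytic isotropic Gaussian spot image (oracle for rendering and
    segmentation tests)."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    cx, cy = center_xy
    return background + amplitude * np.exp(
        -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma ** 2))
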