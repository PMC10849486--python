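"""Shared fixtures: small synthetic scenes and pick sets, generated at test time."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from duster.core import CurationConfig
from duster.particle_io import ImageMeta
from duster.synthetic import SimParams, generate_scene, simulate_picks


@pytest.fixture(scope="session")
def rendered_scene():
    """One small rendered micrograph: 12 high-S/N pentamers + 12 junk blobs."""
    params = SimParams(n_high=12, n_junk=12, nx=640, ny=640)
    return generate_scene(params, seed=11, render=True)


@pytest.fixture(scope="session")
def abstract_scene():
    """Coordinate-level scene on a sparse jittered grid, 2000 particles/class."""
    params = SimParams(
        n_high=2000,
        n_junk=2000,
        nx=9800,
        ny=9800,
        pixel_size_A=1.0,
        min_separation_px=150,
        placement="grid",
        pick_jitter_A=4.0,
        fp_rate=0.0,
        miss_rate=0.0,
    )
    return generate_scene(params, seed=23, render=False)


@pytest.fixture
def pick_pair(abstract_scene):
    """Two independent pickings of the abstract scene."""
    params = abstract_scene.params
    a = simulate_picks(abstract_scene, params, seed=101, set_label="A")
    b = simulate_picks(abstract_scene, params, seed=202, set_label="B")
    return a, b


@pytest.fixture
def flat_meta():
    """Geometry for coordinate-only tests: 1 Å/px so px and Å coincide."""
    return ImageMeta(pixel_size_A=1.0, nx=10_000, ny=10_000)


@pytest.fixture
def default_cfg():
    return CurationConfig(d_th_A=20.0, rounds=1, seed=0)


def make_picks(coords, micrograph_id="mic_000", set_label="A", prefix="p"):
    """Build a minimal pick table from a list of (x, y) tuples."""
    import pandas as pd

    coords = list(coords)
    return pd.DataFrame(
        {
            "pick_id": [f"{prefix}{i:04d}" for i in range(len(coords))],
            "micrograph_id": micrograph_id,
            "x_px": [float(x) for x, _ in coords],
            "y_px": [float(y) for _, y in coords],
            "set_label": set_label,
        }
    )


def gaussian_recenter_results(picks, sigma_px, seed, prob=0.9):
    """RecenterResult with isotropic Gaussian displacement of the pick coordinates."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = len(picks)
    dx = rng.normal(0, sigma_px, n)
    dy = rng.normal(0, sigma_px, n)
    return pd.DataFrame(
        {
            "pick_id": picks["pick_id"].to_numpy(),
            "shift_x_px": dx,
            "shift_y_px": dy,
            "recentered_x_px": picks["x_px"].to_numpy() + dx,
            "recentered_y_px": picks["y_px"].to_numpy() + dy,
            "class_id": np.zeros(n, dtype=int),
            "class_prob": np.full(n, prob),
        }
    )
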