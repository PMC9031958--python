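"""Shared fixtures: small simulated populations and rendered movies."""

import numpy as np
import pandas as pd
import pytest

from nuctrack import synthetic


def truth_to_tracks(truth: pd.DataFrame) -> pd.DataFrame:
    """Turn a ground-truth table into the long track-table schema."""
    tracks = truth.rename(columns={"cell_id": "track_id"}).drop(columns=["step_um"])
    tracks["cb_ratio"] = tracks["length_c_um"] / tracks["length_b_um"]
    return tracks


@pytest.fixture(scope="session")
def control_truth() -> pd.DataFrame:
    cfg = synthetic.preset("control_like", n_cells=60, n_frames=60, seed=101)
    return synthetic.simulate_tracks(cfg)


@pytest.fixture(scope="session")
def cd_truth() -> pd.DataFrame:
    cfg = synthetic.preset("cd_like", n_cells=60, n_frames=60, seed=102)
    return synthetic.simulate_tracks(cfg)


@pytest.fixture(scope="session")
def control_tracks(control_truth) -> pd.DataFrame:
    return truth_to_tracks(control_truth)


@pytest.fixture(scope="session")
def cd_tracks(cd_truth) -> pd.DataFrame:
    return truth_to_tracks(cd_truth)


@pytest.fixture(scope="session")
def small_rendered():
    """A small rendered movie with its ground truth (8 cells, 20 frames)."""
    cfg = synthetic.preset(
        "control_like", n_cells=8, n_frames=20, field_size_px=(512, 512), seed=5
    )
    truth = synthetic.simulate_tracks(cfg)
    frames = synthetic.render_movie(truth, cfg)
    return cfg, truth, frames


def draw_disk(radius_um: float, pixel_size_um: float, shape=(256, 256), center=None):
    """Rasterize a bright disk on a dark background (no noise)."""
    img = np.zeros(shape, dtype=float)
    cy, cx = center or (shape[0] / 2, shape[1] / 2)
    r_px = radius_um / pixel_size_um
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2] = 1000.0
    return img
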