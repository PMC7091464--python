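"""Shared fixtures: synthetic acquisitions reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from nanogap.masking import ContactMask
from nanogap.synthetic_data import (
    DiskContact,
    SimulationParams,
    generate_spacer_image,
    simulate_tracks,
)
from nanogap.tracking import MIN_TRACK_LENGTH


@pytest.fixture(scope="session")
def default_image_mask():
    """Default spacer image and its exact disk mask (fixed seed)."""
    params = SimulationParams(seed=11)
    image, mask = generate_spacer_image(params, DiskContact(radius_um=6.0))
    return image, mask, params


@pytest.fixture(scope="session")
def barrier_free_run(default_image_mask):
    """Barrier-free acquisition over the default disk mask."""
    _, mask, _ = default_image_mask
    params = SimulationParams(seed=22)
    locs, truth = simulate_tracks(params, mask)
    return locs, truth, mask, params


@pytest.fixture(scope="session")
def barrier_run(default_image_mask):
    """Acquisition with entry barrier 1.5 kT and exit barrier 0.3 kT."""
    _, mask, _ = default_image_mask
    params = SimulationParams(seed=21, eps_enter=1.5, eps_exit=0.3)
    locs, truth = simulate_tracks(params, mask)
    return locs, truth, mask, params


def keep_long(tracks: pd.DataFrame) -> pd.DataFrame:
    lengths = tracks.groupby("track_id")["frame"].transform("size")
    return tracks[lengths >= MIN_TRACK_LENGTH]


@pytest.fixture(scope="session")
def square_mask():
    """128x128 px mask with a square contact, edges at 5.12 and 15.36 um."""
    grid = np.zeros((128, 128), dtype=bool)
    grid[32:96, 32:96] = True
    return ContactMask(mask=grid, pixel_size=0.16)


def make_track(track_id, xs, y=10.0, start_frame=0):
    """Horizontal track fixture at constant y (um)."""
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": np.arange(start_frame, start_frame + len(xs)),
            "x_um": np.asarray(xs, dtype=float),
            "y_um": np.full(len(xs), float(y)),
        }
    )
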