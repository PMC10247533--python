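"""Shared fixtures: synthetic embryos are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import rosettex as rx
from rosettex.surface import InteriorMask


@pytest.fixture(scope="session")
def default_embryo():
    """Default study conditions, zero noise (for exact classifier checks)."""
    params = rx.EmbryoParams(seed=11, noise_sd=0.0)
    stack, truth = rx.generate_static_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def basal_embryo():
    """Default SNR, basal-only rosettes (morphometrics configuration)."""
    params = rx.EmbryoParams(seed=7, rosette_location_probs=(1.0, 0.0, 0.0))
    stack, truth = rx.generate_static_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def basal_split(basal_embryo):
    params, stack, truth = basal_embryo
    eroded = rx.erode_physical(truth.interior_mask, 10.0,
                               params.voxel_size_z, params.voxel_size_xy)
    interior = InteriorMask(eroded, 10.0, params.voxel_size_z, params.voxel_size_xy)
    return rx.split_surface(stack, interior, 2.0, "soft")


@pytest.fixture(scope="session")
def movie_run():
    """One tracked synthetic movie: schedule, frames, tables, track graph."""
    from rosettex.movie import default_event_schedule

    params = rx.movie_params(seed=5)
    schedule, roster = default_event_schedule(params)
    frames, truth = rx.generate_timelapse(params, schedule, roster)
    interior = rx.movie_interior(truth.surface_height_map, frames[0], 10.0)
    tables = rx.segment_movie_frames(frames, interior=interior)
    graph = rx.build_tracks(tables)
    return dict(params=params, schedule=schedule, roster=roster, frames=frames,
                truth=truth, tables=tables, graph=graph)


def circle_polygon(cx: float, cy: float, r: float, n: int = 128) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])
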