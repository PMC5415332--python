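"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shoalmaze import MazeGeometry, TrialMetadata, TrialTrajectories
from shoalmaze.occupancy import OccupancySeries, _buffer_arm_series


@pytest.fixture
def geometry() -> MazeGeometry:
    return MazeGeometry(px_per_cm=12.0)


def make_metadata(
    n_fish: int = 4,
    trial_id: str = "t1",
    predation: str = "high",
    sex: str = "female",
    analysis_start: float = 30.0,
    trial_end: float = 300.0,
) -> TrialMetadata:
    return TrialMetadata(
        trial_id=trial_id,
        river="r1",
        predation=predation,
        sex=sex,
        group_size=n_fish,
        body_lengths={f"f{i+1}": 3.0 + 0.1 * i for i in range(n_fish)},
        analysis_start=analysis_start,
        trial_end=trial_end,
    )


def occupancy_from_raw(
    raw: np.ndarray,
    geometry: MazeGeometry,
    metadata: TrialMetadata | None = None,
    fps: float | None = None,
    uncertainty: np.ndarray | None = None,
    depth: np.ndarray | None = None,
) -> OccupancySeries:
    """Build an OccupancySeries from a raw region-code matrix (n_fish, n_frames).

    Buffering uses the production rule; tests pair this with an independent
    state-machine oracle on the same raw matrix.
    """
    raw = np.asarray(raw, dtype=np.int8)
    n_fish, n_frames = raw.shape
    metadata = metadata or make_metadata(n_fish)
    fps = fps or geometry.fps
    frames = np.arange(n_frames, dtype=np.int64)
    times = frames / fps
    buffered = np.vstack([_buffer_arm_series(raw[i], geometry.start_arm) for i in range(n_fish)])
    return OccupancySeries(
        metadata=metadata,
        geometry=geometry,
        fish_ids=metadata.fish_ids,
        frames=frames,
        times=times,
        raw=raw,
        buffered=buffered,
        depth=np.full(raw.shape, np.nan) if depth is None else depth,
        uncertainty=np.zeros(raw.shape) if uncertainty is None else uncertainty,
        gap_fraction={f: 0.0 for f in metadata.fish_ids},
        gap_flagged=False,
    )


def trajectories_from_path(
    points_per_fish: list[np.ndarray],
    geometry: MazeGeometry,
    metadata: TrialMetadata | None = None,
    uncertainty: np.ndarray | None = None,
) -> TrialTrajectories:
    """Build TrialTrajectories from per-fish (n_frames, 2) cm position arrays."""
    n_fish = len(points_per_fish)
    n_frames = len(points_per_fish[0])
    metadata = metadata or make_metadata(n_fish)
    xy = np.stack(points_per_fish)
    return TrialTrajectories(
        metadata=metadata,
        geometry=geometry,
        fish_ids=metadata.fish_ids,
        frames=np.arange(n_frames, dtype=np.int64),
        times=np.arange(n_frames) / geometry.fps,
        xy=xy,
        uncertainty=np.zeros((n_fish, n_frames)) if uncertainty is None else uncertainty,
    )
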