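"""Buffered arm-occupancy series.

While a fish is inside the central triangle it is still credited to the arm
it most recently visited; its buffered arm changes only at the frame it
enters a *different* arm's polygon. The central region therefore acts as a
buffer and only genuine arm-to-arm crossings show up as occupancy changes.
Fish that have not yet visited any arm are credited to the start arm.

Occlusion gaps (missing positions) carry the last buffered arm forward; the
per-fish gap fraction is reported and trials exceeding a configurable
fraction are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import ARM_CODES, MISSING, MazeGeometry, arm_entry_depth, points_to_regions
from .io import TrialMetadata, TrialTrajectories

logger = logging.getLogger(__name__)


@dataclass
class OccupancySeries:
    """Per-frame raw region and buffered arm for every fish in one trial.

    ``raw[f, t]``: region code at frame t (0 center, 1..3 arms, -2 missing).
    ``buffered[f, t]``: arm code in {1, 2, 3} under the buffer rule.
    ``depth[f, t]``: cm past the triangle side while in an arm (NaN
    elsewhere); orders simultaneous same-frame arm entries.
    """

    metadata: TrialMetadata
    geometry: MazeGeometry
    fish_ids: list[str]
    frames: np.ndarray
    times: np.ndarray
    raw: np.ndarray  # (n_fish, n_frames) int8
    buffered: np.ndarray  # (n_fish, n_frames) int8
    depth: np.ndarray  # (n_fish, n_frames)
    uncertainty: np.ndarray  # (n_fish, n_frames)
    gap_fraction: dict[str, float]
    gap_flagged: bool

    @property
    def analyzed(self) -> np.ndarray:
        return (self.times >= self.metadata.analysis_start) & (
            self.times <= self.metadata.trial_end
        )


def _buffer_arm_series(raw: np.ndarray, start_arm: int) -> np.ndarray:
    """Forward-fill arm codes over center/missing frames; start at start_arm."""
    is_arm = (raw >= 1) & (raw <= 3)
    idx = np.where(is_arm, np.arange(raw.size), -1)
    last_arm_idx = np.maximum.accumulate(idx)
    buffered = np.where(last_arm_idx >= 0, raw[np.maximum(last_arm_idx, 0)], start_arm)
    return buffered.astype(np.int8)


def assign_arms(
    trajectories: TrialTrajectories,
    geometry: MazeGeometry | None = None,
    *,
    max_gap_fraction: float = 0.2,
) -> OccupancySeries:
    """Convert raw positions into buffered arm occupancy.

    Re-entering the arm last visited produces no occupancy change; occlusion
    gaps carry the buffered arm forward. Duplicate consecutive frames cannot
    introduce transitions (the buffer rule is idempotent under re-sampling).
    """
    geometry = geometry or trajectories.geometry
    n_fish, n_frames = trajectories.xy.shape[:2]
    raw = np.empty((n_fish, n_frames), dtype=np.int8)
    depth = np.empty((n_fish, n_frames))
    buffered = np.empty((n_fish, n_frames), dtype=np.int8)
    gap_fraction: dict[str, float] = {}

    for i, fid in enumerate(trajectories.fish_ids):
        codes = points_to_regions(trajectories.xy[i], geometry)
        raw[i] = codes
        depth[i] = arm_entry_depth(trajectories.xy[i], codes, geometry)
        buffered[i] = _buffer_arm_series(codes, geometry.start_arm)
        gap_fraction[fid] = float(np.mean(codes == MISSING))

    flagged = any(g > max_gap_fraction for g in gap_fraction.values())
    if flagged:
        logger.warning(
            "trial %s: occlusion gap fraction exceeds %.0f%% for some fish: %s",
            trajectories.metadata.trial_id,
            100 * max_gap_fraction,
            {f: round(g, 3) for f, g in gap_fraction.items() if g > max_gap_fraction},
        )

    return OccupancySeries(
        metadata=trajectories.metadata,
        geometry=geometry,
        fish_ids=list(trajectories.fish_ids),
        frames=trajectories.frames,
        times=trajectories.times,
        raw=raw,
        buffered=buffered,
        depth=depth,
        uncertainty=trajectories.uncertainty,
        gap_fraction=gap_fraction,
        gap_flagged=flagged,
    )
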