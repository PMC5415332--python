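"""Reading and writing trajectory / metadata tables.

Table schemas (CSV, one header row):

trajectory table
    ``trial_id, frame, time_s, fish_id, x_px, y_px, uncertainty``
    One row per fish per frame. ``x_px``/``y_px`` are pixel coordinates in the
    maze-centred frame (converted to cm via ``geometry.px_per_cm``); they may
    be empty for occluded frames. ``uncertainty`` is the tracker's
    misidentification likelihood for the track segment containing the frame
    (0 = certain identity, 1 = identity picked among equally likely options).

metadata table
    ``trial_id, river, predation, sex, group_size, fish_id, body_length_cm``
    One row per fish per trial.

The writer emits exactly this schema, so write -> load round-trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import MazeGeometry

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["trial_id", "frame", "time_s", "fish_id", "x_px", "y_px", "uncertainty"]
METADATA_COLUMNS = ["trial_id", "river", "predation", "sex", "group_size", "fish_id", "body_length_cm"]

PREDATION_LEVELS = ("low", "medium", "high")
SEXES = ("female", "male")


class SchemaError(ValueError):
    """A table does not conform to the documented column schema."""


class TrajectoryValidationError(ValueError):
    """A trajectory table violates a value constraint (ordering, bounds)."""


@dataclass(frozen=True)
class TrialMetadata:
    """Static facts about one trial: provenance, group composition, window."""

    trial_id: str
    river: str
    predation: str
    sex: str
    group_size: int
    body_lengths: Mapping[str, float]  # fish_id -> standard length (cm)
    analysis_start: float = 30.0
    trial_end: float = 300.0

    def __post_init__(self) -> None:
        if self.predation not in PREDATION_LEVELS:
            raise ValueError(f"predation must be one of {PREDATION_LEVELS}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.group_size != len(self.body_lengths):
            raise ValueError("body_lengths must list exactly group_size fish")
        if not (0 <= self.analysis_start < self.trial_end):
            raise ValueError("need 0 <= analysis_start < trial_end")

    @property
    def fish_ids(self) -> list[str]:
        return sorted(self.body_lengths)


@dataclass
class TrialTrajectories:
    """Per-frame positions (cm) and identity uncertainty for one trial.

    ``frames`` is the common frame grid; ``xy[f, t]`` is fish f's position at
    frame t (NaN where the fish was occluded), ``uncertainty[f, t]`` the
    tracker uncertainty. Frames before ``metadata.analysis_start`` are kept
    but flagged by ``analyzed``.
    """

    metadata: TrialMetadata
    geometry: MazeGeometry
    fish_ids: list[str]
    frames: np.ndarray  # (n_frames,) int
    times: np.ndarray  # (n_frames,) s
    xy: np.ndarray  # (n_fish, n_frames, 2) cm
    uncertainty: np.ndarray  # (n_fish, n_frames)

    @property
    def analyzed(self) -> np.ndarray:
        """Boolean mask over frames inside [analysis_start, trial_end]."""
        return (self.times >= self.metadata.analysis_start) & (
            self.times <= self.metadata.trial_end
        )

    @property
    def missing(self) -> np.ndarray:
        """(n_fish, n_frames) True where position is unavailable."""
        return ~np.isfinite(self.xy).all(axis=2)

    def to_table(self) -> pd.DataFrame:
        """Long-format trajectory table in the documented CSV schema."""
        rows = []
        for i, fid in enumerate(self.fish_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": self.metadata.trial_id,
                        "frame": self.frames,
                        "time_s": self.times,
                        "fish_id": fid,
                        "x_px": self.xy[i, :, 0] * self.geometry.px_per_cm,
                        "y_px": self.xy[i, :, 1] * self.geometry.px_per_cm,
                        "uncertainty": self.uncertainty[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True).sort_values(
            ["frame", "fish_id"], kind="stable", ignore_index=True
        )


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def metadata_from_table(meta_df: pd.DataFrame, trial_id: str, **window) -> TrialMetadata:
    """Build :class:`TrialMetadata` for one trial from the metadata table."""
    _require_columns(meta_df, METADATA_COLUMNS, "metadata")
    rows = meta_df[meta_df["trial_id"].astype(str) == str(trial_id)]
    if rows.empty:
        raise SchemaError(f"trial {trial_id!r} absent from metadata table")
    first = rows.iloc[0]
    group_size = int(first["group_size"])
    body_lengths = {
        str(r.fish_id): float(r.body_length_cm) for r in rows.itertuples(index=False)
    }
    return TrialMetadata(
        trial_id=str(trial_id),
        river=str(first["river"]),
        predation=str(first["predation"]),
        sex=str(first["sex"]),
        group_size=group_size,
        body_lengths=body_lengths,
        **window,
    )


def load_trial(
    trajectory_table: pd.DataFrame | str | Path,
    metadata_table: pd.DataFrame | str | Path,
    geometry: MazeGeometry,
    trial_id: str | None = None,
    *,
    analysis_start: float = 30.0,
    trial_end: float = 300.0,
) -> TrialTrajectories:
    """Load and validate one trial from trajectory + metadata tables.

    Positions are converted from pixels to cm with ``geometry.px_per_cm``.
    Raises :class:`SchemaError` for missing columns or identity mismatches and
    :class:`TrajectoryValidationError` for non-monotone time or uncertainty
    outside [0, 1].
    """
    traj = _as_df(trajectory_table)
    meta = _as_df(metadata_table)
    _require_columns(traj, TRAJECTORY_COLUMNS, "trajectory")

    if trial_id is None:
        ids = traj["trial_id"].astype(str).unique()
        if len(ids) != 1:
            raise SchemaError(
                f"trajectory table holds {len(ids)} trials; pass trial_id explicitly"
            )
        trial_id = ids[0]
    traj = traj[traj["trial_id"].astype(str) == str(trial_id)].copy()
    if traj.empty:
        raise SchemaError(f"trial {trial_id!r} absent from trajectory table")

    metadata = metadata_from_table(
        meta, trial_id, analysis_start=analysis_start, trial_end=trial_end
    )

    traj["fish_id"] = traj["fish_id"].astype(str)
    traj_fish = set(traj["fish_id"].unique())
    meta_fish = set(metadata.fish_ids)
    if traj_fish != meta_fish:
        raise SchemaError(
            f"fish identities differ between tables: trajectory {sorted(traj_fish)} "
            f"vs metadata {sorted(meta_fish)}"
        )

    unc = traj["uncertainty"].to_numpy(dtype=float)
    if np.nanmin(unc) < 0 or np.nanmax(unc) > 1:
        raise TrajectoryValidationError("uncertainty values must lie in [0, 1]")

    fish_ids = metadata.fish_ids
    frames = np.sort(traj["frame"].unique().astype(np.int64))
    n_frames = len(frames)
    frame_pos = {f: i for i, f in enumerate(frames)}

    dt = 1.0 / geometry.fps
    times = frames * dt

    xy = np.full((len(fish_ids), n_frames, 2), np.nan)
    uncertainty = np.zeros((len(fish_ids), n_frames))
    for i, fid in enumerate(fish_ids):
        sub = traj[traj["fish_id"] == fid].sort_values("frame", kind="stable")
        t = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrajectoryValidationError(
                f"time_s not strictly increasing for fish {fid!r}"
            )
        f_idx = np.array([frame_pos[f] for f in sub["frame"].astype(np.int64)])
        if len(np.unique(f_idx)) != len(f_idx):
            raise TrajectoryValidationError(f"duplicate frames for fish {fid!r}")
        if not np.allclose(t, frames[f_idx] * dt, atol=dt / 4):
            raise TrajectoryValidationError(
                f"time_s inconsistent with frame/fps grid for fish {fid!r}"
            )
        xy[i, f_idx, 0] = sub["x_px"].to_numpy(dtype=float) / geometry.px_per_cm
        xy[i, f_idx, 1] = sub["y_px"].to_numpy(dtype=float) / geometry.px_per_cm
        uncertainty[i, f_idx] = sub["uncertainty"].to_numpy(dtype=float)
        n_gap = int(n_frames - len(f_idx))
        if n_gap:
            logger.info("trial %s fish %s: %d missing frames", trial_id, fid, n_gap)

    return TrialTrajectories(
        metadata=metadata,
        geometry=geometry,
        fish_ids=fish_ids,
        frames=frames,
        times=times,
        xy=xy,
        uncertainty=uncertainty,
    )


def metadata_to_table(metadata: TrialMetadata) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": metadata.trial_id,
            "river": metadata.river,
            "predation": metadata.predation,
            "sex": metadata.sex,
            "group_size": metadata.group_size,
            "fish_id": metadata.fish_ids,
            "body_length_cm": [metadata.body_lengths[f] for f in metadata.fish_ids],
        }
    )


def write_dataset(
    trials: list[TrialTrajectories],
    trajectory_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write trials to the documented CSV schema (round-trip safe)."""
    traj = pd.concat([t.to_table() for t in trials], ignore_index=True)
    meta = pd.concat([metadata_to_table(t.metadata) for t in trials], ignore_index=True)
    traj.to_csv(trajectory_path, index=False)
    meta.to_csv(metadata_path, index=False)


def _as_df(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.read_csv(table)
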