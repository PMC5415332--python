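"""Arm-to-arm transition events: extraction, classification, annotation.

A transition is a change of buffered arm. Each transition is classified by
the buffered arms of the other group members at the entry frame:

* **initiation** — movement into an arm containing no other fish;
* **follow** — movement into an arm already occupied by at least one other
  fish (a fish lingering in the central triangle still counts in its buffered
  arm).

For each initiation we record whether it was followed: at least one other
fish entered the initiated arm strictly before the initiator's next departure
from it (otherwise the initiator left unfollowed). The latency to the first
follower and the number of distinct followers within that window are
annotated. Initiations still open at trial end are censored: the window
truncates at ``trial_end``.

Transitions inherit the tracker's identity-uncertainty value of the segment
active at the entry frame and can be thresholded: every event whose
uncertainty exceeds the threshold is removed before computing counts.

Same-frame tie-break: if two fish enter arms on the same video frame, the one
deeper past the triangle side is taken to have crossed earlier (at equal
swimming speed, depth past the boundary is a monotone proxy for crossing
time); remaining ties order by fish id. Earlier entries update occupancy
before later same-frame entries are classified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import TrialMetadata
from .occupancy import OccupancySeries

EVENT_COLUMNS = [
    "trial_id",
    "fish_id",
    "order",
    "frame",
    "time_s",
    "from_arm",
    "to_arm",
    "kind",
    "n_occupants_at_entry",
    "uncertainty",
    "followed",
    "latency_to_first_follow_s",
    "n_followers",
    "censored",
]


@dataclass
class EventLog:
    """Time-ordered transition events for one trial."""

    metadata: TrialMetadata
    events: pd.DataFrame  # EVENT_COLUMNS schema
    threshold_applied: float | None = None

    def __len__(self) -> int:
        return len(self.events)

    def to_table(self) -> pd.DataFrame:
        """Export table; adds log10 of the follow latency (s) for initiations.

        Zero latencies (same-frame follows) are floored at half a frame
        interval before the log transform.
        """
        df = self.events.copy()
        lat = df["latency_to_first_follow_s"].to_numpy(dtype=float)
        floor = 0.5 / 25.0
        with np.errstate(invalid="ignore", divide="ignore"):
            df["log10_latency"] = np.log10(np.maximum(lat, floor))
        df.loc[~np.isfinite(lat), "log10_latency"] = np.nan
        return df


def _empty_events(trial_id: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=EVENT_COLUMNS)
    return df.astype(
        {
            "order": "int64",
            "frame": "int64",
            "time_s": "float64",
            "from_arm": "int64",
            "to_arm": "int64",
            "n_occupants_at_entry": "int64",
            "uncertainty": "float64",
            "followed": "boolean",
            "latency_to_first_follow_s": "float64",
            "n_followers": "Int64",
            "censored": "boolean",
        },
        errors="ignore",
    )


def extract_transitions(
    occupancy: OccupancySeries, metadata: TrialMetadata | None = None
) -> EventLog:
    """Extract and classify all buffered-arm changes in the analysis window.

    One event per buffered-arm change per fish with entry time inside
    [analysis_start, trial_end]. Classification replays entries in
    (frame, depth-desc, fish_id) order so that same-frame entries see
    earlier same-frame entries already in place.
    """
    metadata = metadata or occupancy.metadata
    buffered = occupancy.buffered
    times = occupancy.times
    n_fish, n_frames = buffered.shape

    changes = []  # (frame_idx, depth_rank_key, fish_idx, from_arm, to_arm)
    for i in range(n_fish):
        b = buffered[i]
        idx = np.flatnonzero(b[1:] != b[:-1]) + 1
        for t in idx:
            if not (metadata.analysis_start <= times[t] <= metadata.trial_end):
                continue
            d = occupancy.depth[i, t]
            changes.append((int(t), -(d if np.isfinite(d) else -np.inf), i, int(b[t - 1]), int(b[t])))

    if not changes:
        return EventLog(metadata=metadata, events=_empty_events(metadata.trial_id))

    changes.sort(key=lambda c: (c[0], c[1], occupancy.fish_ids[c[2]]))

    rows = []
    k = 0
    while k < len(changes):
        frame = changes[k][0]
        # occupancy state just before this frame's entries
        state = buffered[:, frame - 1].copy() if frame > 0 else buffered[:, 0].copy()
        while k < len(changes) and changes[k][0] == frame:
            _, _, i, from_arm, to_arm = changes[k]
            n_occ = int(np.sum((state == to_arm) & (np.arange(n_fish) != i)))
            rows.append(
                {
                    "trial_id": metadata.trial_id,
                    "fish_id": occupancy.fish_ids[i],
                    "order": len(rows),
                    "frame": int(occupancy.frames[frame]),
                    "time_s": float(times[frame]),
                    "from_arm": from_arm,
                    "to_arm": to_arm,
                    "kind": "initiation" if n_occ == 0 else "follow",
                    "n_occupants_at_entry": n_occ,
                    "uncertainty": float(occupancy.uncertainty[i, frame]),
                    "followed": pd.NA,
                    "latency_to_first_follow_s": np.nan,
                    "n_followers": pd.NA,
                    "censored": pd.NA,
                }
            )
            state[i] = to_arm
            k += 1

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events["followed"] = events["followed"].astype("boolean")
    events["censored"] = events["censored"].astype("boolean")
    events["n_followers"] = events["n_followers"].astype("Int64")
    return EventLog(metadata=metadata, events=events)


def annotate_follow_outcomes(
    event_log: EventLog, occupancy: OccupancySeries | None = None
) -> EventLog:
    """Annotate each initiation with its follow outcome.

    ``followed`` is True iff at least one other fish entered the initiated arm
    after the initiation and before the initiator's next transition (its
    departure from that arm, in buffered terms). Initiations with no
    subsequent departure are censored at ``trial_end``; their window runs to
    the end of the trial. Event order resolves same-frame sequencing.
    """
    meta = event_log.metadata
    ev = event_log.events.copy()
    if ev.empty:
        return EventLog(metadata=meta, events=ev, threshold_applied=event_log.threshold_applied)

    orders = ev["order"].to_numpy()
    fish = ev["fish_id"].to_numpy()
    to_arm = ev["to_arm"].to_numpy()
    time_s = ev["time_s"].to_numpy()
    kind = ev["kind"].to_numpy()

    followed = np.zeros(len(ev), dtype=bool)
    latency = np.full(len(ev), np.nan)
    n_followers = np.zeros(len(ev), dtype=int)
    censored = np.zeros(len(ev), dtype=bool)

    for r in range(len(ev)):
        if kind[r] != "initiation":
            continue
        own_later = (fish == fish[r]) & (orders > orders[r])
        if own_later.any():
            dep_order = orders[own_later].min()
            window = (orders > orders[r]) & (orders < dep_order)
        else:
            censored[r] = True
            window = (orders > orders[r]) & (time_s <= meta.trial_end)
        entries = window & (to_arm == to_arm[r]) & (fish != fish[r])
        if entries.any():
            followed[r] = True
            first = orders[entries].argmin()
            latency[r] = time_s[entries][first] - time_s[r]
            n_followers[r] = len(np.unique(fish[entries]))

    is_init = kind == "initiation"
    ev["followed"] = pd.array(np.where(is_init, followed, None), dtype="boolean")
    ev["latency_to_first_follow_s"] = np.where(is_init, latency, np.nan)
    ev["n_followers"] = pd.array(
        [int(n) if i else None for n, i in zip(n_followers, is_init)], dtype="Int64"
    )
    ev["censored"] = pd.array(np.where(is_init, censored, None), dtype="boolean")
    return EventLog(metadata=meta, events=ev, threshold_applied=event_log.threshold_applied)


def filter_by_uncertainty(event_log: EventLog, threshold: float) -> EventLog:
    """Remove every event whose identity uncertainty exceeds ``threshold``.

    Downstream counts are recomputed from the filtered log; classification
    labels are not revised (thresholding removes transitions, as in a tracker
    post-hoc filter, rather than re-running classification).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    kept = event_log.events[event_log.events["uncertainty"] <= threshold].reset_index(
        drop=True
    )
    return EventLog(metadata=event_log.metadata, events=kept, threshold_applied=threshold)


def split_half_counts(event_log: EventLog, metadata: TrialMetadata | None = None) -> pd.DataFrame:
    """Per-fish initiation counts in the first and second half of the trial.

    The analysed window [analysis_start, trial_end] is split at its midpoint;
    an initiation exactly at the midpoint counts in the second half. Columns:
    ``fish_id, n_init_first_half, n_init_second_half``.
    """
    metadata = metadata or event_log.metadata
    mid = 0.5 * (metadata.analysis_start + metadata.trial_end)
    ev = event_log.events
    init = ev[ev["kind"] == "initiation"]
    rows = []
    for fid in metadata.fish_ids:
        t = init.loc[init["fish_id"] == fid, "time_s"].to_numpy()
        rows.append(
            {
                "fish_id": fid,
                "n_init_first_half": int(np.sum(t < mid)),
                "n_init_second_half": int(np.sum(t >= mid)),
            }
        )
    return pd.DataFrame(rows)
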