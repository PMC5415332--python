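"""Per-fish and per-group summary statistics.

Per fish: initiation / follow / total transition counts and split-half
initiation counts. Per group: the coefficient of variation (COV) of
initiation counts — the diversity / differentiation statistic — plus the
max and min initiation counts, arm-based group cohesion, and open-arena
validation measures (mean speed, nearest and mean neighbor distance).

Transforms follow the analysis conventions for these quantities: follow
latencies are log10-transformed, mean cohesion is arcsine-square-root
transformed, and body lengths are standardized within sex.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventLog, split_half_counts
from .io import TrialMetadata
from .occupancy import OccupancySeries

FISH_COUNT_COLUMNS = [
    "trial_id",
    "fish_id",
    "n_initiations",
    "n_follows",
    "n_total",
    "n_init_first_half",
    "n_init_second_half",
]


def per_fish_counts(event_log: EventLog, metadata: TrialMetadata | None = None) -> pd.DataFrame:
    """Tally initiations, follows, totals and split-half initiation counts.

    Every fish in the trial metadata appears, with zeros if it never moved.
    Conservation holds by construction: ``n_total = n_initiations + n_follows``
    and the two halves sum to ``n_initiations``.
    """
    metadata = metadata or event_log.metadata
    ev = event_log.events
    halves = split_half_counts(event_log, metadata).set_index("fish_id")
    rows = []
    for fid in metadata.fish_ids:
        sub = ev[ev["fish_id"] == fid]
        n_init = int((sub["kind"] == "initiation").sum())
        n_follow = int((sub["kind"] == "follow").sum())
        rows.append(
            {
                "trial_id": metadata.trial_id,
                "fish_id": fid,
                "n_initiations": n_init,
                "n_follows": n_follow,
                "n_total": n_init + n_follow,
                "n_init_first_half": int(halves.loc[fid, "n_init_first_half"]),
                "n_init_second_half": int(halves.loc[fid, "n_init_second_half"]),
            }
        )
    return pd.DataFrame(rows, columns=FISH_COUNT_COLUMNS)


def group_cov(counts) -> float:
    """Coefficient of variation of per-fish initiation counts within a group.

    Sample (n-1) standard deviation divided by the mean. Returns NaN when the
    mean is zero (no initiations carry no diversity information; such trials
    are excluded from COV analyses).
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("group_cov needs at least two fish")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(x.std(ddof=1) / m)


def group_cohesion(occupancy: OccupancySeries, metadata: TrialMetadata | None = None) -> dict:
    """Arm-based group cohesion over the analysed window.

    Per fish and frame: the number of other fish sharing its buffered arm
    divided by the maximum possible (group_size - 1); averaged over frames per
    fish, then over fish. Returns the mean, its arcsine-square-root transform
    and the per-fish values.
    """
    metadata = metadata or occupancy.metadata
    if metadata.group_size < 2:
        raise ValueError("cohesion is undefined for single-fish trials")
    b = occupancy.buffered[:, occupancy.analyzed]
    n_fish = b.shape[0]
    same = (b[:, None, :] == b[None, :, :]).sum(axis=1) - 1  # others sharing arm
    per_fish = same.mean(axis=1) / (n_fish - 1)
    mean = float(per_fish.mean())
    return {
        "mean_cohesion": mean,
        "asin_sqrt_cohesion": float(np.arcsin(np.sqrt(np.clip(mean, 0.0, 1.0)))),
        "per_fish": {f: float(c) for f, c in zip(occupancy.fish_ids, per_fish)},
    }


def open_arena_measures(trajectories) -> dict:
    """Open-arena style activity/cohesion measures from the full trajectories.

    Mean speed (cm/s) from frame-to-frame displacement (occlusion gaps are
    skipped), and nearest / mean neighbor distances (cm) averaged over frames
    and fish. Computed over the analysed window, using all positions including
    frames spent in the central region.
    """
    mask = trajectories.analyzed
    xy = trajectories.xy[:, mask, :]
    dt_steps = np.diff(trajectories.times[mask])
    n_fish = xy.shape[0]

    speeds = []
    for i in range(n_fish):
        d = np.linalg.norm(np.diff(xy[i], axis=0), axis=1)
        ok = np.isfinite(d)
        if ok.any():
            speeds.append(float(np.mean(d[ok] / dt_steps[ok])))
    mean_speed = float(np.mean(speeds)) if speeds else float("nan")

    if n_fish >= 2:
        diff = xy[:, None, :, :] - xy[None, :, :, :]
        dist = np.linalg.norm(diff, axis=-1)  # (n_fish, n_fish, n_frames)
        eye = np.eye(n_fish, dtype=bool)
        dist[eye] = np.nan
        with np.errstate(all="ignore"):
            nearest = np.nanmin(dist, axis=1)
            meand = np.nanmean(dist, axis=1)
        mean_nnd = float(np.nanmean(nearest))
        mean_nd = float(np.nanmean(meand))
    else:
        mean_nnd = mean_nd = float("nan")

    return {
        "mean_speed_cm_s": mean_speed,
        "mean_nearest_neighbor_distance_cm": mean_nnd,
        "mean_neighbor_distance_cm": mean_nd,
    }


def group_stats(
    event_log: EventLog,
    occupancy: OccupancySeries,
    trajectories=None,
) -> dict:
    """Assemble the per-group summary row for one trial."""
    meta = event_log.metadata
    counts = per_fish_counts(event_log, meta)
    init = counts["n_initiations"].to_numpy()
    cohesion = group_cohesion(occupancy, meta)
    row = {
        "trial_id": meta.trial_id,
        "river": meta.river,
        "predation": meta.predation,
        "sex": meta.sex,
        "group_size": meta.group_size,
        "cov_initiations": group_cov(init),
        "max_initiations": int(init.max()),
        "min_initiations": int(init.min()),
        "mean_initiations": float(init.mean()),
        "mean_total_movements": float(counts["n_total"].mean()),
        "mean_cohesion": cohesion["mean_cohesion"],
        "asin_sqrt_cohesion": cohesion["asin_sqrt_cohesion"],
    }
    if trajectories is not None:
        row.update(open_arena_measures(trajectories))
    return row


def split_half_consistency(counts: pd.DataFrame, by: str = "predation") -> pd.DataFrame:
    """Spearman rank correlation of first- vs second-half initiation counts.

    ``counts`` is a fish-level table with ``n_init_first_half``,
    ``n_init_second_half`` and a grouping column (default ``predation``).
    Constant vectors give an undefined correlation, reported as NaN.
    """
    rows = []
    for level, sub in counts.groupby(by, observed=True):
        x = sub["n_init_first_half"].to_numpy(dtype=float)
        y = sub["n_init_second_half"].to_numpy(dtype=float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p, n = float("nan"), float("nan"), len(x)
        else:
            res = stats.spearmanr(x, y)
            r, p, n = float(res.statistic), float(res.pvalue), len(x)
        rows.append({by: level, "spearman_r": r, "p_value": p, "n_fish": n})
    return pd.DataFrame(rows)


def standardize_body_length(lengths, sexes) -> np.ndarray:
    """Standardize body lengths within each sex: (x - mean) / sample SD.

    Body size covaries with sex, so it is normalized within sex before use as
    a covariate. Sexes with fewer than two fish or zero SD give NaN.
    """
    lengths = np.asarray(lengths, dtype=float)
    sexes = np.asarray(sexes)
    out = np.full(lengths.shape, np.nan)
    for s in np.unique(sexes):
        m = sexes == s
        if m.sum() < 2:
            continue
        sd = lengths[m].std(ddof=1)
        if sd == 0:
            continue
        out[m] = (lengths[m] - lengths[m].mean()) / sd
    return out


def per_arm_balance(events: pd.DataFrame, by: str | None = "predation") -> pd.DataFrame:
    """Initiation and follow counts by destination arm (optionally by stratum).

    ``events`` is a concatenated event table that may carry a grouping column
    (e.g. predation level, joined from trial metadata). Used to check that arm
    use is approximately balanced.
    """
    df = events.copy()
    if df.empty:
        cols = ([by] if by and by in df.columns else []) + ["to_arm", "kind", "n_events"]
        return pd.DataFrame(columns=cols)
    keys = ([by] if by and by in df.columns else []) + ["to_arm", "kind"]
    out = df.groupby(keys, observed=True).size().rename("n_events").reset_index()
    return out.sort_values(keys, ignore_index=True)


def latency_analysis(event_log_events: pd.DataFrame | EventLog) -> dict:
    """Follow-latency table for followed initiations, with exclusion bookkeeping.

    Initiations that were never followed (the initiator left the arm before
    any other fish entered) are excluded from latency analyses; the fraction
    excluded is reported as a percentage rounded to one decimal.
    """
    ev = event_log_events.events if isinstance(event_log_events, EventLog) else event_log_events
    init = ev[ev["kind"] == "initiation"]
    n_total = len(init)
    if n_total == 0:
        return {"n_initiations": 0, "n_unfollowed": 0, "excluded_pct": float("nan"), "table": init}
    followed_mask = init["followed"].fillna(False).to_numpy(dtype=bool)
    n_unfollowed = int((~followed_mask).sum())
    table = init[followed_mask].copy()
    lat = table["latency_to_first_follow_s"].to_numpy(dtype=float)
    floor = 0.5 / 25.0
    with np.errstate(divide="ignore"):
        table["log10_latency"] = np.log10(np.maximum(lat, floor))
    return {
        "n_initiations": n_total,
        "n_unfollowed": n_unfollowed,
        "excluded_pct": round(100.0 * n_unfollowed / n_total, 1),
        "table": table,
    }


def residual_variability(
    df: pd.DataFrame, value_col: str, strata: list[str] = ("predation", "sex", "group_size")
) -> pd.Series:
    """Absolute residuals from stratum means (predation x sex x group size).

    A light-weight interindividual-variability export: |x - stratum mean|,
    ready for external variance-comparison tests on the exported tables.
    """
    strata = list(strata)
    fitted = df.groupby(strata, observed=True)[value_col].transform("mean")
    return (df[value_col] - fitted).abs()
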