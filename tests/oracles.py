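"""Independent brute-force oracles.

Plain-Python reimplementations of the pipeline's core operations, written as
direct frame scans and exhaustive enumerations with no shared code with the
package. Tests assert exact agreement between package and oracle.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def buffered_series(raw_row, start_arm: int) -> list[int]:
    """Step-by-step state machine for the buffered-arm rule on one fish."""
    out = []
    current = start_arm
    for code in raw_row:
        if code in (1, 2, 3):
            current = int(code)
        out.append(current)
    return out


def frame_scan_events(
    raw, fish_ids, times, start_arm: int, analysis_start: float, trial_end: float
) -> list[dict]:
    """Frame-by-frame transition extraction + classification.

    Within a frame, fish are processed in fish-id order (matching the
    package's tie-break when entry depths are unavailable); earlier entries
    update occupancy before later ones are classified.
    """
    n_fish, n_frames = np.asarray(raw).shape
    buf = [buffered_series(raw[i], start_arm) for i in range(n_fish)]
    order_of = sorted(range(n_fish), key=lambda i: fish_ids[i])
    state = [buf[i][0] for i in range(n_fish)]
    events = []
    for t in range(1, n_frames):
        for i in order_of:
            if buf[i][t] != state[i]:
                to_arm = buf[i][t]
                if analysis_start <= times[t] <= trial_end:
                    occupants = sum(1 for j in range(n_fish) if j != i and state[j] == to_arm)
                    events.append(
                        {
                            "fish_id": fish_ids[i],
                            "frame": t,
                            "time_s": times[t],
                            "from_arm": state[i],
                            "to_arm": to_arm,
                            "kind": "initiation" if occupants == 0 else "follow",
                            "n_occupants_at_entry": occupants,
                        }
                    )
                state[i] = to_arm
    return events


def follow_annotation(events: list[dict], trial_end: float) -> list[dict]:
    """Interval-overlap annotation of follow outcomes for each initiation.

    ``events`` must be in chronological (extraction) order. An initiation's
    window runs from its own index to the initiator's next event (exclusive)
    or to trial end (censored).
    """
    out = []
    for idx, ev in enumerate(events):
        if ev["kind"] != "initiation":
            continue
        later_own = [k for k in range(idx + 1, len(events)) if events[k]["fish_id"] == ev["fish_id"]]
        end_idx = later_own[0] if later_own else len(events)
        censored = not later_own
        entries = [
            events[k]
            for k in range(idx + 1, end_idx)
            if events[k]["to_arm"] == ev["to_arm"]
            and events[k]["fish_id"] != ev["fish_id"]
            and events[k]["time_s"] <= trial_end
        ]
        out.append(
            {
                "index": idx,
                "followed": bool(entries),
                "latency": entries[0]["time_s"] - ev["time_s"] if entries else math.nan,
                "n_followers": len({e["fish_id"] for e in entries}),
                "censored": censored,
            }
        )
    return out


def tally_counts(events: list[dict], fish_ids) -> dict:
    """Per-fish initiation/follow tallies."""
    out = {f: {"initiation": 0, "follow": 0} for f in fish_ids}
    for ev in events:
        out[ev["fish_id"]][ev["kind"]] += 1
    return out


def cov(values) -> float:
    """Direct two-pass sample-SD/mean evaluation."""
    values = list(values)
    n = len(values)
    m = sum(values) / n
    if m == 0:
        return math.nan
    sd = math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
    return sd / m


def spearman(x, y) -> float:
    """Rank-then-Pearson with midranks for ties."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def ols_slope(x, y) -> float:
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxx = sum((a - mx) ** 2 for a in x)
    if sxx == 0:
        return math.nan
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / sxx


def enumerate_pairwise_slopes(groups: list[tuple]) -> list[float]:
    """All fish-1/fish-2 labelings for groups of two (2^k layouts).

    Degenerate layouts (all fish-1 values equal) are omitted, matching the
    redraw convention.
    """
    slopes = []
    for flips in itertools.product([0, 1], repeat=len(groups)):
        x = [g[f] for g, f in zip(groups, flips)]
        y = [g[1 - f] for g, f in zip(groups, flips)]
        s = ols_slope(x, y)
        if not math.isnan(s):
            slopes.append(s)
    return slopes


def enumerate_shuffle_means(values: list, sizes: list[int], statistic) -> list[float]:
    """Mean group statistic for every ordering of ``values`` into groups.

    Exhaustive over all permutations of the pooled values; the Monte-Carlo
    shuffle draws uniformly from exactly this distribution.
    """
    means = []
    for perm in itertools.permutations(values):
        stats, k = [], 0
        for s in sizes:
            stats.append(statistic(perm[k : k + s]))
            k += s
        ok = [v for v in stats if not math.isnan(v)]
        means.append(sum(ok) / len(ok))
    return means
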