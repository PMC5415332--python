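"""Randomization tests for within-group differentiation.

Two Monte-Carlo procedures test whether the number of initiations made by a
fish depends on the other members of its group:

1. **Pairwise-slope test** — in every iteration, two distinct fish are drawn
   from each group and arbitrarily labelled fish 1 and fish 2; the ordinary
   least-squares slope of fish 2's initiation count on fish 1's across groups
   is recorded. Over many iterations a negative mean slope indicates a
   negative within-group effect (one fish initiating a lot suppresses the
   other), a positive mean slope a positive effect.

2. **Membership-shuffle test** — the observed mean of a per-group statistic
   (COV, max or min of initiation counts) is compared to its distribution
   when individuals' observed records are randomly re-assorted into groups of
   the same sizes within each stratum (predation level x group size, since
   group size affects initiation counts). If the observed mean falls outside
   the null 95% interval, group composition matters: fish differentiated (or
   conformed) within their actual groups.

Empirical p-values use the add-one correction, with ties counted as as-extreme
(conservative); two-sided p is twice the smaller tail, capped at 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_STATISTICS = ("cov", "max", "min")


class DegenerateDataError(ValueError):
    """Input counts carry no variation, so the test statistic is undefined."""


@dataclass
class RandomizationResult:
    """Observed statistic vs Monte-Carlo null distribution."""

    statistic_label: str  # pairwise_slope | cov | max_initiations | min_initiations
    observed: float
    null_mean: float
    null_ci95: tuple[float, float]
    p_value: float
    n_iterations: int
    seed: int
    stratification: str
    n_groups: int
    n_redrawn: int = 0
    null_values: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self, include_null: bool = False) -> dict:
        d = asdict(self)
        null = d.pop("null_values")
        d["null_ci95"] = list(d["null_ci95"])
        if include_null and null is not None:
            d["null_values"] = np.asarray(null).tolist()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(**kwargs), indent=2)


def empirical_p(null_values, observed: float, tail: str = "two_sided") -> float:
    """Add-one corrected empirical p-value of ``observed`` against a null sample.

    lower: P(null <= observed); upper: P(null >= observed);
    two_sided: min(1, 2 * min(lower, upper)). Ties count as as-extreme.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empirical_p needs at least one null value")
    n = null.size
    p_lower = (1 + np.sum(null <= observed)) / (1 + n)
    p_upper = (1 + np.sum(null >= observed)) / (1 + n)
    if tail == "lower":
        return float(p_lower)
    if tail == "upper":
        return float(p_upper)
    if tail == "two_sided":
        return float(min(1.0, 2.0 * min(p_lower, p_upper)))
    raise ValueError("tail must be lower, upper or two_sided")


def _groups_from_table(counts: pd.DataFrame, value_col: str) -> list[np.ndarray]:
    return [
        sub[value_col].to_numpy(dtype=float)
        for _, sub in counts.groupby("trial_id", observed=True, sort=True)
    ]


def pairwise_slope_test(
    counts: pd.DataFrame | list,
    n_iterations: int = 10_000,
    seed: int = 0,
    value_col: str = "n_initiations",
    max_redraw_rounds: int = 1000,
) -> RandomizationResult:
    """Random fish-1/fish-2 labelling slope test for within-group interaction.

    ``counts`` is either a fish-level table with ``trial_id`` and
    ``value_col`` columns or a list of per-group count arrays (each length
    >= 2). Iterations whose fish-1 counts are all identical (undefined OLS
    slope) are redrawn; their number is reported in ``n_redrawn``.

    The p-value is the two-sided add-one empirical proportion of iteration
    slopes on the opposite side of zero (twice the smaller sign proportion).
    """
    groups = counts if isinstance(counts, list) else _groups_from_table(counts, value_col)
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("pairwise_slope_test needs at least 3 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 fish")
    if all(np.ptp(g) == 0 for g in groups):
        raise DegenerateDataError(
            "all groups have identical within-group counts; the slope is undefined"
        )

    rng = np.random.default_rng(seed)
    n_groups = len(groups)
    slopes = np.full(n_iterations, np.nan)
    pending = np.arange(n_iterations)
    n_redrawn = 0
    rounds = 0
    while pending.size and rounds < max_redraw_rounds:
        m = pending.size
        x = np.empty((m, n_groups))
        y = np.empty((m, n_groups))
        for g, vals in enumerate(groups):
            k = len(vals)
            i = rng.integers(0, k, size=m)
            j = rng.integers(0, k - 1, size=m)
            j = j + (j >= i)
            x[:, g] = vals[i]
            y[:, g] = vals[j]
        xc = x - x.mean(axis=1, keepdims=True)
        sxx = np.sum(xc * xc, axis=1)
        ok = sxx > 0
        slope = np.full(m, np.nan)
        slope[ok] = np.sum(xc[ok] * (y[ok] - y[ok].mean(axis=1, keepdims=True)), axis=1) / sxx[ok]
        slopes[pending[ok]] = slope[ok]
        pending = pending[~ok]
        n_redrawn += int((~ok).sum())
        rounds += 1
    if pending.size:
        raise DegenerateDataError(
            f"{pending.size} iterations remained degenerate after {max_redraw_rounds} redraw rounds"
        )

    observed = float(slopes.mean())
    p = empirical_p(slopes, 0.0, tail="two_sided")
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return RandomizationResult(
        statistic_label="pairwise_slope",
        observed=observed,
        null_mean=float(slopes.mean()),
        null_ci95=(float(lo), float(hi)),
        p_value=p,
        n_iterations=n_iterations,
        seed=seed,
        stratification="per-group fish-1/fish-2 relabelling",
        n_groups=n_groups,
        n_redrawn=n_redrawn,
        null_values=slopes,
    )


def _stat_over_groups(values: np.ndarray, statistic: str) -> np.ndarray:
    """Per-group statistic over the last axis of (..., n_groups, group_size)."""
    if statistic == "cov":
        m = values.mean(axis=-1)
        sd = values.std(axis=-1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(m > 0, sd / np.where(m == 0, 1.0, m), np.nan)
        return out
    if statistic == "max":
        return values.max(axis=-1)
    if statistic == "min":
        return values.min(axis=-1)
    raise ValueError(f"statistic must be one of {GROUP_STATISTICS}")


def membership_shuffle_test(
    counts: pd.DataFrame,
    statistic: str = "cov",
    n_iterations: int = 10_000,
    seed: int = 0,
    value_col: str = "n_initiations",
    strata_cols: tuple[str, ...] = ("predation", "group_size"),
) -> RandomizationResult:
    """Compare a group statistic's observed mean against random group membership.

    ``counts`` is a fish-level table with ``trial_id``, ``value_col`` and the
    stratum columns. Each iteration permutes individuals' observed counts
    among groups within every stratum (preserving group sizes), recomputes the
    per-group statistic and records the mean over groups. Strata with a single
    group cannot be shuffled and are excluded with a warning. Groups with an
    undefined statistic (COV of all-zero counts) are excluded from the mean,
    both observed and in every null iteration.
    """
    if statistic not in GROUP_STATISTICS:
        raise ValueError(f"statistic must be one of {GROUP_STATISTICS}")
    missing = [c for c in (*strata_cols, "trial_id", value_col) if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table is missing columns: {missing}")

    rng = np.random.default_rng(seed)
    strata_values: list[np.ndarray] = []  # (n_groups_s, size_s) observed layout
    n_groups = 0
    for key, stratum in counts.groupby(list(strata_cols), observed=True, sort=True):
        sizes = stratum.groupby("trial_id", observed=True).size()
        if sizes.nunique() != 1:
            raise ValueError(f"stratum {key}: groups have unequal sizes {sizes.unique()}")
        if len(sizes) < 2:
            logger.warning("stratum %s has a single group; excluded from shuffle", key)
            continue
        mat = (
            stratum.sort_values(["trial_id"], kind="stable")[value_col]
            .to_numpy(dtype=float)
            .reshape(len(sizes), int(sizes.iloc[0]))
        )
        strata_values.append(mat)
        n_groups += len(sizes)
    if not strata_values:
        raise ValueError("no stratum with >= 2 groups; nothing to shuffle")

    observed_stats = np.concatenate([_stat_over_groups(m, statistic) for m in strata_values])
    observed = float(np.nanmean(observed_stats))

    null_parts = []
    for mat in strata_values:
        n_g, size = mat.shape
        flat = np.broadcast_to(mat.reshape(-1), (n_iterations, n_g * size)).copy()
        rng.permuted(flat, axis=1, out=flat)
        null_parts.append(_stat_over_groups(flat.reshape(n_iterations, n_g, size), statistic))
    all_stats = np.concatenate(null_parts, axis=1)  # (n_iterations, n_groups)
    with np.errstate(all="ignore"):
        null_means = np.nanmean(all_stats, axis=1)

    label = {"cov": "cov", "max": "max_initiations", "min": "min_initiations"}[statistic]
    lo, hi = np.percentile(null_means, [2.5, 97.5])
    return RandomizationResult(
        statistic_label=label,
        observed=observed,
        null_mean=float(null_means.mean()),
        null_ci95=(float(lo), float(hi)),
        p_value=empirical_p(null_means, observed, tail="two_sided"),
        n_iterations=n_iterations,
        seed=seed,
        stratification=" x ".join(strata_cols),
        n_groups=n_groups,
        null_values=null_means,
    )


def results_to_frame(results: list[RandomizationResult]) -> pd.DataFrame:
    """One row per test: label, observed, null mean/CI, p, bookkeeping."""
    rows = []
    for r in results:
        d = r.to_dict()
        d["null_ci95_lo"], d["null_ci95_hi"] = d.pop("null_ci95")
        rows.append(d)
    return pd.DataFrame(rows)


def plot_randomization_results(results: list[RandomizationResult], ax=None):
    """Observed mean (asterisk) vs null mean with 95% CI error bars per test."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.2 * len(results), 4))
    for i, r in enumerate(results):
        lo, hi = r.null_ci95
        ax.errorbar(
            [i],
            [r.null_mean],
            yerr=[[r.null_mean - lo], [hi - r.null_mean]],
            fmt="s",
            color="black",
            capsize=4,
        )
        ax.plot([i], [r.observed], marker="*", markersize=14, color="red", linestyle="none")
    ax.set_xticks(range(len(results)))
    ax.set_xticklabels([r.statistic_label for r in results], rotation=30, ha="right")
    ax.set_ylabel("group statistic (mean over groups)")
    return ax
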