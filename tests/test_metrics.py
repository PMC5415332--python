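"""Per-fish and per-group summary statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from shoalmaze import (
    extract_transitions,
    group_cohesion,
    group_cov,
    latency_analysis,
    open_arena_measures,
    per_arm_balance,
    per_fish_counts,
    split_half_consistency,
    standardize_body_length,
)

from conftest import make_metadata, occupancy_from_raw, trajectories_from_path
from oracles import cov as oracle_cov, spearman as oracle_spearman, tally_counts


def test_per_fish_counts_direct_tally(geometry):
    raw = np.array(
        [
            [1, 2, 2, 3, 3, 2, 2],  # f1: init(2), init(3), follow-or-init back to 2
            [1, 1, 2, 2, 2, 2, 2],  # f2: follow into 2
        ],
        dtype=np.int8,
    )
    md = make_metadata(2, analysis_start=0.0)
    log = extract_transitions(occupancy_from_raw(raw, geometry, md))
    counts = per_fish_counts(log).set_index("fish_id")
    assert counts.loc["f1", "n_initiations"] == 2  # arm 3 empty; arm 2 holds f2 on return
    assert counts.loc["f1", "n_follows"] == 1
    assert counts.loc["f2", "n_follows"] == 1
    assert (counts["n_total"] == counts["n_initiations"] + counts["n_follows"]).all()


def test_per_fish_counts_zero_for_absent_fish(geometry):
    raw = np.ones((4, 60), dtype=np.int8)
    md = make_metadata(4, analysis_start=0.0)
    log = extract_transitions(occupancy_from_raw(raw, geometry, md))
    counts = per_fish_counts(log)
    assert len(counts) == 4
    assert (counts[["n_initiations", "n_follows", "n_total"]].to_numpy() == 0).all()


def test_per_fish_counts_match_brute_force_tally(geometry):
    rng = np.random.default_rng(40)
    for _ in range(100):
        raw = rng.integers(0, 4, size=(4, 120)).astype(np.int8)
        md = make_metadata(4, analysis_start=0.0, trial_end=120 / geometry.fps)
        log = extract_transitions(occupancy_from_raw(raw, geometry, md))
        counts = per_fish_counts(log).set_index("fish_id")
        tal = tally_counts(log.events.to_dict(orient="records"), md.fish_ids)
        for fid in md.fish_ids:
            assert counts.loc[fid, "n_initiations"] == tal[fid]["initiation"]
            assert counts.loc[fid, "n_follows"] == tal[fid]["follow"]


def test_group_cov_worked_examples():
    assert group_cov([2, 0]) == pytest.approx(math.sqrt(2))
    assert group_cov([3, 3, 3, 3]) == 0.0
    assert math.isnan(group_cov([0, 0]))  # zero mean: flagged missing
    with pytest.raises(ValueError):
        group_cov([5])


def test_group_cov_matches_direct_formula_and_scale_invariance():
    rng = np.random.default_rng(9)
    for _ in range(50):
        x = rng.integers(0, 20, size=rng.integers(2, 6))
        if x.mean() == 0:
            continue
        assert group_cov(x) == pytest.approx(oracle_cov(x))
        assert group_cov(x * 7) == pytest.approx(group_cov(x))  # scale invariant


def test_cohesion_bounds_and_split(geometry):
    md = make_metadata(2, analysis_start=0.0)
    together = np.ones((2, 100), dtype=np.int8)
    assert group_cohesion(occupancy_from_raw(together, geometry, md))["mean_cohesion"] == 1.0

    md4 = make_metadata(4, analysis_start=0.0)
    split22 = np.vstack([np.ones((2, 100)), np.full((2, 100), 2)]).astype(np.int8)
    res = group_cohesion(occupancy_from_raw(split22, geometry, md4))
    assert res["mean_cohesion"] == pytest.approx(1 / 3)


def test_pair_cohesion_equals_fraction_of_frames_together(geometry):
    """150 s together out of a 270 s analysed window -> 150/270."""
    fps = geometry.fps
    n_frames = int(300 * fps)
    md = make_metadata(2)  # window 30..300 s -> 6750 analysed frames
    raw = np.ones((2, n_frames), dtype=np.int8)
    analyzed_start = int(30 * fps)
    # fish 2 sits in arm 2 for the last 120 s of the window (3000 frames)
    raw[1, analyzed_start + 3750 :] = 2
    res = group_cohesion(occupancy_from_raw(raw, geometry, md))
    assert res["mean_cohesion"] == pytest.approx(150 / 270, abs=1e-6)
    assert res["asin_sqrt_cohesion"] == pytest.approx(math.asin(math.sqrt(150 / 270)))


def test_cohesion_rejects_single_fish(geometry):
    md = make_metadata(1, analysis_start=0.0)
    raw = np.ones((1, 10), dtype=np.int8)
    with pytest.raises(ValueError):
        group_cohesion(occupancy_from_raw(raw, geometry, md))


def test_open_arena_measures_trivial_cases(geometry):
    md = make_metadata(2, analysis_start=0.0)
    a = np.tile([0.0, 20.0], (50, 1))  # stationary in arm 1
    b = np.tile([5.0, 20.0], (50, 1))  # 5 cm away, also stationary
    tt = trajectories_from_path([a, b], geometry, md)
    res = open_arena_measures(tt)
    assert res["mean_speed_cm_s"] == 0.0
    assert res["mean_nearest_neighbor_distance_cm"] == pytest.approx(5.0)
    assert res["mean_neighbor_distance_cm"] == pytest.approx(5.0)


def test_open_arena_measures_match_brute_force(geometry):
    rng = np.random.default_rng(31)
    md = make_metadata(3, analysis_start=0.0, trial_end=10.0)
    pts = [np.cumsum(rng.normal(0, 0.05, size=(40, 2)), axis=0) for _ in range(3)]
    tt = trajectories_from_path(pts, geometry, md)
    res = open_arena_measures(tt)
    # brute force per-frame recomputation
    speeds = []
    for p in pts:
        d = np.linalg.norm(np.diff(p, axis=0), axis=1) * geometry.fps
        speeds.append(d.mean())
    assert res["mean_speed_cm_s"] == pytest.approx(np.mean(speeds))
    nnd, mnd = [], []
    for t in range(40):
        for i in range(3):
            ds = [np.linalg.norm(pts[i][t] - pts[j][t]) for j in range(3) if j != i]
            nnd.append(min(ds))
            mnd.append(np.mean(ds))
    assert res["mean_nearest_neighbor_distance_cm"] == pytest.approx(np.mean(nnd))
    assert res["mean_neighbor_distance_cm"] == pytest.approx(np.mean(mnd))


def test_split_half_consistency_examples_and_oracle():
    df = pd.DataFrame(
        {
            "predation": ["low"] * 4 + ["high"] * 4,
            "n_init_first_half": [0, 1, 2, 3, 0, 1, 2, 3],
            "n_init_second_half": [0, 1, 2, 3, 3, 2, 1, 0],
        }
    )
    res = split_half_consistency(df).set_index("predation")
    assert res.loc["low", "spearman_r"] == pytest.approx(1.0)
    assert res.loc["high", "spearman_r"] == pytest.approx(-1.0)

    rng = np.random.default_rng(13)
    x = rng.integers(0, 5, size=30)
    y = rng.integers(0, 5, size=30)
    df2 = pd.DataFrame(
        {"predation": "medium", "n_init_first_half": x, "n_init_second_half": y}
    )
    got = split_half_consistency(df2)["spearman_r"].iloc[0]
    assert got == pytest.approx(oracle_spearman(x, y))


def test_split_half_consistency_constant_vector_flagged():
    df = pd.DataFrame(
        {"predation": "low", "n_init_first_half": [2, 2, 2], "n_init_second_half": [0, 1, 2]}
    )
    assert math.isnan(split_half_consistency(df)["spearman_r"].iloc[0])


def test_standardize_body_length():
    out = standardize_body_length([2.0, 4.0], ["female", "female"])
    np.testing.assert_allclose(out, [-1 / math.sqrt(2), 1 / math.sqrt(2)])
    # degenerate: identical lengths -> flagged NaN
    out = standardize_body_length([3.0, 3.0], ["male", "male"])
    assert np.isnan(out).all()
    # singleton sex -> NaN for that fish
    out = standardize_body_length([3.0, 2.0, 4.0], ["male", "female", "female"])
    assert math.isnan(out[0]) and not np.isnan(out[1:]).any()
    # property: mean 0, sample SD 1 within each sex
    rng = np.random.default_rng(3)
    lengths = rng.uniform(2, 5, size=40)
    sexes = np.where(rng.random(40) < 0.5, "female", "male")
    z = standardize_body_length(lengths, sexes)
    for s in ("female", "male"):
        zs = z[sexes == s]
        assert zs.mean() == pytest.approx(0.0, abs=1e-12)
        assert zs.std(ddof=1) == pytest.approx(1.0)


def test_per_arm_balance_tally():
    ev = pd.DataFrame(
        {
            "predation": "low",
            "to_arm": [1, 2, 3, 1],
            "kind": "initiation",
        }
    )
    out = per_arm_balance(ev)
    got = out.set_index("to_arm")["n_events"]
    assert got.loc[1] == 2 and got.loc[2] == 1 and got.loc[3] == 1
    assert per_arm_balance(pd.DataFrame(columns=["to_arm", "kind"])).empty


def test_latency_analysis_exclusion_bookkeeping():
    """406 unfollowed of 1884 initiations -> 21.5% excluded from latency analysis."""
    n, k = 1884, 406
    ev = pd.DataFrame(
        {
            "kind": "initiation",
            "followed": [False] * k + [True] * (n - k),
            "latency_to_first_follow_s": [np.nan] * k + [1.0] * (n - k),
        }
    )
    res = latency_analysis(ev)
    assert res["n_initiations"] == n
    assert res["n_unfollowed"] == k
    assert res["excluded_pct"] == 21.5
    assert len(res["table"]) == n - k
    assert "log10_latency" in res["table"].columns
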