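"""Agent-based simulator of small shoals exploring a three-armed maze.

The generator stands in for undeposited experimental data: it produces
trajectory and metadata tables in the exact I/O schema, together with the
generative ground truth, so the full analysis pipeline can be exercised and
validated end to end.

Behavioural model (event-driven, continuous time, rendered to video frames):

* Each fish i has a baseline initiation propensity λ_i (events/s) drawn from
  a gamma distribution; heterogeneity across fish is controlled by the gamma
  shape (CV = 1/sqrt(shape)).
* A fish's initiation clock fires after an exponential waiting time at its
  current propensity; it then swims to one of the two other arms (uniform
  choice, matching the near-equal arm use seen in this kind of assay).
* When a fish arrives in an empty arm (an initiation), every groupmate not in
  transit independently follows with probability ``p_follow`` after an
  exponential latency with mean ``tau_follow``; non-followers stay put.
  Exponential latencies plus transit time give the positively skewed observed
  follow-latency distribution.
* Social feedback: the first time an initiation is followed, the initiator's
  propensity is multiplied by (1 + beta_feedback), every groupmate's is
  divided by the same factor, and the rates are rescaled so the group's total
  propensity is conserved — winner reinforcement that redistributes the
  tendency to initiate toward successful initiators, differentiating the
  group into leader and follower roles without runaway rates.
  ``beta_feedback = 0`` disables feedback, making per-fish counts
  exchangeable across groups.
* Movements are rendered at ``fps`` along arm centre-lines at
  ``movement_speed`` with small lateral jitter; jitter is suppressed whenever
  it would move a point across a region boundary, so the rendered trajectory
  crosses region borders exactly where the continuous-time model says it
  does. Tracker identity uncertainty is drawn per track segment from a beta
  distribution.

Fish rest a few cm inside the current arm between movements, near the
decision zone where the arms meet.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import MazeGeometry, points_to_regions
from .io import TrialMetadata, TrialTrajectories

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSpec:
    """One simulated trial's design cell."""

    trial_id: str
    predation: str
    sex: str
    group_size: int
    river: str = ""


@dataclass(frozen=True)
class StratumSpec:
    """A block of identically configured groups."""

    predation: str
    n_groups: int
    group_size: int
    sex: str

    def __post_init__(self) -> None:
        if self.group_size not in (2, 4):
            raise ValueError("group_size must be 2 or 4")
        if self.n_groups < 0:
            raise ValueError("n_groups must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Simulator configuration.

    ``lambda_shape`` and ``lambda_rate`` parameterize the gamma distribution
    of baseline initiation propensities: λ_i ~ Gamma(shape, scale=1/rate), in
    events/s. The defaults (shape 2, rate 80 s) give mean λ = 0.025 /s with
    CV = 1/sqrt(2) ≈ 0.71, which under the default follow parameters yields
    roughly 15 movements per fish over a 5-minute trial in groups of four.
    """

    strata: tuple[StratumSpec, ...] = ()
    trial_duration: float = 300.0
    analysis_start: float = 30.0
    fps: float = 25.0
    lambda_shape: float = 2.0
    lambda_rate: float = 80.0  # seconds; scale = 1/rate (per-second propensity)
    p_follow: float = 0.8
    tau_follow: float = 0.8  # s, mean exponential follow latency
    beta_feedback: float = 0.0
    uncertainty_beta_params: tuple[float, float] = (1.0, 19.0)
    movement_speed: float = 10.0  # cm/s
    rest_depth: float = 5.0  # cm into the arm where fish loiter
    jitter_sd: float = 0.25  # cm lateral jitter (AR(1)-smoothed)
    jitter_rho: float = 0.95
    segment_mean_s: float = 20.0  # mean tracker-segment duration
    body_length_mean: dict = field(
        default_factory=lambda: {"female": 4.0, "male": 2.5}
    )
    body_length_sd: float = 0.3

    def __post_init__(self) -> None:
        if min(self.trial_duration, self.fps, self.lambda_shape, self.lambda_rate) <= 0:
            raise ValueError("durations and gamma hyper-parameters must be > 0")
        if not (0.0 <= self.p_follow <= 1.0):
            raise ValueError("p_follow must lie in [0, 1]")
        if self.tau_follow < 0 or self.beta_feedback < 0:
            raise ValueError("tau_follow and beta_feedback must be >= 0")
        if self.movement_speed <= 0 or self.rest_depth <= 0:
            raise ValueError("movement_speed and rest_depth must be > 0")
        if not (0 <= self.analysis_start < self.trial_duration):
            raise ValueError("need 0 <= analysis_start < trial_duration")

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimConfig":
        cfg = dict(cfg)
        strata = tuple(StratumSpec(**s) for s in cfg.pop("strata", []))
        if "uncertainty_beta_params" in cfg:
            cfg["uncertainty_beta_params"] = tuple(cfg["uncertainty_beta_params"])
        return cls(strata=strata, **cfg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strata"] = [asdict(s) for s in self.strata]
        return d


@dataclass
class GroundTruth:
    """Generative record for one simulated trial.

    ``events`` has one row per arm arrival with the decision time, arrival
    (boundary-crossing) time, arrival frame and the generative kind — the
    occupancy-based initiation/follow taxonomy evaluated at the arrival.
    ``counts`` tallies the events inside the analysis window, which must
    reconcile exactly with the pipeline's extraction from the rendered
    trajectories.
    """

    trial_id: str
    baseline_lambda: dict[str, float]
    final_lambda: dict[str, float]
    events: pd.DataFrame  # fish_id, t_decision, t_arrival, frame, time_s, from_arm, to_arm, kind, followed
    counts: pd.DataFrame  # fish_id, n_initiations, n_follows, n_total
    group: GroupSpec | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "trial_id": self.trial_id,
                "baseline_lambda": self.baseline_lambda,
                "final_lambda": self.final_lambda,
                "events": self.events.to_dict(orient="records"),
                "counts": self.counts.to_dict(orient="records"),
            },
            indent=2,
        )


def default_geometry(px_per_cm: float = 12.0) -> MazeGeometry:
    """Maze geometry used by the simulator (calibration is arbitrary but fixed)."""
    return MazeGeometry(px_per_cm=px_per_cm)


# ---------------------------------------------------------------------------
# event engine
# ---------------------------------------------------------------------------


def _transit_lengths(geometry: MazeGeometry, rest_depth: float, lateral: float) -> dict:
    """Path lengths: rest -> own-arm mouth, mouth -> other-arm mouth, mouth -> rest."""
    mouths = {k: geometry.edge_midpoint(k) + lateral * geometry.arm_perps[k - 1] for k in (1, 2, 3)}
    center = {
        (a, b): float(np.linalg.norm(mouths[a] - mouths[b]))
        for a in (1, 2, 3)
        for b in (1, 2, 3)
        if a != b
    }
    return {"out": rest_depth, "center": center, "in": rest_depth}


def _simulate_events(
    config: SimConfig, group_size: int, rng: np.random.Generator, geometry: MazeGeometry
):
    """Run the continuous-time engine; returns per-fish moves and propensities."""
    n = group_size
    lam0 = rng.gamma(config.lambda_shape, 1.0 / config.lambda_rate, size=n)
    lam = lam0.copy()
    # lateral lane per fish keeps rendered paths distinct; |offset| <= 2 cm
    lateral = np.linspace(-2.0, 2.0, n) if n > 1 else np.zeros(1)
    lengths = [_transit_lengths(geometry, config.rest_depth, lateral[i]) for i in range(n)]
    speed = config.movement_speed

    arm = np.full(n, geometry.start_arm, dtype=int)
    busy_until = np.zeros(n)  # time the fish reaches its rest point
    in_transit = np.zeros(n, dtype=bool)
    arrival_at = np.full(n, np.inf)  # boundary-crossing time of current move
    move_target = np.zeros(n, dtype=int)
    move_decided = np.zeros(n)
    next_init = rng.exponential(1.0 / lam)
    pending_follow = np.full(n, np.inf)  # scheduled follow decision time
    follow_target = np.zeros(n, dtype=int)

    open_init = {}  # fish -> dict(arm=..., followed=bool) for its live initiation
    moves: list[dict] = []
    T = config.trial_duration

    def start_move(i: int, t: float, target: int) -> None:
        li = lengths[i]
        t_arr = t + (li["out"] + li["center"][(arm[i], target)]) / speed
        busy_until[i] = t_arr + li["in"] / speed
        arrival_at[i] = t_arr
        move_target[i] = target
        move_decided[i] = t
        in_transit[i] = True
        pending_follow[i] = np.inf
        next_init[i] = np.inf

    while True:
        cand = np.minimum(np.where(in_transit, arrival_at, np.inf),
                          np.minimum(np.where(~in_transit, next_init, np.inf),
                                     np.where(~in_transit, pending_follow, np.inf)))
        i = int(np.argmin(cand))
        t = float(cand[i])
        if not np.isfinite(t) or t > T:
            break

        if in_transit[i] and arrival_at[i] == t:
            # arrival: the fish crosses into the target arm
            target = int(move_target[i])
            occupants = int(np.sum(arm == target)) - (1 if arm[i] == target else 0)
            # close the fish's own open initiation: it has now left that arm
            open_init.pop(i, None)
            prev = int(arm[i])
            arm[i] = target
            kind = "initiation" if occupants == 0 else "follow"
            moves.append(
                {
                    "fish": i,
                    "t_decision": move_decided[i],
                    "t_arrival": t,
                    "from_arm": prev,
                    "to_arm": target,
                    "kind": kind,
                    "followed": False,
                }
            )
            in_transit[i] = False
            arrival_at[i] = np.inf
            t_free = float(busy_until[i])
            next_init[i] = t_free + rng.exponential(1.0 / lam[i])

            if kind == "initiation":
                open_init[i] = {"arm": target, "move_idx": len(moves) - 1}
                for j in range(n):
                    if j == i or in_transit[j]:
                        continue
                    if rng.random() < config.p_follow:
                        pending_follow[j] = t + (
                            rng.exponential(config.tau_follow) if config.tau_follow > 0 else 0.0
                        )
                        follow_target[j] = target
            else:
                # first follower of a live initiation triggers feedback
                for leader, info in list(open_init.items()):
                    if info["arm"] == target and leader != i:
                        if not moves[info["move_idx"]]["followed"]:
                            moves[info["move_idx"]]["followed"] = True
                            if config.beta_feedback > 0:
                                f = 1.0 + config.beta_feedback
                                total = lam.sum()
                                for g in range(n):
                                    lam[g] = lam[g] * f if g == leader else lam[g] / f
                                # redistribute rather than amplify: conserve the
                                # group's total propensity so feedback shifts
                                # shares toward successful initiators without
                                # runaway rates
                                lam *= total / lam.sum()
                                # propensities changed: resample free fishes'
                                # clocks (exponential memorylessness makes this
                                # the piecewise-constant-rate process)
                                for g in range(n):
                                    if not in_transit[g]:
                                        base = max(t, busy_until[g])
                                        next_init[g] = base + rng.exponential(1.0 / lam[g])
            continue

        # decision events (fish is free)
        if pending_follow[i] == t:
            target = int(follow_target[i])
            pending_follow[i] = np.inf
            if target != arm[i]:
                start_move(i, t, target)
            continue
        if next_init[i] == t:
            others = [a for a in (1, 2, 3) if a != arm[i]]
            target = int(rng.choice(others))
            start_move(i, t, target)
            continue
        raise AssertionError("unreachable event state")  # pragma: no cover

    return moves, lam0, lam, lateral, lengths


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_fish(
    fish_moves: list[dict],
    lateral: float,
    lengths: dict,
    config: SimConfig,
    geometry: MazeGeometry,
    frame_times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-linear path through the move waypoints, sampled at frames."""
    speed = config.movement_speed

    def rest_point(a: int) -> np.ndarray:
        return (
            geometry.edge_midpoint(a)
            + config.rest_depth * geometry.arm_axes[a - 1]
            + lateral * geometry.arm_perps[a - 1]
        )

    def mouth(a: int) -> np.ndarray:
        return geometry.edge_midpoint(a) + lateral * geometry.arm_perps[a - 1]

    key_t = [0.0]
    key_xy = [rest_point(geometry.start_arm)]
    for mv in fish_moves:
        a, b = int(mv["from_arm"]), int(mv["to_arm"])
        t0 = float(mv["t_decision"])
        t_out = t0 + lengths["out"] / speed
        t_arr = float(mv["t_arrival"])
        t_rest = t_arr + lengths["in"] / speed
        key_t.extend([t0, t_out, t_arr, t_rest])
        key_xy.extend([rest_point(a), mouth(a), mouth(b), rest_point(b)])
    key_t = np.asarray(key_t)
    key_xy = np.asarray(key_xy)
    x = np.interp(frame_times, key_t, key_xy[:, 0])
    y = np.interp(frame_times, key_t, key_xy[:, 1])
    path = np.column_stack([x, y])

    if config.jitter_sd > 0:
        # AR(1)-smoothed lateral wiggle, suppressed where it would cross a
        # region border so rendered crossings match the event engine exactly
        n = len(frame_times)
        innov_sd = config.jitter_sd * np.sqrt(1 - config.jitter_rho**2)
        noise = np.empty(n)
        noise[0] = rng.normal(0, config.jitter_sd)
        eps = rng.normal(0, innov_sd, size=n - 1)
        for k in range(1, n):
            noise[k] = config.jitter_rho * noise[k - 1] + eps[k - 1]
        # inside an arm, jitter exactly perpendicular to the arm axis so the
        # axial entry depth (the same-frame tie-break) is untouched; in the
        # center, perpendicular to the local heading
        base_region = points_to_regions(path, geometry, on_outside="code")
        heading = np.gradient(path, axis=0)
        norms = np.linalg.norm(heading, axis=1, keepdims=True)
        heading = np.divide(heading, norms, out=np.tile([[0.0, 1.0]], (n, 1)), where=norms > 1e-12)
        perp = np.column_stack([-heading[:, 1], heading[:, 0]])
        for k in (1, 2, 3):
            in_arm = base_region == k
            if in_arm.any():
                perp[in_arm] = geometry.arm_perps[k - 1]
        jittered = path + noise[:, None] * perp
        jit_region = points_to_regions(jittered, geometry, on_outside="code")
        keep = jit_region == base_region
        path = np.where(keep[:, None], jittered, path)
    return path


def _segment_uncertainty(
    n_frames: int, fps: float, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame identity uncertainty, constant within tracker segments."""
    a, b = config.uncertainty_beta_params
    out = np.empty(n_frames)
    k = 0
    while k < n_frames:
        seg = max(1, int(round(rng.exponential(config.segment_mean_s) * fps)))
        out[k : k + seg] = rng.beta(a, b)
        k += seg
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_trial(
    config: SimConfig,
    group_spec: GroupSpec,
    seed: int | np.random.SeedSequence,
    geometry: MazeGeometry | None = None,
    render: bool = True,
) -> tuple[TrialTrajectories | None, GroundTruth]:
    """Simulate one trial; optionally render 25-fps trajectories.

    With ``render=False`` only the generative ground truth is produced (much
    faster; used for large simulation studies on counts). Ground-truth kinds
    are evaluated at frame resolution so they reconcile exactly with event
    extraction from the rendered tables.
    """
    geometry = geometry or default_geometry()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = group_spec.group_size

    moves, lam0, lam_final, lateral, lengths = _simulate_events(config, n, rng, geometry)

    n_frames = int(round(config.trial_duration * config.fps))
    frame_times = np.arange(n_frames) / config.fps
    fish_ids = [f"f{i+1}" for i in range(n)]

    # ground truth at frame resolution: arrival frame = first frame at or
    # after the boundary crossing; moves arriving beyond the last frame are
    # never rendered inside the video and are dropped
    gt_rows = []
    for mv in moves:
        fr = int(np.ceil(mv["t_arrival"] * config.fps - 1e-9))
        if fr >= n_frames:
            continue
        gt_rows.append(
            {
                "fish_id": fish_ids[mv["fish"]],
                "t_decision": mv["t_decision"],
                "t_arrival": mv["t_arrival"],
                "frame": fr,
                "time_s": fr / config.fps,
                "from_arm": mv["from_arm"],
                "to_arm": mv["to_arm"],
                "kind": mv["kind"],
                "followed": mv["followed"],
            }
        )
    gt_events = pd.DataFrame(
        gt_rows,
        columns=[
            "fish_id", "t_decision", "t_arrival", "frame", "time_s",
            "from_arm", "to_arm", "kind", "followed",
        ],
    )
    in_window = gt_events["time_s"].between(config.analysis_start, config.trial_duration)
    windowed = gt_events[in_window]
    counts = []
    for fid in fish_ids:
        sub = windowed[windowed["fish_id"] == fid]
        ni = int((sub["kind"] == "initiation").sum())
        nf = int((sub["kind"] == "follow").sum())
        counts.append({"fish_id": fid, "n_initiations": ni, "n_follows": nf, "n_total": ni + nf})
    ground_truth = GroundTruth(
        trial_id=group_spec.trial_id,
        baseline_lambda={f: float(v) for f, v in zip(fish_ids, lam0)},
        final_lambda={f: float(v) for f, v in zip(fish_ids, lam_final)},
        events=gt_events,
        counts=pd.DataFrame(counts),
        group=group_spec,
    )

    sexes = group_spec.sex
    bl_mean = config.body_length_mean.get(sexes, 3.0)
    body_lengths = {
        fid: float(max(1.0, rng.normal(bl_mean, config.body_length_sd))) for fid in fish_ids
    }
    metadata = TrialMetadata(
        trial_id=group_spec.trial_id,
        river=group_spec.river or f"{group_spec.predation}_river",
        predation=group_spec.predation,
        sex=group_spec.sex,
        group_size=n,
        body_lengths=body_lengths,
        analysis_start=config.analysis_start,
        trial_end=config.trial_duration,
    )

    if not render:
        return None, ground_truth

    xy = np.empty((n, n_frames, 2))
    uncertainty = np.empty((n, n_frames))
    for i, fid in enumerate(fish_ids):
        fish_moves = [m for m in moves if m["fish"] == i]
        xy[i] = _render_fish(
            fish_moves, float(lateral[i]), lengths[i], config, geometry, frame_times, rng
        )
        uncertainty[i] = _segment_uncertainty(n_frames, config.fps, config, rng)

    trajectories = TrialTrajectories(
        metadata=metadata,
        geometry=geometry,
        fish_ids=fish_ids,
        frames=np.arange(n_frames, dtype=np.int64),
        times=frame_times,
        xy=xy,
        uncertainty=uncertainty,
    )
    return trajectories, ground_truth


def simulate_dataset(
    config: SimConfig,
    seed: int,
    geometry: MazeGeometry | None = None,
    render: bool = True,
) -> tuple[list[TrialTrajectories], list[GroundTruth]]:
    """Simulate every stratum of ``config``; deterministic given ``seed``."""
    geometry = geometry or default_geometry()
    specs: list[GroupSpec] = []
    for s in config.strata:
        for g in range(s.n_groups):
            specs.append(
                GroupSpec(
                    trial_id=f"{s.predation}_{s.sex}_n{s.group_size}_{g:03d}",
                    predation=s.predation,
                    sex=s.sex,
                    group_size=s.group_size,
                )
            )
    child_seeds = np.random.SeedSequence(seed).spawn(len(specs))
    trials, truths = [], []
    for spec, ss in zip(specs, child_seeds):
        tr, gt = simulate_trial(config, spec, ss, geometry=geometry, render=render)
        if tr is not None:
            trials.append(tr)
        truths.append(gt)
    return trials, truths


def ground_truth_counts(truths: list[GroundTruth]) -> pd.DataFrame:
    """Tidy fish-level count table from generative ground truths.

    Same layout as the pipeline's per-fish counts (trial_id, fish_id,
    n_initiations, n_follows, plus design columns), ready for the
    randomization tests.
    """
    rows = []
    for gt in truths:
        c = gt.counts.copy()
        c.insert(0, "trial_id", gt.trial_id)
        if gt.group is not None:
            c["predation"] = gt.group.predation
            c["sex"] = gt.group.sex
            c["group_size"] = gt.group.group_size
        rows.append(c)
    if not rows:
        return pd.DataFrame(
            columns=["trial_id", "fish_id", "n_initiations", "n_follows", "n_total"]
        )
    return pd.concat(rows, ignore_index=True)


def study_design_config(**overrides) -> SimConfig:
    """Stratum table mirroring the original study design's scale.

    102 groups and 310 fish across three predation levels (84 / 108 / 118
    fish), two group sizes and both sexes.
    """
    strata = []
    plan = {  # predation -> (n_pairs, n_quads)
        "low": (14, 14),
        "medium": (18, 18),
        "high": (17, 21),
    }
    for predation, (n2, n4) in plan.items():
        for size, total in ((2, n2), (4, n4)):
            half = total // 2
            strata.append(StratumSpec(predation, half, size, "female"))
            strata.append(StratumSpec(predation, total - half, size, "male"))
    return SimConfig(strata=tuple(strata), **overrides)
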