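# Methods

This note documents the models and procedures implemented in `shoalmaze`,
the numerical and design choices that were genuinely open, and what the
synthetic data can and cannot show.

## Arena geometry and region classification

The arena is an equilateral central triangle (side 10 cm, default) with a
36.5 × 10 cm rectangular arm attached to each side. Coordinates are
maze-centred: the triangle's centroid is the origin, arm 1's axis points
along +y, arms are numbered counter-clockwise. Pixel positions are converted
to cm with an explicit `px_per_cm` calibration — it must be supplied in the
geometry config because it cannot be recovered from the maze dimensions.

Classification is direct coordinate algebra: a point is in arm *k* if its
axial coordinate along arm *k*'s axis lies in `[apothem, apothem + length]`
and its lateral coordinate within half the arm width; it is in the center if
its axial coordinate is at most the apothem along all three axes. Points on
a border belong to the arm, so a boundary touch counts as arm entry —
consistent with defining arm entry as leaving the central triangle. Points
outside every region (tracking noise) are snapped to the nearest region
within 0.5 cm (shapely distance); farther out is an error. Test code checks
this classifier against shapely's point-in-polygon as an independent oracle.

## Buffered occupancy

While in the central triangle a fish keeps the label of the arm it last
visited; its *buffered arm* changes only at the frame it enters a different
arm. The buffer rule is a forward-fill of arm codes over center frames,
initialised to the start arm (the arm holding the start compartment) for
fish that have not yet visited any arm. Occlusion gaps carry the buffered
arm forward; per-fish gap fractions are reported and a trial is flagged when
any fish exceeds 20% missing frames (configurable). Re-sampling idempotence
holds: duplicating frames cannot create transitions.

## Events

A transition is a buffered-arm change with entry time inside the analysed
window (default 30–300 s; the first 30 s are excluded because the arena view
is still changing after the start door is removed). Classification replays
entries in (frame, entry-depth descending, fish id) order: at equal swimming
speed, the fish deeper past the triangle side on the shared frame crossed
earlier, so depth is a monotone proxy for crossing time. Earlier entries
update occupancy before later same-frame entries are classified. When depth
is unavailable the fish-id order breaks the tie; this fallback is the one
place where relabelling fish can alter same-frame classification.

An initiation's follow window runs from its entry to the initiator's next
transition (its departure, in buffered terms); `followed` is true iff at
least one other fish enters the arm strictly within the window,
`latency_to_first_follow` is the first such entry time minus the initiation
time, and `n_followers` counts distinct entrants in the window. Initiations
whose initiator never leaves are censored at trial end and the window
truncates there. Fish entering after the initiator departed count as follows
in the per-fish taxonomy but not as followers of that initiation — the text
defining the unfollowed case fixes only one side of this boundary, so the
window rule is a documented package choice.

Uncertainty filtering removes every event whose per-segment identity
uncertainty exceeds the threshold; counts are recomputed from the filtered
log, but classifications are not revised (thresholding mimics a tracker
post-hoc filter that deletes suspect transitions). The default threshold is
1.0 (no filtering) with a sweep utility for 0.9 → 0.05.

## Metrics

* **COV** uses the sample (n−1) standard deviation: groups are small (2 or
  4 fish), where the unbiased form is conventional. Groups whose fish made
  no initiations at all have an undefined COV and are excluded from COV
  analyses (they carry no diversity information) rather than being scored 0.
* **Cohesion** is computed on buffered arms over the analysed window (the
  pre-30 s frames are excluded, consistent with all other measures); for
  pairs it equals the fraction of analysed frames spent in the same buffered
  arm. The arcsine-square-root transform is exported alongside.
* **Open-arena measures** (mean speed; nearest and mean neighbor distance)
  use raw positions, including center frames, because they validate the
  arm-based measures against what open-arena studies report. Gap frames are
  skipped in displacement computations.
* **Split halves** partition the analysed window at its midpoint (165 s for
  the default window); an initiation exactly at the midpoint counts in the
  second half. Consistency is the Spearman rank correlation of first- vs
  second-half initiation counts, pooled within predation level.
* **Body length** is standardized within sex as (x − mean)/sample SD; body
  size covaries with sex, so a pooled z-score would mostly encode sex. A
  variant dividing by SD/√n would differ only by a per-sex constant and not
  affect any rank-based or slope-sign conclusion.
* **Follow latencies** are exported log10-transformed; zero latencies
  (same-frame follows) are floored at half a frame interval (0.02 s) before
  the transform.

## Randomization tests

Both tests are purely empirical; no asymptotic p-values are computed.

* **Pairwise slope**: per iteration, two distinct fish are drawn uniformly
  without replacement from each group and labelled fish 1/fish 2; the OLS
  slope of fish-2 counts on fish-1 counts across groups is recorded;
  10,000 iterations by default. Iterations with zero fish-1 variance are
  redrawn and their count reported; inputs where every labelling is
  degenerate raise an error. The summary p-value is the two-sided add-one
  empirical proportion of iteration slopes on the opposite side of zero
  (twice the smaller sign proportion, capped at 1). The upstream analysis
  this replicates reports per-level p-values without defining their
  computation, so this definition is a documented package choice and a known
  divergence risk when comparing p-values directly.
* **Membership shuffle**: individuals' observed count records (not raw
  events) are permuted among groups within each predation-level × group-size
  stratum, preserving group sizes; group size affects initiation counts, so
  shuffling across sizes would confound the null. Strata with a single group
  cannot be shuffled and are excluded with a warning. The null distribution
  is the per-iteration mean of the group statistic; the 95% interval is the
  2.5/97.5 percentile band and the p-value the two-sided add-one tail
  probability of the observed mean (two-sided by default; the upstream
  presentation reports CI bands without fixing the tail convention).
* **Empirical p**: add-one corrected, ties count as as-extreme
  (conservative); two-sided = min(1, 2·min(lower, upper)).
* **Reproducibility**: one top-level seed; per-test streams are derived
  deterministically (`numpy` SeedSequence). Identical seeds give bit-identical
  results.

## The simulator

`simulate_trial` runs an event-driven continuous-time model per group:

* Baseline initiation propensities λᵢ ~ Gamma(shape 2, scale 1/80 s⁻¹):
  mean 0.025 events/s and CV = 1/√2 ≈ 0.71. With the default follow
  parameters this yields ≈ 14–15 movements per fish per 5-minute trial in
  4-fish groups, matching the per-fish activity scale this assay produces;
  the shape-2 choice puts substantial, but not degenerate, heterogeneity
  between fish.
* A free fish's initiation clock fires after Exp(1/λᵢ); it moves to one of
  the two other arms uniformly (arm use in this assay is near-balanced).
  Movement decisions, boundary crossings and settling are separated by the
  transit time at `movement_speed` (10 cm/s) from a resting point 5 cm
  inside the arm, near the decision zone; clocks are suppressed during
  transit and resampled on arrival (valid for piecewise-constant rates by
  memorylessness).
* On arrival into an empty arm (an initiation), each free groupmate follows
  with probability `p_follow` = 0.8 after Exp(`tau_follow` = 0.8 s) latency;
  fish already in transit miss the opportunity. Exponential latency plus
  transit gives the positively skewed observed latency distribution, with
  roughly three quarters of initiations followed within 2 s under defaults.
* **Social feedback** (`beta_feedback` ≥ 0, default 0): when an initiation
  receives its first follower, the initiator's propensity is multiplied by
  (1+β) and each groupmate's divided by (1+β), then all rates are rescaled
  so the group's total propensity is conserved. Feedback therefore
  *redistributes* the tendency to initiate toward successful initiators
  rather than amplifying it. The rescaling matters: without it the update
  compounds into runaway rates (thousands of events per second), the winner
  vacates arms before followers arrive, and the intended leader/follower
  differentiation is destroyed. With conservation, β = 0.5 produces strongly
  negative within-pair count correlations and COV/max values above the
  membership-shuffle null, growing with β; β = 0 leaves per-fish counts
  exchangeable across groups so both randomization tests are calibrated.
* Trials are rendered to 25-fps positions along piecewise-linear paths
  through arm mouths, with AR(1)-smoothed lateral jitter (SD 0.25 cm,
  ρ = 0.95). Jitter inside an arm is exactly perpendicular to the arm axis
  (so entry depth, the same-frame tie-break, is untouched) and is suppressed
  wherever it would move a point across a region border — rendered
  trajectories cross borders exactly where the continuous-time model says.
  Identity uncertainty is drawn per tracker segment (exponential segment
  lengths, mean 20 s) from Beta(1, 19) (mean 0.05, mostly-certain tracks).
* **Ground truth** records every arrival at frame resolution with its
  occupancy-based kind; by construction these reconcile bit-exactly with
  the pipeline's extraction from the rendered tables — the keystone
  end-to-end identity that the test suite asserts on 50 trials.

The default study-scale design (`study_design_config`) reproduces the
original sampling frame: 102 groups / 310 fish split over three predation
levels (84/108/118 fish), two group sizes and both sexes.

### What the simulator does not emulate

It is a structural, not calibrated, emulator: no burst-and-coast swimming,
wall-following or within-arm behaviour (fish rest near the arm mouth
between moves, so simulated mean speeds are lower and neighbor distances
tighter than live fish would show); no occlusion gaps by default; no
between-population differences unless configured per stratum. Passing tests
therefore validate the *pipeline's bookkeeping and the statistical
machinery* — they do not validate biological conclusions about real fish,
and quantities that depend on motion detail (speed, neighbor distances)
are only checked for internal consistency, not realism.

## Problem sizes and numerical notes

The test suite runs the oracle-equivalence checks at 100 random 4 × 500
occupancy matrices, the generative identity at 50 rendered trials, the
type-I calibration and power studies at 200 simulated 12-group datasets with
2,000-iteration randomizations, and the split-half property at 20 replicates
of 100 fish — sizes at which the Monte-Carlo error of each criterion is far
smaller than its acceptance band. Exhaustive enumerations (2³ labelings; all
6! orderings of six fish into three pairs) anchor the Monte-Carlo nulls on
small instances. Degenerate inputs are handled explicitly: undefined COV →
flagged missing and excluded; constant split-half vectors → undefined
correlation, flagged; all-identical pairwise counts → error; single-group
strata → excluded with a warning.
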