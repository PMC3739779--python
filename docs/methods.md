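# Methods

## The generative model

Each simulated animal is a point (its tracked centroid) in a rectangular
arena, sampled at 25 frames/s from t = 0 to the session end inclusive, so a
session of `T` seconds has `25·T` frame intervals. Motion is built from
three independent stochastic components:

1. **Bout alternation.** Rest bouts (zero displacement) alternate with swim
   bouts. Both durations are exponential — the simplest one-parameter,
   memoryless choice, and deliberately swappable (`simulate._bout_states`
   is the single place the law enters). The process starts in its
   stationary regime: the initial state is drawn with probability
   `f = mu_swim / (mu_swim + mu_rest)` of being active, and memorylessness
   makes the first duration the correct residual. The expected active
   fraction of any session therefore equals `f` exactly, which the test
   suite checks against Monte-Carlo means.

2. **Within-bout speed.** Per-frame speeds are normal around
   `cruise_speed_mean`, clipped symmetrically at ±2.5 SD (mean-preserving)
   and strictly positive. Headings perform a persistent random walk with
   stage-tuned wrapped-normal turn increments (sharper for larvae), frozen
   during rest. Turn concentration affects the shape of the path but not
   its length, so it is not a calibrated parameter.

3. **Bursts.** Brief episodes of duration `burst_duration` at
   `burst_speed_mean` override the bout state (a burst can interrupt a
   rest). Inter-burst gaps are a dead-time renewal process: an 8-s
   refractory period plus an exponential tail, with `burst_rate` the
   realized mean rate. A pure Poisson process was considered and rejected:
   its arrival clustering merges bursts on the 3-s analysis grid so
   strongly that the mean number of *distinguishable* events in a 5-minute
   session cannot exceed ~18 regardless of rate, which contradicts the
   reference larval count (~28); a refractory period after an all-out burst
   is also the physiologically sensible choice. The event count stays
   independent of the cruise parameters, which is the property the burst
   component exists to provide.

Walls reflect specularly, implemented by folding the unbounded cumulative
coordinate with a period-2W triangle wave — exact specular reflection of
piecewise-linear motion, preserving per-step path length.

Determinism: one master seed; per-animal seeds derive from
`SeedSequence(master, spawn_key=(assay, animal_index))`. Identical
(profile, session, seed) triples give bit-identical trajectories.

## Stage conventions and arenas

| stage   | arena (mm)  | integration period | surface calibration |
|---------|-------------|--------------------|---------------------|
| 6 dpf   | 15.5 × 15.5 | 60 s               | not resolved        |
| 1 month | 95 × 60     | 300 s              | 2.23 mm²/px         |
| 3 months| 245 × 150   | 300 s              | 3.61 mm²/px         |

The larval arena is one well of a 24-well plate. Its exact geometry is not
standardised in the source protocols; we model the well footprint as a
15.5 mm square (the trajectory/arena types are rectangular throughout) and
leave it configurable. Fast-swim sessions are 300 s with 3-s bins at every
stage.

## Movement threshold

`segment_activity` classifies a frame interval as "moving" when its
displacement exceeds `move_threshold` (default **0.002 mm/frame**, i.e.
0.05 mm/s at 25 fps). The threshold separates two regimes that the
synthetic chain keeps cleanly apart: genuine rest frames have displacement
exactly zero (the renderer's noise stays below the detection threshold, so
a stationary silhouette is bit-stable and the tracker returns an identical
centroid), while the slowest within-bout motion of the packaged profiles
(larval sculling, ≥ 0.06 mm/s) sits above it. The default matters: larval
cohorts spend most of their active time in slow sculling punctuated by
bursts, and a threshold above the sculling displacement would reclassify
most of their activity as rest. The value is configurable in every entry
point, and raising it can only decrease swimming time (tested property).

## Profile calibration

Packaged profiles are fitted so that simulated cohort means of the
*measured* pipeline outputs hit per-strain targets (reference AB values:
881 cm and 2435 s per hour and 28 events per 5 min at 6 dpf; 4719 cm /
2506 s at 1 month; 16370 cm / 3116 s at 3 months; other strains follow the
study's qualitative ordering with plausible, not published, values — see
the YAML headers). The fit (`locotrace.calibration`) is:

1. moment matching: swimming time → active fraction → `swim_bout_mean`
   given a stage-typical `rest_bout_mean`; distance → speed scale;
2. deterministic bisection of `burst_rate` against the simulated mean
   event count (6 dpf only, where an event target exists), bracketed
   inside the monotone regime (rate < 60 s / refractory);
3. a few multiplicative refinement rounds of (1) under fixed seeds, which
   absorb second-order effects (bursts landing in rest bouts, clipping,
   path folded at walls).

Two regimes emerge. Larvae: slow sculling (~0.12 mm/s) carries the
swimming *time* while bursts (~24 mm travelled each) carry most of the
*distance* — this split is forced by the three 6-dpf targets jointly: with
~2435 s/h of detected movement, any sustained cruise fast enough to
dominate distance would exceed 5 mm in every 12-s window and fuse the
session into a handful of giant "events". Juveniles/adults: genuine cruise
(≈ 1.7 / 4.7 cm/s) carries distance, bursts are a minor component.

## Metric definitions

- `distance` sums all per-frame displacements (bin sums conserve total
  path length to 1 part in 1e12; binning at any divisor period leaves the
  total unchanged).
- `swim_time` sums moving intervals; `rest_time = T − swim_time` holds
  exactly, by construction, for every input (fuzz-tested).
- `mean_speed = distance / swim_time` — the *active* speed, excluding
  frames without detected movement. A zero-activity animal gets speed 0
  and an explicit flag instead of being dropped. Note that for juvenile
  and adult reference cohorts the published speed exceeds published
  distance ÷ published swimming time (2.21 vs 1.88, 5.87 vs 5.25 cm/s);
  those figures were likely produced by a different (frame-wise) averaging.
  This package implements the quoted definition, and only the internally
  consistent larval triple (881 / 2435 → 0.36 cm/s) is used as a reference
  check.
- Fast-swim events: a bin is *hot* when some window of ≤ 4 consecutive
  3-s bins containing it sums to > 5 mm and the bin itself is ≥ 0.5 mm
  (the quiescence floor prevents a rest bin inside a qualifying window
  from bridging two bursts). Maximal hot runs are events; each is anchored
  at its peak bin and truncated to the best ≤ 4-bin window for reporting.
  A brute-force window-enumeration oracle must agree exactly on random
  series (tested on 1000). The alternative `single-bin` rule (count bins
  > 5 mm individually) is provided for comparison; `window` is default.

## Tracking emulator

Background is the modal intensity; foreground is |pixel − background| >
threshold (default 11); components use 8-connectivity with a 4-px minimum
(standard blob practice); the largest component wins; absence is a valid
result. Missing frames carry the last position forward with a flag —
inventing zero displacement rather than interpolated motion, matching the
"no movement detected" semantics. The surface cut (117) shares the same
background model. The rendered field of view extends one body length past
the arena so wall-hugging animals are never clipped (clipping would bias
centroids inward by several pixels). With sub-threshold noise the
simulate → render → track loop recovers path length within 2% and
positions within a fraction of a pixel.

## Statistics

Two-sided tests throughout; p-values from exact t/F distributions.
"Bonferroni–Dunn" is implemented as Dunn's procedure: all pairwise mean
comparisons using the one-way ANOVA pooled error term,
`t = (m_i − m_j) / sqrt(MS_err (1/n_i + 1/n_j))` at the error df, declared
at α / n_pairs (0.05/15 ≈ 0.0033 for six strains). The two-way
strain × time-bin ANOVA is fixed-effects and crossed, treating bins as
independent observations; the caveat that bins are really repeated
measures on the same animals is acknowledged — mixed models are out of
scope. Degenerate inputs (zero pooled variance, saturated designs) return
flagged results rather than raising.

## What the synthetic data does and does not show

The generator reproduces the *statistics the pipeline measures*: bout-level
activity alternation, binned distance structure, burst counts, cohort means
and their variability. It does not attempt tail-beat kinematics,
hydrodynamics (viscous→inertial transition), day/night rhythm,
multi-animal interaction, thigmotaxis, or strain-specific turn statistics.
Passing recovery tests therefore shows the measurement chain is correct
and internally consistent — not that real fish behave like the model. Two
known gaps: (i) at 1 and 3 months the published fast-swim counts (~22–30)
are not reproduced — under sustained cruising every active bin exceeds the
5-mm window threshold, so the merged-run count saturates at the number of
long pauses (~4–10); the printed counts are reproduced only at 6 dpf,
where locomotion is burst-dominated; (ii) per-animal variances are not
calibrated against published SEMs (only means are).

## Problem sizes

Default verification runs use the study's cohort sizes (47 larvae, 19
adults) for recovery checks; 1000 random series for the event-scoring
oracle; 20 random profiles with short (8-s) sessions for the rendering
round trip; and 1000–1500 replicates for the renewal-theory and type-I
error calibrations. These sizes give Monte-Carlo standard errors several
times smaller than the tolerances they are tested against.
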