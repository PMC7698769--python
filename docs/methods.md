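# Methods

`cropscout` simulates fully autonomous aerial crop scouting: a small
unmanned aerial system (UAS) visits a fraction of a gridded field, and the
software reconstructs a complete binary crop-health map from that partial
sample. This note describes the models, the parameters that matter, the
synthetic data the package is exercised on, and the design choices made
where the design was genuinely open.

## The world model

A field is a `rows x cols` lattice of management zones (default 32 x 42 =
1344 zones of ~4.3 m² each — the geometry of a single aerial image tile of
an 80-acre corn field). Each zone carries an RGB image tile and a binary
health label derived from the excess green vegetation index,

    ExG = 2*ghat - rhat - bhat,      rhat = R/(R+G+B), etc.,

a zone being labeled unhealthy when its mean ExG falls below 80% of the mean
zone ExG of its field (a zone exactly at the threshold is healthy). The 80%
rule makes labels scale-invariant: global illumination changes that multiply
every zone's ExG leave the map unchanged. The rule is undefined on fields
with non-positive mean ExG and the code refuses rather than guesses.

A flight path induces a three-way **area partition**: *visible* zones
(flown over; ground truth known), *neighbor* zones (unobserved but
8-adjacent to a visible zone) and *unknown* zones (everything else).

## Spatial extrapolation

Crop stressors spread locally, so neighboring zones are informative about
each other. Eight **directional predictors** — one per compass offset —
each answer: given the image of the observed zone at offset *d* from an
unobserved target, is the target healthy? Predictor *d* is trained on pairs
(tile at `center + d`, truth label at `center`) over all interior centers of
the training fields. A zone with several visible neighbors gets one
probability per neighbor (each through that neighbor's directional model);
the ensemble probability is their arithmetic mean, and the label is healthy
iff it is >= 0.5.

The default backend is a seeded logistic regression over per-tile features
(mean/percentile/σ of ExG, channel means). This sits deliberately in the
~90% single-tile accuracy regime; the backend is pluggable (any object with
`fit_features`/`predict_features`), and degenerate one-class training data
falls back to a Laplace-smoothed constant.

**Reference set.** Held-out zone images (never used in training) are scored
once with a direction-free confidence: the mean of all eight backends
applied to the tile itself. When the fill algorithm predicts an unobserved
zone it substitutes the reference image whose confidence is closest to the
prediction (ties to the lowest index), so the zone gains a stand-in image
and can serve as pseudo-observed input later.

**Window fill.** Extrapolation operates on a UAS-centered odd-sized
**prediction window** (sizes 7–23; windows are clipped at field borders, not
padded). Each iteration predicts *all* current neighbor-area zones from the
pre-iteration visible set (a synchronous batch, so the result is independent
of zone processing order), substitutes reference tiles, promotes the batch
to visible and re-partitions. The wavefront reaches the window edge in at
most `(w-1)/2` iterations when the visible set contains the center.
Originally observed zones are never overwritten, and a second fill of a
filled window is a no-op (idempotence). A sequential mode (fills feed each
other within an iteration) exists behind a flag only to document that the
iteration ordering was ambiguous in the source material; batch is the
default because it is order-invariant and testable.

Window extraction copies statuses from the full-grid partition; the fill
algorithm first recomputes a window-local partition because a zone whose
only visible contact lies outside the window is unreachable from inside it.

## Path planning

The planner is a memory-based (KNN) approximation of Q-learning. Training
experiences come from simulated random flights: starting at a random border
zone, each step moves to a uniformly random unvisited 8-neighbor (a 4-
neighbor mode exists behind `adjacency=4`; the source material never states
whether diagonal moves are allowed), relocating to the nearest unsampled
zone (Chebyshev distance, ties row-major) when boxed in. One record is
stored per transition: the encoded window state, the action, the realized
utility gain and the destination zone's realized label. Relocations are
attributed the compass direction of their displacement sign so every
transition has an action.

**State encoding** is the flattened observed-truth layer (1 / 0 / 0.5 where
unobserved or out of field) concatenated with the flattened predicted-
probability layer plus the coverage fraction: length `2*w² + 1`. The 0.5
sentinel is the uninformative midpoint.

**Action rules.** At flight time the `k = 11` nearest records (L2 on encoded
states, stable ties) are retrieved. The default rule flies toward the
candidate action with the largest absolute disagreement between the
retrieved estimate (mean realized destination label among retrieved records
taking that action) and the spatial ensemble's probability for the
destination — the zone the system understands least. An alternative rule
maximizes the mean retrieved utility gain (gains normalized by the dataset's
maximum absolute gain, mapping to [-1, 1]). Both exist because the source
material describes both; the disagreement rule is the default. Candidates
with no retrieved evidence rank below any candidate with evidence; ties
resolve in the fixed compass order N, NE, E, SE, S, SW, W, NW. Utility gain
is measured window-locally (filled-window accuracy after minus before the
step): whole-field refills at every transition of every training path would
be prohibitively slow, and the window is the planner's own field of view.

**Local-field baseline.** The baseline policy's state is only the last
zone's image features (mean ExG, mean HSV saturation, channel means); it
uses the same KNN/argmax machinery on utility gains. Its final map comes
from recursive dilation: synchronous passes assign every unlabeled zone the
majority label of its labeled 8-neighbors (ties to healthy — the tie rule is
a config switch). Dilation reinforces clusters: a solid block of one label
out-votes competing fronts where scattered seeds lose ties, which is exactly
the failure mode this baseline exhibits on fields with large stressed
patches.

## Mission loop and energy model

A mission flies a policy (`whole_field`, `local_field`, `random`,
`exhaustive` boustrophedon, or `non_scouting`) until the target coverage
(ceil of coverage x zones) is reached, then produces the final map: a
whole-field fill (window wide enough to cover the field) for the
window-based policies and random scouting, dilation for the local baseline,
ground truth for exhaustive, and all-unhealthy for non-scouting (treat
everything uniformly).

The battery drains 5% per zone-step from 100%; when the level reaches the
30% floor after a step it is swapped to 100% before the next step, and the
charge count is 1 plus the number of swaps. This rule reproduces every cell
of the two empirical traces the model was reverse-engineered from (35% at
exhaustive step 13, then 85/65/45 at steps 17/21/25 after the swap; 50% at
autonomous step 10); the interlude bookkeeping between steps 14 and 16 is
not uniquely identified by those traces, and other rules might match them
too. Relocation flights cost one drain step per zone of Chebyshev distance
(configurable; the source material is silent).

## Economics and runoff risk

Positive means healthy. A **false positive** (truly unhealthy zone
classified healthy) goes untreated and loses ~$0.8 of yield; a **false
negative** (truly healthy zone classified unhealthy) is treated
unnecessarily at ~$0.1 and contributes to nutrient-runoff risk. The
per-zone constants derive from $763.8 revenue/acre and $130 fertilizer/acre
over 4.3 m² zones (one-decimal rounding), giving the 8:1 cost asymmetry.
Because the words "false positive/negative" are used inconsistently in parts
of the source prose, the cost model is keyed to semantics
(`missed_unhealthy`, `overtreated_healthy`), not to the labels.

Net revenue = zones x $0.8 - $0.8 x missed unhealthy - $0.1 x zones
classified unhealthy - labor. Labor is charges x hours-per-charge x wages:
one $10/h unskilled worker for autonomous policies, plus a $20/h skilled
worker for exhaustive scouting. Hours per charge default to 0.33 h (the
mid-range of a 15–25 min commodity-UAS flight); the reference labor
figures ($212 exhaustive, $44 autonomous at 40%) cannot be re-derived from
printed flight-time assumptions, so they are treated as inputs and only
their ratio (4.8x) is recomputed. Charges scale linearly with zones visited
(29/hectare exhaustive -> 12 at 40%, 6 at 20%). Runoff risk is the
percentage of truly healthy zones slated for unnecessary fertilization,
100 x FN / (TP + FN). Metrics with zero denominators are reported as
missing, never silently zero.

## Synthetic data: what it emulates, what it does not

The generator reproduces the two statistical properties the method depends
on:

1. **Spatially clustered health** — iid Gaussian noise per zone, smoothed
   with a Gaussian kernel of width `cluster_scale`, lowest
   `unhealthy_fraction` quantile marked unhealthy. Defaults: 30% unhealthy,
   scale 4 (on the 32 x 42 default grid). The realized unhealthy count is
   exact to the rounded target.
2. **ExG-separable but imperfect textures** — healthy tiles are rendered
   from a green-dominant base color, unhealthy from a soil-toned one, with
   tile-level green jitter (`tile_green_sd = 34`) calibrated once so a
   Bayes-optimal single-tile ExG threshold scores ≈ 0.90, matching the
   accuracy regime the extrapolation models are assumed to operate in, plus
   per-pixel noise. Tiles are 32 px (not the ~109 px of real zones): texture
   statistics, not resolution, carry the signal.

Everything is a pure function of the spec (seed included). What the
generator does **not** emulate: real corn morphology, row structure,
illumination gradients, sensor artifacts, tractor traces (beyond an optional
low-ExG streak flag for demos), or correlations between texture and cluster
shape. Passing tests therefore demonstrate the *mechanics* of the pipeline
under the stated statistical assumptions, not performance on real imagery.

## Desk-scale study conditions

Monte-Carlo comparisons run on **quarter-scale replica fields**: 16 x 21
zones with `cluster_scale = 2`, preserving the full field's
correlation-length-to-field ratio (4/32 = 2/16), with window size 7
(similarly proportional to the full-scale configuration's best 15 x 15 on 32 rows).
Keeping the absolute correlation length while shrinking the grid distorts
the spatial regime — clusters spanning a third of the field make random
sampling nearly as good as informed sampling — so the ratio, not the
absolute scale, is what the replica preserves. The RL bank is built from 40
random paths at 40% coverage over 3 training fields (~5,400 records; the
full-scale 73,000-record bank is a configuration target reachable through
`build_rl_dataset`, not a test requirement), with 300 reference tiles and
k = 11. Policy comparisons use at least 20 field seeds.

Under these conditions whole-field RL reaches ~0.88 mean map accuracy at
40% coverage and ~0.78 at 20%, exceeding random scouting by roughly 1–3
accuracy points depending on the seed set; the margin is of the same order
as its 20-field Monte-Carlo error, so single small comparisons can
occasionally invert even though the pooled effect is positive. Accuracy is
monotone in coverage over 10–40% well within two standard errors.

## Numerical choices and degenerate inputs

- Confidences are stored as probability-of-healthy in [0, 1] throughout;
  the (label, confidence >= 0.5) view is derived.
- Ensemble label threshold is >= 0.5 (healthy on the boundary).
- KNN distances use stable argsort, so equidistant records resolve by
  dataset order; reference-tile ties resolve to the lowest index.
- The nearest-unsampled relocation breaks Chebyshev ties in row-major
  order.
- Empty visited sets, unlabeled training fields, empty reference sets,
  even window sizes, non-visible window centers and all-unlabeled dilation
  inputs all raise immediately with actionable messages.
- Seeds are combined as integer key sequences for `numpy.random.default_rng`
  (never string hashes, which are not stable across processes).

## Known limitations

- The directional predictors see a single adjacent tile, the literal
  reading of "one model per direction"; a 3 x 3 context variant might be
  stronger but is not what the design describes.
- The KNN-vs-ensemble disagreement is operationalized as
  |mean retrieved destination label - ensemble probability|; the source
  material names the quantity without defining it numerically. This is the
  central interpretive decision of the planner.
- Window-local utility gains are a proxy for whole-map accuracy improvement.
- The economics model prices one treatment (fertilizer) and one crop (corn)
  and ignores weather, market and pest dynamics.
- Charges-per-area reporting assumes strict linearity between zones visited
  and battery swaps.
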