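# Methods

## The branching model

Ductal morphogenesis is modelled as a branching-annihilating random walk in
the plane. The state is a set of active termini, each with a position, a
unit direction, and the polyline of the duct segment it is extending. Per
update, in randomized order, each active terminus:

1. advances by the elongation step δ along its direction, after rotating the
   direction by a Normal(0, σ) wobble;
2. terminates (permanently) if the new position lies within the
   annihilation radius r_a of any already-deposited duct path, including the
   central duct — termination is checked before branching, so it wins ties;
3. otherwise bifurcates with probability p_b, closing the current segment
   and spawning two daughters at ±θ about the current direction, each offset
   by one step;
4. otherwise simply extends its segment.

The initial condition is `n_initial_termini` (default 40) termini launching
perpendicular to a straight central duct, at inter-root gaps drawn i.i.d.
Exponential(mean = spacing) truncated below at r_a ("independent adjacent
subtrees"; a fixed-gap option exists for tests). Roots launch on one side of
the duct; sidedness is not constrained by the data the model describes, and
a single side keeps the nominal spacing the literal inter-root gap.

### Units and defaults

All lengths are expressed in units of `spacing`, the mean separation of
adjacent subtree roots along the central duct — the model's single key
length scale. Defaults:

| parameter | default | meaning |
|---|---|---|
| spacing | 1 | inter-subtree root separation (unit of length) |
| n_initial_termini | 40 | termini seeding the central duct |
| step_length δ | 0.05 | elongation per update |
| branch_prob p_b | 0.05 | bifurcation probability per update; mean branch length δ/p_b = 1 spacing |
| annihilation_radius r_a | 0.25 | proximity at which ducts terminate |
| branch_angle θ | 30° | half-angle per daughter |
| angle_noise σ | 0.15 rad | per-step direction wobble |
| self_exclusion_length | 0.75 (= 3 r_a) | geodesic arc within which deposited points are ignored |
| max_steps | 500 | development window (see below) |

δ and p_b are chosen so the mean branch length equals the subtree spacing;
r_a and σ are calibration knobs exposed in the config. In an open plane the
tip front advances indefinitely, so `max_steps` plays the role organ harvest
plays in an experiment: it bounds the simulated growth period. At 500 steps
(25 spacings of path per tip) networks show >10 serial branch generations
and subtrees ranging from 1 branch to several hundred, and a run takes
about 2 s; the ensemble statistics reported by the acceptance script use
120 such runs.

### Proximity bookkeeping

Proximity is evaluated against the path points the simulation deposits (one
per elongation step, so spacing δ ≪ r_a) on a uniform grid with cell size
r_a. A terminus ignores points whose arc distance *through the tree* is
within `self_exclusion_length`. This single geodesic rule covers the
terminus's own trailing path, the junction it was born at, and its newborn
sibling — all of which are within r_a Euclidean at birth and would otherwise
annihilate every tip immediately — and it expires exactly when the sibling
pair has separated geometrically. Central-duct points are excluded only
within the same arc budget of the terminus's own root attachment.

### Emergent behavior, measured

* The active termini form a traveling pulse: the ensemble-mean front radius
  grows essentially linearly. Monotonicity is asserted on 25-step
  increments, because the per-step ensemble mean (at 100 runs) carries
  Monte-Carlo noise (±0.05 spacing) comparable to the per-step drift
  (+0.025), while over 25 steps the drift (+0.6) dominates.
* Pooled subtree sizes are strongly heterogeneous: at defaults ~10 % of
  subtrees exceed 3× the pooled mean (the tail(3) statistic).
* Bulk density is *roughly* constant but not statistically flat: the radial
  profile over the region laid down earliest (out to the 10th-percentile
  final terminus radius) rises from ~2.3 to ~3.1 duct-length per unit area
  across four bands. Two structural causes: each subtree leaves the duct as
  a single unbranched stalk, making the first ~1 spacing of radius sparser;
  and the zone laid while the tip population was still equilibrating keeps a
  ~3 %-per-band gradient. The corresponding flatness test is therefore
  expected to fail at defaults and is left failing rather than tuned away;
  bands 2–4 of the profile vary by <10 %.

## Precursor drift and monoclonal conversion

Each terminus carries a pool of N precursor slots with labels (confetti
color, clone id, or unlabeled). At a bifurcation the N cells are partitioned
uniformly at random into groups of ⌊N/2⌋ and ⌈N/2⌉ (side assignment random
for odd N); each daughter's cells duplicate once, the larger daughter
discards one uniformly chosen copy and the smaller duplicates one uniformly
chosen cell again, restoring size N. Both odd-N corrections preserve the
martingale E[k′ | k] = k, hence the exact fixation law P(all-labeled) = k/N,
verified against both the analytic value and a 10⁵-lineage Monte-Carlo run.
For N = 1 the lone precursor is copied to both daughters (the only
size-preserving rule).

A segment's label composition is the pool state at the moment its
construction begins; "monoclonal" means zero label entropy (all one color or
all unlabeled). The labeled count along a random lineage is a Markov chain
on {0..N} built from hypergeometric draws (`transition_matrix`), used for
exact fixation/conversion solves; vectorized Monte-Carlo chains
(`simulate_conversion_chains`) and whole-tree ensembles
(`ensemble_conversion_profile`, with unbiased subsampling beyond 2×10⁵
tracked segments per generation) provide the stochastic routes.

Two discrete subtleties worth knowing:

* At generation 1 the expected monoclonal fraction is exactly 1/2 for every
  even N (the single labeled cell lands in one daughter); profiles are
  informative from generation 2 on.
* The unconditional lineage absorption time is dominated by that early
  label loss and barely depends on N. The *conversion-generation* statistic
  therefore conditions on fixation — the ducts a traced clone actually shows
  converting — and uses an interpolated median (the discrete CDF crossed at
  1/2), which grows ~linearly with N (0.5, 2.75, 9.1, 22.3 for
  N = 2, 4, 8, 16): the inverse-N conversion-rate law.

`infer_precursor_number` scores each candidate N by the
segment-count-weighted mean squared difference between the observed and
simulated monoclonal-fraction profiles over shared generations; the fitting
statistic is a package choice (the comparison being emulated was visual),
and parameter recovery on synthetic N = 4 profiles of 10³ subtrees is part
of the acceptance suite.

## Clone statistics

* Potency: a lineage (acinar/ductal/islet) is present iff its volume
  strictly exceeds `presence_threshold` (default 0 µm³ — imaging-based
  assignments carry no stated cutoff; the threshold is exposed for
  sensitivity analysis).
* Rescaled distributions: sizes divided by the sample mean; `tail(x)` is the
  fraction strictly above x.
* QQ-R²: both samples mean-rescaled, quantiles evaluated at
  p = (i − 0.5)/m, i = 1..m, m the smaller sample size, with type-7 linear
  interpolation between order statistics; R² = 1 − Σ(q_b − q_a)²/Σ(q_b −
  mean q_b)². The grid/interpolation convention is fixed so R² values are
  reproducible; alternates can be compared against it.
* Rank tests: U uses the ½-tie convention; the exact two-sided p is the
  enumerated probability of a U at least as far from nm/2 as observed, over
  all C(n+m, n) assignments (feasible and used for n+m ≤ 12; `auto` mode
  switches there). Asymptotic p-values come from scipy (normal approximation
  with tie and continuity corrections; asymptotic KS). Null rejection rates
  at α = 0.05 calibrate to 0.050/0.049 over 10³ replicates.
* Small-size binning before rank tests (flooring rescaled sizes below a
  configurable quantile to a common value) is available but off by default,
  since no bin edges are canonically defined.
* Center/periphery: a clone is central iff its distance from the supplied
  organ center, normalized by the organ radius estimate, is ≤ 2/3.

## Clonality QC

The same-color pair probability per 3D-distance bin is rescaled by the
any-color pair count in the bin, removing organ-shape effects; under clonal
(independent) induction the curve is flat. The null envelope redraws colors
i.i.d. from the per-mouse empirical color frequencies at fixed positions
(1000 resamples, per-bin 2.5/97.5 % quantiles). Default bins: 10 equal-width
bins from 0 to the 95th percentile of pair distances. Merger correction
groups same-color clones by single linkage at the user-supplied radius
(transitive closure is the only reading of "within a radius" that is an
equivalence); merged clones get summed volumes and volume-weighted
centroids. The operation is idempotent and conserves per-color volume; the
radius has no canonical value and is a required parameter.

## Synthetic data generator

`generate_clone_table` chains the simulator and the drift model into a
virtual tracing experiment: each organ is one default-parameter network;
each root terminus carries a ductal pool and an acinar pool (both size N,
default 4, same dynamics — acinar-committed precursors are conveyed with the
ducts); labels are induced at the start of branching, each ductal-pool cell
independently with total probability `induction_fraction` (default 0.025,
matching clonal-density labeling below 3 % by volume) split across colors
RFP:GFP:YFP:CFP = 5:3:3:1. An induced ductal cell is multipotent with
probability `potency_mix` multipotent/(multipotent + ductal-committed)
(defaults 0.15/0.35), in which case it co-seeds one acinar-pool slot;
direct acinar induction is down-weighted by one minus that probability so
the marginal per-cell labeling probability is equal in both pools — combined
with the drift martingale, the expected labeled volume fraction of every
compartment equals the nominal induction fraction.

Volumes are booked per segment: ductal volume ∝ segment length ×
`duct_cells_per_spacing` × `cell_volume` × pool share; acinar likewise with
`acinar_cells_per_spacing`; islet volume is emitted by a per-segment
Bernoulli (`islet_emission_prob`, default 0.2) as `delamination_fraction`
(default 0.05) of the segment's trunk output — a minimal mechanism for
ductal-islet bipotency, since islets derive from trailing ducts at an
unmeasured rate. The cells-per-length and cell-volume constants are
order-of-magnitude placeholders (they cancel from every rescaled statistic)
and positions are volume-weighted centroids with Gaussian jitter
(`position_noise`, 30 µm) mapped at 150 µm per spacing unit.

What passing tests on these data do show: the pipeline's statistics recover
planted truth (potency classes, color ratios, precursor number, clonality
violations) under the stated noise model. What they do not show: robustness
to real-imaging artifacts — section truncation of clones, segmentation
error, boundary effects of true organ geometry — none of which the
generator emulates.

Clone cohesion is structural here: induction happens at subtree roots, so a
clone's mass lies in one subtree by construction (the corresponding check
guards the bookkeeping rather than discovering biology).

## Numerical and design choices

* One seeded `numpy` Generator stream per run; ensembles draw per-run seeds
  from the stream, and the CLI/acceptance script derive component seeds from
  the global `--seed` via `SeedSequence` spawning (all below 2³¹).
* Identical (params, seed) gives byte-identical serialized outputs; clone
  CSVs are written with shortest-round-trip float reprs and read with
  pandas' `round_trip` parser so write∘read is the identity.
* Network JSON validates structure on read (cycles, dangling parents,
  generation consistency) and refuses truncated files outright.
* Degenerate inputs raise: empty pools, empty samples, zero expected
  chi-square cells (with a pooling hint), all-excluded proximity queries
  return ∞, zero-variance QQ references.
* Examples of known limitations: the simulator's bulk-density gradient
  (above); rank-test p-values on clustered cohorts are anti-conservative
  (clones within an organ share a subtree realization); the acinar/islet
  volume constants are placeholders; no organ boundary, 3D geometry, or
  plexus remodeling.
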