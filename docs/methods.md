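# Methods

This note records the model as implemented, the parameter choices and their
rationale, what the synthetic inputs do and do not emulate, and the
numerical decisions a maintainer would need to know. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Movement model

A migration path is a correlated random walk (CRW) of fixed-length steps
inside a planar lake polygon (Cartesian meters; no geographic CRS).
Headings are degrees clockwise from grid north; the per-step turning angle
is drawn from Normal(μ = 0, σ). The first step is treated like every other
step: a turn drawn around the basin's initial bearing (the inward shoreline
normal at the river mouth for constructed basins), rather than a
deterministic move along it — the alternative is a one-step perturbation
with no measurable effect on any grid summary.

**Boundary handling.** A proposed step whose segment would cross the
shoreline is rejected and redrawn with standard deviation
σ_eff = σ(1 + c·k^e), defaults c = 0.1 and e = 2, where k counts
consecutive rejections *within the current step* and resets to zero on
acceptance. The per-step reset is a deliberate choice: letting k accumulate
over the whole path inflates σ without bound, destroys the walk's
directional persistence, and (verified by simulation) collapses success
everywhere below ~30%, which is incompatible with the behavior the model is
meant to reproduce. Both c and e are config-exposed because the inflation
rule's typography is ambiguous in the source material. A retry ceiling
(default 100) guarantees termination; paths ending that way are a separate
`failure_retries` outcome, counted and reported — zero occur in all shipped
designs.

**Termination.** A walk succeeds when a step reaches the outlet capture
disc and fails when its step budget floor(max_path_length / L) is spent, so
every path of a given step length has the same maximum possible length
(75 km in the hypothetical design — at least 8× the direct distance).

## Capture-region semantics (a genuinely open design point)

Two readings exist for the outlet region's published size ("440 m"
perimeter for the hypothetical basins; 29–200 m for the real lakes), and
two for detection:

* radius: the figure is the **full circumference** of the disc
  (r = P/2π ≈ 70 m) vs. the **in-lake arc** of a disc straddling the
  shoreline (r ≈ 140 m on a near-straight shore, solved by bisection);
* detection: success when a step's **endpoint** lands in the disc (arrival
  checked once per step, as with discrete position fixes) vs. when the
  step's **segment** crosses the disc at all.

We probed all combinations against the published success surface and
adopted **full-circumference sizing with endpoint detection** as the
default. This is the only reading that reproduces the study's central
step-length result — success peaking near L ≈ 100 m and declining markedly
at 200 m — because a 200-m step can jump past a ~70-m-radius target between
position fixes, while segment detection makes success monotone increasing
in step length regardless of the radius choice. The alternatives remain
available (`CRWParams.capture_mode="segment"`,
`capture_sizing="arc"`; the arc solver is `geometry.size_capture_region`).

Consequence worth knowing: under these defaults the published real-lake
simulation results (near-100% success in the two small lakes) are *not*
reproduced on our synthetic shorelines — a ~5-m-radius target in a lake of
0.5–2 km² is found rarely by endpoint checks. The real outlets sit in
river-mouth funnels that act as much larger effective targets; our
harmonic stand-ins have no such funnels. Real-lake runs here are
protocol illustrations, not quantitative reproductions.

## Basin construction

All basins are shapely polygons normalized by uniform scaling to their
target area exactly (so area invariants hold by construction).

* **Circular** (25.0 km², 256 vertices): start and end on the
  circumference 5.5 km apart, symmetric about the southern axis.
* **Elliptical** (22.1 km², aspect 2:1 — the aspect is unstated in the
  source and config-exposed): start/end begin at the circular basin's
  angular coordinates as parametric angles, then the end point slides along
  the boundary until the straight-line separation is 5.5 km (root-finding on
  arc offset).
* **Rounded-rectangular** (27.8 km²): a capsule (corner radius = half the
  short side). The published constraints — area 27.8 km² *and* terminal
  start/end separation 11.3 km — jointly determine the width, giving aspect
  ≈ 4.37:1; a 4:1 capsule cannot reach 11.3 km tip-to-tip at that area, so
  the aspect is implied rather than assumed. The *lateral* variant puts
  start and end on one long shore 5.5 km apart; the *terminal* variant puts
  them at the two tips.
* **Real-lake stand-ins**: five star-shaped harmonic outlines (≤200
  vertices, generated by `scripts/make_lake_fixtures.py`, bundled as
  GeoJSON flagged `synthetic`/`approximate`), area-normalized to the
  published surface areas (0.69, 0.45, 1.83, 71, 5.1 km²), with published
  endpoint perimeters and path caps (75/75/55.8/75/30.4 km — the two
  shorter caps applied verbatim; the speed × longest-migration-time formula
  is exposed separately as `max_path_length_for_lake` because the published
  caps are not derivable from it).

An equal-area switch (24.3 km² for all hypothetical basins) covers the
source's internally inconsistent area statements; defaults follow the
per-shape figures.

## Randomness and reproducibility

All draws come from numpy `Generator`s seeded through `SeedSequence`
material `[seed..., path_index]`; per-cell seeds are
`[global_seed, crc32("basin|step|sigma")]`, so any cell's ensemble is
bit-reproducible in isolation and adding cells to a design never perturbs
existing ones. Identical (design, seed) runs produce byte-identical CSV
tables.

## Metrics and statistics

Per cell (basin × step length × σ; 200 paths in full designs): success
rate (%), distance (m; successes only by default, a flag includes
failures), and passage time = distance / (0.17 m s⁻¹ · 86,400 s) days,
i.e. continuous 24-h swimming. Means are reported with standard errors.

The statistics layer fits per-path binary success with a logit-link
binomial GLM (statsmodels; per-path and aggregated-proportion fits are
likelihood-equivalent — per-path chosen for simpler weighting), model
selection by backward elimination with likelihood-ratio tests at α = 0.05,
odds ratios as exp(β) with Wald intervals (default level 95%; a 97.5%
switch mirrors reports quoting that level). Complete separation is detected
from exploding coefficients and flagged, with interval reporting
suppressed. Group comparisons: Pearson chi-squared without continuity
correction (multi-group convention; configurable for 2×2), Kruskal–Wallis
with tie correction, Dunn's pairwise Z (hand-rolled: no post hoc package in
the dependency set), Holm–Bonferroni adjustment via statsmodels.
Simulation-vs-telemetry comparison is per-cell: an exact binomial test of
the cell's success count at the observed proportion, plus coverage flags
(observed rate inside the cell's binomial CI; observed mean passage time
inside the cell's t-interval).

## Pseudo-telemetry generator

Emulates per-fish tracking outcomes: Bernoulli success at a given rate,
entry dates uniform over a six-week run, and passage times for successes
from a moment-matched lognormal (right-skewed, strictly positive, SD of the
same order as the mean — the pattern in published lake-passage summaries,
e.g. 5.2 ± 4.2 d). It does not emulate detection inefficiency, tag loss,
partial migration or within-lake positions, so telemetry-comparison tests
exercise the statistical machinery, not telemetry realism.

## Numerical and performance choices

* Point-in-polygon: boundary counts as inside (closed polygon), so paths
  cannot escape via exact-boundary landings.
* Generated convex basins carry an analytic containment predicate
  (incircle-shrunk circle/ellipse/capsule, conservative with respect to the
  vertex polygon by a factor cos(π/n)), and convexity reduces the in-lake
  step test to an endpoint check. Arbitrary shorelines use a uniform
  spatial hash of boundary edges: starting strictly inside, a step stays
  inside iff its segment crosses no local boundary edge (exact orientation
  tests; river-mouth starts nudged ~1 cm inboard so the test is
  well-defined). This keeps the 16,000-path grid under ~20 s and the
  9,000-path real-lake grid under ~1 min on one CPU.
* Capture-disc arc sizing solves radius by bisection to 1% of the target
  arc, with the polygonal-circle chord-length bias corrected analytically.
* Degenerate inputs fail loudly: invalid polygons, σ < 0, caps below one
  step, empty telemetry, non-nested GLMs.

## Problem sizes

Full designs match the study: 80 cells × 200 paths (hypothetical) and 45
cells × 200 paths (real lakes). The shipped smoke profiles (20–50
paths/cell) exist for interactive exploration; all reproduction numbers in
tests and the acceptance script use full replication.

## Known limitations

* The published per-cell success levels are reproduced to within a few
  percentage points but not uniformly inside the comparison bands: with the
  adopted geometry the elliptical basin at 100 m and the circular basin at
  50 m sit ~6 and ~2 points below their bands, and the terminal-vs-lateral
  contrast ~2 points above its band. The source never states the exact
  start/end angular placements, the ellipse aspect, or the drawn shapes'
  deviations from ideal figures; those unknowns move pooled levels by
  several points, which is the scale of the residuals. The corresponding
  acceptance checks are left failing rather than fitted away.
* Real-lake runs use constructed shorelines and are qualitative only (see
  capture-semantics section).
* No Lévy or biased walks, no flow-cue navigation near the outlet, no
  time-varying σ beyond the collision rule, no swim-speed variation.
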