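# Methods

This note documents the models, parameters and numerical choices behind
`cryoscreen`, and what the synthetic benchmark does and does not show
about real data.

## The synthetic specimen

The simulator emulates a holey-film single-particle specimen on a
bar/window mesh grid. Defaults (all overridable on `SyntheticSpec`):

| parameter | default | meaning |
|---|---|---|
| `grid_pitch_um` | 90 | window center-to-center distance |
| `square_size_um` | 40 | window side |
| `hole_diameter_um` | 1.2 | film hole diameter |
| `hole_pitch_um` | 2.5 | hole lattice pitch |
| `n_tiles` | 6 | atlas is a 6 × 6 tile mosaic |
| `tile_px`, `atlas_px_size_um` | 256, 0.6 | tile raster; the mosaic then holds ~80 windows, a typical per-grid count |
| `square_px_size_um` | 0.04 | square-view raster (a 40 µm window with margin ≈ 1300 px) |
| `tile_overlap` | 0.10 | fixed; stitching is by known stage positions |
| `ice_intensity_range` | (120, 200) | gray levels attained at the extremes of the ice ramp |
| `contaminant_density` | 3 | expected contaminant blobs per square (Poisson) |
| `noise_sigma` | 2 | additive Gaussian on top of Poisson shot noise |

Gray convention: higher gray = more electron transmission = thinner ice;
"darkest" always means lowest gray. Windows render in one of six quality
classes; each class has a distinct signature (reduced bright area for
*small*, a dark fissure polyline for *cracked*, compact dark blobs ≥ 20%
coverage for *contaminated*, a near-background interior for *dry*, and
truncation by the mosaic edge for *partial* — partial windows are placed
so ~15% of their width hangs past the field). Ice thickness is a pure
linear ramp across the grid field along a configurable direction; each
hole is drawn as a uniform disk whose value is the ramp at its center, so
noiseless measurements recover the truth exactly. All randomness flows
from the single spec seed through named `numpy` generators; identical
specs produce bit-identical images.

What the simulator deliberately does **not** model: detector MTF/CTF,
beam damage, film drift blur, lens distortion, stage/camera rotation, and
non-planar ice. Passing benchmarks therefore demonstrate the correctness
and determinism of the decision pipeline under controlled, idealized
imaging — not the accuracy of any detector on real micrographs, which is
the province of learned detectors behind the same `WindowDetector` /
hole-finder interfaces.

## Detection and classification

**Squares.** The atlas (downsampled so its long side ≤ 2048 px before any
detection) is smoothed (σ = 2 px), thresholded at
`median + 0.2 · (p99 − median)`, closed with a 3-px disk (bridges
fissures), hole-filled (absorbs blobs), and labeled. Candidates outside
the 0.8–1.2 bounding-box aspect band or overlapping a larger candidate by
> 30% are suppressed. Classification tests features in a fixed order:
edge truncation → near-background interior (dry when the window level is
below bg + 0.45·(bright − bg)) → bright-region span < 0.6 of the box
(small) → compact dark components covering > 0.2 (contaminated) → an
elongated dark component ≥ 0.5 of the side in a lightly smoothed patch
(cracked) → good. Feature thresholds were calibrated once on the
simulator and live in `SquareFinderConfig`.

**Holes.** Square views are resampled to ≤ 1280 px, convolved with a
disk-minus-annulus kernel sized by the diameter prior, and candidate
peaks are local maxima of the absolute response above 3.5 robust standard
deviations with ≥ 0.3 pitch separation. A RANSAC-style fit over candidate
pairs separated by ≈ one pitch proposes square-lattice bases; the winner
maximizes inliers (ties: lowest total snap distance, then lowest
candidate ids) and inliers are snapped to the lattice (duplicates on one
node keep the best residual). Contaminants are flagged — never deleted —
when off-lattice (> 0.25 · diameter from the fitted lattice), of low
circularity (< 0.35, measured on a denoised local segmentation), or
extremely dark (> 4 robust SD below the on-lattice intensity
distribution). Because every threshold is a ratio or robust z-score,
detection and flagging are invariant under affine gray rescaling.

**Intensity.** Per-hole intensity is the median over a disk of
0.8 × radius (margin avoids the rim gradient); the even-count median is
the mean of the two central order statistics. The mean is available via
`intensity_stat="mean"` for protocols defined on average signal.

## Selection

1-D k-means with centers initialized at the `(i + 0.5)/k` quantiles of
the *distinct* values (ties cannot collapse the init), Lloyd iterations
to convergence, clusters relabeled by ascending center so cluster 0 is
always darkest/smallest. k is reduced to the number of distinct values.
Square representatives are chosen round-robin over clusters (largest
first), nearest-to-centroid first, ties by lowest id; holes round-robin
brightest-cluster first. With ≥ 2 clusters and `reject_darkest` the
entire darkest cluster is rejected before selection.
`n_holes_per_square = 0` selects every included hole (collection mode);
contaminant-flagged and rejected holes are never selectable. Random
in-hole offsets are uniform over a disk of `fraction · radius`, drawn
from a generator keyed by (policy seed, square id, hole id), so replays
command identical offsets. The rolling defocus ladder spans the
configured range (default −1.2 to −1.8 µm) in 7 even steps, wrapping by
exposure index.

## BIS planning and tilt

The planner solves a maximum-coverage disk-cover greedily: repeatedly
pick the ungrouped hole whose radius-disk covers the most ungrouped holes
(ties by lowest id); stop when the best candidate is below
`min_group_size`. This makes the plan maximal by construction (any hole
within radius of a chosen center was claimed when the center was picked).
`validate_bis_plan` independently checks radius, disjointness, minimum
size and maximality. An exact lexicographic oracle
(`optimal_group_count`, a small MILP over center choice + assignment with
per-center lower bounds) certifies on ≤ 12-hole instances that the greedy
count is within one group of optimal.

Tilt is modeled as a rigid rotation of the specimen plane about an
in-plane axis (default: the stage y-axis): height `z = v sin θ`,
in-plane foreshortening `v → v cos θ`, with `v` the signed perpendicular
distance from the axis. The 3-D rotation form (`tilt_point_3d`) is exactly
inverted by the rotation at −θ. Defocus is referenced to the group's
center hole because autofocus runs once per stage position; fitting a
plane to three corrected targets recovers (θ, axis) to numerical
precision, which the tests use as the inverse oracle. |θ| < 70° is
enforced.

## Session engine

The microscope contract is a narrow verb set (`load_grid`, `move_stage`,
`eucentric`, `acquire_*`, `autofocus`, `measure_drift`,
`set_image_shift/defocus/tilt`) behind a non-blocking single-client lock;
the only shipped implementation is the simulator-backed mock, which
injects a configurable positioning error with geometric decay (default
0.3 per corrective move) and an exponentially settling drift rate
(default 4 Å/s halving per poll). Recentering iterates view → measure →
correct, stopping below 0.1 × hole radius or failing after 3 iterations;
drift is polled until ≤ the threshold (default 1 Å/s) or timeout.
Acquired images go to a FIFO queue processed on a separate thread —
enqueue is O(1) and never blocks, so acquisition order is provably
independent of processing speed; processing fills image statistics and
leaves CTF fields as explicit placeholders (frame alignment and CTF
fitting are external tools out of scope here). A failure on one target
marks it failed and the session continues.

The session record is append-only: a sequence-numbered, timestamped event
log plus materialized STAR/JSON exports. Replays with identical config
and seeds reproduce the event sequence exactly (timestamps aside).
Partial atlases take the first `atlas_fraction ≥ 0.25` of tiles in
center-out order. "Pause between grids" is a blocking checkpoint hook
(the CLI wires it to a confirmation prompt).

## Benchmark problem sizes

The shipped benchmark (`scripts/acceptance.py`, mirrored by the test
suite) uses 20 simulated grids (~80 windows each; hole metrics on 2 good
squares per grid, ~290 holes each), 500 random planner instances of
5–200 holes with radius 2–6 µm and minimum group size 1–6 (exact-oracle
comparison on the ≤ 12-hole subset), and one full collection-mode session
plus replay on a single-grid config. These sizes give stable fleet-level
rates while keeping the whole benchmark at desk scale.

## Known limitations

* The classical detectors are calibrated to the simulator's rendering
  vocabulary; on real micrographs they are a baseline, not a claim.
* The square-lattice assumption in hole snapping handles the dominant
  film geometries but not hexagonal lattices (the basis proposal would
  need a second vector search).
* Eucentricity and autofocus are mocked as no-ops; drift and positioning
  error models are phenomenological.
* The greedy planner can exceed the optimal group count by one on
  adversarial instances; the oracle bound is only asserted for small n.
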