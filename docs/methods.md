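# Methods

This note documents the models, algorithms, parameter choices and numerical
conventions behind `fucciflow`, and what the synthetic-movie tests do and do
not demonstrate about real microscopy data.

## Coordinate and unit conventions

Images are indexed `[row, col]`; positions are `(x, y)` with `x = column`,
`y = row`, 0-based, pixel centers at integer coordinates. Time is counted in
frames. All internal computation is in pixels and frames; physical units
(µm, minutes) are applied only when exporting velocity tables, via
`KinematicsParams.px_per_um` (default 1.5385 px/µm ≈ 0.65 µm/px, typical of a
10× objective) and `min_per_frame` (default 10 min, a common acquisition
interval for collective-migration experiments).

## Synthetic monolayer model (`fucci_sim`)

The simulator exists so that every downstream stage can be validated against
known ground truth. It models the *features the pipeline is sensitive to* —
dense, persistent, trackable nuclear motion and the red→yellow→green reporter
progression — and nothing more.

**Motion.** Each nucleus performs a persistent random walk: its heading is an
exponentially smoothed mixture of the previous heading and a fresh uniform
random direction (`persistence` ∈ [0, 1], default 0.7), scaled to
`motility_speed` (default 0.5 px/frame), plus an optional uniform `drift`.
Pairs closer than `repulsion_radius` (default 16 px) push apart with a soft
linear spring (half the overlap per step, split between the pair), which
maintains monolayer-like spacing. Walls reflect. Initial positions are
rejection-sampled to be at least `repulsion_radius` apart; configurations
with `n_cells_init · repulsion_radius² > FOV²` are rejected as over-packed.

**Phase clock.** Each cell draws its COLORLESS/RED/YELLOW/GREEN durations
once, from a normal distribution with the configured means and coefficient of
variation (`phase_duration_cv`, default 0.2), rounded and truncated at 1
frame. Defaults (red 40, yellow 6, green 30, colorless 4 frames at
10 min/frame) give a ~13 h cycle — a deliberately short, desk-scale cycle,
not a calibration to any cell line. Initial cells start at a uniformly random
point of their cycle (`init_phase="random"`), so all phases coexist from
frame 0; setting `init_phase` to a phase name starts every cell at that
phase's first frame (used by the hand-traced clock tests). When GREEN expires
and `division_enabled` is set, the cell is replaced by two COLORLESS
daughters offset ±`repulsion_radius`/2 along a random axis; with division
disabled the cell lingers in GREEN.

**Reporter intensities.** Piecewise linear: the red reporter ramps 0→peak
across RED, then decays linearly to 0 across YELLOW; the green reporter ramps
0→peak across YELLOW and holds at peak through GREEN, vanishing at division.
COLORLESS emits nothing. Real cdt1/geminin kinetics are nonlinear and
cell-line specific; linear ramps are the minimal shape with the right
qualitative behaviour (faint phase onsets, bright co-expression window) and
are not presented as calibrated kinetics.

**Rendering.** Each nucleus is an isotropic Gaussian spot
(`nucleus_sigma_px`, default 3 px) with amplitude equal to its reporter
level, evaluated within a ±4σ window, plus uniform `background` (100 counts)
and i.i.d. Gaussian camera noise (`noise_sd`), clipped at zero. Stacks are
written as unsigned 16-bit multi-page TIFF.

**Determinism.** One `numpy` generator seeded from `rng_seed` drives all
draws in a fixed order (placement, per-cell clocks, per-frame headings in
cell-id order, division axes as they occur); rendering noise uses a child
seed. Identical configs reproduce byte-identical tables.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: nuclear shape anisotropy and its dynamics,
photobleaching, focus drift, intensity inhomogeneity within a nucleus,
spatially correlated background, apoptosis, and segmentation-difficulty
regimes such as genuinely overlapping nuclei. Results on real movies depend
on segmentation quality in ways these tests cannot certify.

## Segmentation

The built-in segmenter is a classical baseline: Gaussian smoothing
(`smoothing_sigma_px`, default 1.5 px) → global threshold (Otsu, or a fixed
count value) → hole filling → optional splitting of touching nuclei by
watershed on the negated Euclidean distance transform, seeded at distance
maxima at least `watershed_min_distance_px` apart → removal of components
smaller than `min_area_px2`. A constant frame under Otsu yields an empty
mask by convention. Label masks produced by external tools (e.g. a trained
neural segmenter) can be loaded instead and are passed through verbatim;
the rest of the pipeline is agnostic to their origin.

Per-label measurements: unweighted pixel centroid, pixel-count area, mean
intensity, and the 0.5-level sub-pixel contour (longest contour of the
padded label mask) whose polyline length is reported as the perimeter.
Contour-based perimeters are convention-dependent; tests rely on areas and
centroids, which are not.

## Tracking

Frame-to-frame linking is a minimum-total-cost one-to-one assignment
(Hungarian algorithm, `scipy.optimize.linear_sum_assignment`) on Euclidean
centroid distance, with links beyond `max_link_distance_px` (default 15 px)
forbidden. Cost is distance only; no intensity or size term. A second
assignment over fragment ends and starts closes gaps of up to
`max_gap_frames` missed frames (default 2) within `max_gap_distance_px`;
chains of merges are followed transitively. Tracks shorter than
`min_track_length` detections (default 3) are dropped. Track ids are ordered
by (start frame, y, x of the first detection), making runs deterministic;
assignment ties are resolved by the solver's deterministic order.

Defaults suit the simulator's 10×/10-min-like regime (sub-diameter motion
per frame); they are starting points for real data, not reproductions of any
published tracker settings. Division is deliberately *not* handled by track
splitting: the green track simply ends at mitosis and daughters start new
colorless→red records, so lineage is out of scope.

The TrackMate-XML importer reads the `Spot` (ID, FRAME, POSITION_X/Y) and
`Edge` (source, target) subset, in pixel units, and rebuilds tracks as
connected components of the edge graph; everything else in the file is
ignored. A minimal exporter writes the same subset for round-tripping.

## Track fusion and the G1→S call

The pairing pipeline is pre-filter → similarity → matching → fusion.

**Grid pre-filter.** The FOV is split into `grid_n` × `grid_n` half-open
squares (`grid_n` = 10; boundary points belong to exactly one square, the far
FOV edges close onto the last square). A red/green pair survives iff some
square was visited by both tracks at any time. This is purely a computational
filter: with well-separated cells it provably never removes a pair the
similarity threshold would accept, and the test suite checks equivalence
against brute-force all-pairs matching on randomized instances.

**Similarity.** S_ij is the mean Euclidean center distance over the frames
*both* tracks cover. Averaging over temporally overlapping frames (rather
than whole lifespans) is the only well-defined reading here, because the two
tracks of one cell coexist only around G1/S. Frames closed by gap closing
contribute linearly interpolated positions. Pairs overlapping fewer than
`min_overlap_frames` (default 2) frames are discarded, guarding against
1-frame coincidences.

**Matching.** Pairs with S_ij strictly below `similarity_threshold`
(default 2 px, appropriate at 10×; scale it with magnification) are accepted
greedily in ascending S_ij with ties broken by lower red id then green id,
under a one-to-one constraint. Greedy-by-score is deterministic and agrees
with the minimum-total-score maximal matching in the non-degenerate cases
tested; a full optimal matching was not adopted because real conflicts at
sub-threshold distances are rare and the greedy rule is easier to audit.

**Fusion.** Phase per frame: RED where only the red track covers the frame,
YELLOW where both do, GREEN where only the green does — so the YELLOW window
is exactly the co-detection window. Fused position is the covering track's
centroid, or the mean of both centroids on YELLOW frames (keeps the
trajectory continuous and channel-symmetric; the choice is invisible to
phase calling). Morphology is carried per channel where observed. Unmatched
tracks become single-phase cells rather than being dropped, so tissue-level
counts see every detected nucleus.

**G1→S.** The transition frame is derived from the YELLOW window alone:
its first frame, its floor midpoint (default), or its last frame. This
replaces any user-chosen intensity cutoff; the midpoint is a convenient
point estimate for event-time analyses, while start/end bound the window.

## Tissue-level analysis

**Voronoi areas.** Cell footprints are approximated by the Voronoi regions
of all nucleus centers (both channels pooled), clipped to the FOV rectangle.
Clipping is exact: every seed is reflected across the four FOV edges before
the tessellation, so the bisector between a seed and its mirror *is* the
edge, interior regions are finite convex polygons, and per-frame areas sum
to the FOV area to ~1e-9 relative tolerance. Duplicate centers (< 1e-9 px
apart) raise an error naming the frame. Regions touching the boundary are
flagged `is_border` and excluded from area statistics by default — the
footprint approximation is only trustworthy for confluent, interior cells.
Degenerate care: region vertices are ordered by angle about their mean
before polygon construction.

**Velocities.** Per-track tangential velocity is the forward difference
v(t) = (r(t+1) − r(t))/Δt across gap-closed positions; the last frame
carries the previous vector so every frame of a ≥2-frame track has one.
The Eulerian field averages these vectors in square bins of side
`bin_side_fraction` × FOV (default 1/10) centered on a triangular lattice:
full rows of n = 1/`bin_side_fraction` points (in-row spacing FOV/10)
alternating with offset rows of n−1 points shifted by FOV/20, rows FOV/20
apart, the whole lattice centered in the FOV — 10×10 + 9×9 = 181 points by
default. The in-row spacing must be twice the row spacing for this
alternating construction to close at 181 points; "equilateral" is nominal
(a strictly equilateral lattice with FOV/20 sides cannot tile a square FOV
into 181 points). Bins deliberately overlap (side 2× the point spacing) —
the overlap is smoothing, not a bug; empty bins are flagged undefined, never
zero-filled.

**Summaries.** Phase counts per frame are cell counts by fused phase label,
with fractions normalized by the per-frame total. Mean Voronoi area per
phase carries a 95% CI of the mean, mean ± 1.96·sd/√n (normal
approximation, sd with ddof = 1); n < 2 yields an undefined CI rather than
a zero-width one. The CI method is recorded in the table's header comment.

## Pipeline and reproducibility

All intermediate artifacts are plain CSV (with `#` header comments naming
units and the coordinate convention) or TIFF, so each stage can be replaced
or inspected independently. A JSON manifest (config echo, package version,
seed, artifact row counts) accompanies every run. Identical config + seed
reproduce byte-identical tables; CSV floats are written at 6 decimals, so
resuming a run *from its own CSV artifacts* reproduces values to that
precision rather than to machine precision.

## Problem sizes used in the test suite

The validation suite runs entirely on simulated data: ground-truth pairing
recovery uses a 200-cell, 60-frame, 512-px movie without noise (the safe
regime: spacing ≳ 20 px, motion ≲ 2 px/frame); pre-filter/brute-force
equivalence uses 30 randomized instances of up to 50+50 tracks; determinism
and CLI tests use 10–30-frame movies of 8–60 cells. These sizes exercise
every code path at desk scale; nothing in the implementation is specific to
them.

## Known limitations

- Pairing assumes at least `min_overlap_frames` of co-detection; cells whose
  co-expression window falls entirely between frames (very fast transitions
  or long acquisition intervals) cannot be paired.
- The greedy matching rule can in principle differ from a globally optimal
  assignment when several sub-threshold candidates conflict; with the
  default 2 px threshold and non-overlapping nuclei this was never observed
  in testing.
- Voronoi areas are meaningful only in confluent regions; border cells are
  flagged, not corrected.
- The classical segmenter is a baseline: on low-contrast or overlapping
  nuclei a trained segmenter (loaded via the external-mask path) should be
  preferred.
- No lineage: mother/daughter identity across division is recorded only in
  the simulator's ground truth, not recovered by the pipeline.
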