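# Methods

This note documents the models, conventions, numerical choices and
limitations behind `cellaxis`. It describes what the code computes; every
empirical statement here is reproduced by the test suite or by
`scripts/acceptance.py`.

## Coordinate convention

All geometry is in pixel units with 0-based indices, pixel centers at
integer coordinates, and y increasing downward (image convention).
Importers of 1-based sources (MATLAB-derived tables, MAT cell lists,
1-based slice numbers) subtract the base on import; the convention of a
table is declared in its metadata and `build_dataset` refuses mixed
conventions rather than guessing. Physical units enter only through the
optional `pixel_size` (µm/px) and `time_interval` (s) metadata at
presentation time — keeping analysis in pixels avoids silently mixing
calibrations when merging datasets from different microscopes.

## Cell frame: minimum-area bounding box

A cell's internal frame is its minimum-area enclosing rectangle, computed
over the convex hull of the outline polygon. By the rotating-calipers
property the optimal rectangle is aligned with a hull edge, so the
implementation scans hull-edge orientations only; an exhaustive 0.01°
rotation scan serves as the independent oracle in the acceptance checks.
Minimum *area* (not minimum width) was chosen because it is the standard
calipers object and behaves well for rod-shaped cells; a medial-axis
("curved centerline") coordinate system is deliberately out of scope —
length-axis coordinates come from the rectangle frame.

Ties deserve care. For a triangle, *every* edge-aligned box has area
2·(triangle area), and for squares four orientations tie. Area ties (within
1e−9 relative) are therefore broken first toward the box of largest length
— a rotation-invariant choice, so (length, width) do not depend on how the
image was oriented — and then toward the length-axis angle of smallest
absolute value, so an axis-aligned square reports 0° rather than −90°.
Angles are reported in degrees in [−90, 90).

`orient_mesh` applies the rigid motion R(−θ)(x − c): a pure
rotation+translation, so polygon area is preserved to floating-point
accuracy (checked to 1e−9 relative) and the oriented outline has x-extent
= length and y-extent = width with its box center at the origin.

## Spot/object/pixel relativization

Containment uses the even-odd rule with the boundary counting as inside
(a closed polygon), so foci detected on the membrane are deterministically
kept. When several outlines contain a spot — touching cells in chains are a
known segmentation difficulty — the spot goes to the cell with the nearest
box center and is flagged `ambiguous` rather than discarded, preserving
auditability. Cells whose polygons fail the simple-polygon test are
skipped, logged and counted, never repaired: silent geometry repair would
bias downstream size statistics. The across-axis sign (d > 0 toward rotated
+y) is a pure convention; no biological polarity is implied, and kymographs
instead maintain pole consistency over time by choosing, per frame, the
profile orientation (as-is or mirrored) closer in L2 distance to the
previous frame.

Spot counts are conserved by construction: assigned + unassigned = input,
and every `cell_id` in `spots_relative` must exist in the meshframe
(validated on assembly and after loading).

## Data model and persistence

The standard containers are: per-cell outlines with box fits and oriented
vertices (meshframe), foci in image coordinates (spotframe) and in
cell-internal coordinates (spots_relative), fluorescent-object outlines
(objectframe), tidy per-frame track tables, image stacks, and `cell_list` —
the original input tables preserved verbatim per source, so standardization
never loses upstream information. Multi-channel spot tables keep `channel`
as a column; channels are never merged.

Datasets persist as one comma-separated UTF-8 table per frame type plus a
plain-text manifest with a SHA-256 checksum per file; floats are written
with 17 significant digits and read back with round-trip parsing, so
save→load is the identity on all numeric fields. Missing or tampered files
fail loudly (`CorruptDataset`). Native cell ids survive import unchanged —
required for the importer/writer round-trip property — and a
`compose_cell_id(source, frame, native)` helper produces globally unique
ids when datasets from several programs are merged.

## Importers

One generic delimited-table importer covers meshes, spots, objects and
tracks through a `ColumnMapping` (standard field → source column, plus the
coordinate base). Mappings for MicrobeJ, SuperSegger, Morphometrics and
ObjectJ exports ship as editable plain-text presets; the exact header names
of those exports vary between versions, so the presets are documented
starting points rather than guarantees, and any export can be adapted by
editing a copy. Two structured dialects get bespoke parsers: MAT v5 cell
lists whose per-cell mesh is an N×4 array of paired left/right contour
points — converted to a single polygon by walking the left contour and
returning along the reversed right contour, dropping the duplicated pole
points (2N−2 vertices) — and single-molecule spot tables with 1-based slice
numbers and trajectory ids. The MAT variable name is configurable (default
`cellList`) because cell-list layouts changed across segmentation-program
versions; both the struct-with-`meshData` and bare per-frame cell-array
variants are parsed, from the unsqueezed MAT object tree (scalar squeezing
makes one-frame files ambiguous).

## Time-lapse analysis

Cell length is the division proxy: a division is called between frames t
and t+1 when length(t+1) ≤ (1−δ)·length(t). The default δ = 0.25 reflects
that a division halves the length (a 50% drop), so a 25% threshold
tolerates observation noise while staying far above growth fluctuations;
it is configurable, and explicit genealogy from the upstream tracker
overrides length-based calls. Percentage-of-division interpolates linearly
in wall-clock time — not frame index — from 0 at the birth frame to 100 at
the division frame, honoring uneven sampling. A cycle is complete only if
both endpoints were observed; a track's first cycle counts as complete only
when the track is known to start at birth (`first_frame_is_birth`, or
genealogy). Incomplete frames keep NaN percentages and are excluded from
cycle statistics but retained in the dataset.

Track filtering discards, in order of precedence: non-growers (maximum
length over the cycle / birth length below 1.2; whole-track ratio when no
complete cycle exists), tracks without a complete cycle, and tracks below a
mean-fluorescence floor. Reasons are recorded per track and counted.
Percentage binning uses [0,10), …, [90,100] so that exactly 100% falls in
the last bin. Lineages are validated as forests (≤2 daughters, no cycles)
and exported as Newick with branch lengths equal to cycle durations in
seconds.

## Profiles and clustering

Axis profiles split l_rel ∈ [−0.5, 0.5] into equal bins (default 25) and
average pixel intensities per bin; bins left empty by the pixel grid are
linearly interpolated from populated neighbors and flagged. The
cells × percentage matrix interpolates each cell's mean fluorescence to a
0–100 grid (101 points) from its first complete cycle; grid points outside
a cell's observed range take the nearest observed value and are flagged as
extrapolated; cells with fewer than two annotated frames are excluded and
logged.

The default dissimilarity is Euclidean distance between z-normalized rows
(1 − Pearson r is available; z-normalization plus Euclidean emphasizes
profile *shape* over absolute intensity, which is what separates
association/dissociation dynamics), and the default linkage is average.
Both are configurable because no single published choice exists for this
analysis; the cluster *procedure* — dissimilarity matrix, agglomerative
clustering, cut at k, summaries as mean ± sd profile and cell fraction per
cluster — is the fixed part. Labels are renumbered by decreasing cluster
size for stable reporting.

## Synthetic data

The generator produces exactly the study conditions the analytics are
designed for, with truth recorded for every quantity:

* outlines: rods (rectangle + semicircular caps, with a vertex placed
  exactly on each pole so box fits recover length to <1%), cocci (circles)
  and ovococci (ellipses), placed on a grid that precludes overlap;
* images: background + Gaussian point-spread per spot, optional Poisson
  shot noise; a sweeping-band movie (Gaussian band moving from mid-cell to
  the quarter position, the motion of divisome/replisome markers between
  divisions) for kymograph checks;
* tracks: exponential growth L(t) = L_birth·e^{gt} with g = 0.01/min,
  equal-daughter division at L_div, multiplicative observation noise of 3%,
  2-minute frames over 4 hours, and a planted 10% of non-growers — the slow
  time-lapse regime in which length-based division detection is meant to
  operate. L_div = 40 px (~2.6 µm at 0.065 µm/px) sets a realistic
  ovococcus scale;
* profile cohorts: three archetypes of fluorescence over the cycle
  (a pre-division dip that recovers, a gradual decline, a late drop) with
  additive noise defaulting to 10% of the minimum L2 separation between
  archetype curves.

All randomness flows through NumPy's seeded PCG64 generator; regeneration
is bit-identical per seed. What the generator does *not* emulate: realistic
optics (no Airy PSF, no camera gain), segmentation errors (outlines are
exact), cell crowding/chaining, asymmetric division (exposed as a
parameter, default symmetric), or photobleaching. Passing tests therefore
demonstrate the correctness of the *computations* under clean conditions —
recall and false-call rates on real data depend on segmentation quality
upstream, which this toolbox deliberately does not model.

## Problem sizes and numerical tolerances

Acceptance-scale checks use 500–1000 random polygons against the 0.01–0.02°
scan oracle, >10⁵ containment pairs, 10⁴ relativization round-trips
(1e−9 px), 500 noisy tracks for division detection, and 150 cells for
clustering recovery — sizes at which every oracle comparison is exhaustive
yet the whole suite runs in seconds. Bounding-box tie tolerance is 1e−9
relative; persistence round-trips are exact (17-digit floats); kernel
density bandwidth defaults to one grid bin width, which keeps the numeric
integral within ~2% of 1 on the default grid (truncation at the grid edge
accounts for the rest).

## Known limitations

* Length-axis coordinates come from the bounding-box frame; strongly curved
  cells would need a medial-axis system, which is out of scope.
* Division detection assumes a track follows one cell line; it does not
  re-derive genealogy from image overlap (the upstream tracker's job).
* Preset column names for MicrobeJ/SuperSegger/Morphometrics/ObjectJ
  exports are best-effort and may need editing for specific versions.
* No model-based (mixture) clustering and no dynamic-time-warping
  dissimilarity; no interactive or animated output.
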