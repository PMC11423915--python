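# Methods

This note documents the measurement model behind `kelpmorph`, the choices
made where the procedure was genuinely open, and what the synthetic-data
tests do and do not establish about real segmentations.

## Input model

The sample unit is a *lamina*: one embryo at one time point, represented as
a set of closed cell-wall contours traced by hand in a vector editor and
saved as plain SVG. Each cell is its own closed outline, so the wall between
two adjacent cells appears twice in the file. Only straight-line elements
are accepted (`path` with M/L/H/V/Z, `polygon`, `rect`); anything else is
skipped with a warning, and an open path is an error naming the element,
since a silent skip would change the cell count. Physical calibration
(µm per drawing unit) always comes from the experiment manifest, never from
SVG metadata, which hand-edited files cannot be trusted to carry. On ingest
the y-axis is flipped (SVG y grows downward) and contours are normalised to
counter-clockwise orientation; consecutive vertices closer than 1e-9 µm —
tracing artefacts — are merged.

## Cell shape descriptors

Area and perimeter come straight from the shoelace formula and edge lengths.
The minimal bounding rectangle (MBR) of the convex hull is computed by
rotating calipers: the minimum-area enclosing rectangle has a side collinear
with a hull edge, so scanning hull-edge orientations is exact; orientations
whose areas tie within 1e-9 *relative* resolve to the smallest angle in
[0, π) — a relative tolerance, so the deterministic choice is invariant
under uniform scaling of the input. The
cell's main axis and elongation (l/w ≥ 1) are those of the MBR; a square MBR
has elongation 1.

**Rectangularity** measures how close an outline is to a perpendicular-sided
quadrilateral. The MBR is rescaled uniformly about its own centre to the
cell's area, and the score is area(cell ∩ scaled MBR) / area(cell). Two
readings of "rescaled to the same area" are possible — scaling the cell or
scaling the rectangle; we scale the rectangle, which leaves the measured
object untouched, and under either reading a true rectangle scores exactly
1. The score is invariant under rigid motions and uniform scaling and lies
in (0, 1]. Geometric predicates use an absolute tolerance of 1e-9 µm,
orders of magnitude below hand-tracing precision.

## Tissue topology

Two cells are neighbours when they share at least `min_shared` = 0.2 µm
(200 nm) of wall; the threshold is a configuration parameter. Because
duplicated hand-traced walls are nearly but not exactly coincident, shared
wall is measured with a proximity tolerance (`proximity_tol`, default
0.05 µm): the portion of one cell's boundary within that distance of the
other's is found, then *projected onto* the other boundary, and the length
of the projection is summed (on the circular ring parameter, with each
increment capped by the sampling step, since projection onto a curve is
1-Lipschitz). Projection is what makes corners honest: near a shared corner
short stretches of unrelated walls come within tolerance, but they project
to a point and contribute no length, so two unit squares sharing a full edge
measure exactly 1 µm. The two directed measurements are averaged, making the
measure symmetric. Accuracy is of the order of the proximity tolerance, far
below the 200 nm edge criterion. Candidate pairs are pruned by expanded
bounding boxes; the pruning cannot change the result and is verified against
brute force in the tests.

## Blade measurements

The blade region is the union of the cell polygons (duplicated walls
therefore never double-count). Orientation comes from the second-order area
moments of the union: the principal directions of the area covariance
matrix. Axis *lengths* are the extents of the union projected onto the
principal directions — an extent-based reading of "length and width" that
makes the blade l/w ratio a quotient of projected extents, with main ≥
secondary enforced by comparing extents. Developmental windows are closed
intervals in cell count, [20:47], [48:103], [104:307]; anything outside is
labelled "other".

Division-plane orientation is classified relative to the blade main
(apico-basal) axis with the relative angle folded into [0°, 90°]: within
`oblique_band` (default 30°) of parallel is longitudinal, within the band of
perpendicular is transverse, otherwise oblique. The band is configurable
because observed divisions cluster tightly at the two poles, so the
classification is insensitive to the exact width.

## Growth rate

Counts are aligned so t = 0 is the first longitudinal division (the phase
I→II transition); which observation that is must be flagged in the input,
keeping orientation inference out of the regression. Ordinary least squares
of log N on t over −48 h ≤ t ≤ 72 h (endpoints included; natural log
internally — the result is basis-independent) gives the multiplicative rate
r = e^slope and doubling time τ = 1/log₂(r). A non-growing series (r ≤ 1)
reports τ = ∞ with a warning and is excluded from group means with a logged
count. Fits are per embryo; group summaries average the per-embryo τ.

## Statistics

Cell-level scalars are compared with Welch's unequal-variance t-test
(Welch–Satterthwaite df); blade-level scalars with the two-sample
Mann–Whitney test, exact by enumeration when the combined sample is ≤ 12
(blade groups are 4–6 embryos) and the tie-corrected,
continuity-corrected normal approximation otherwise; neighbour counts with
Pearson's χ² (no Yates correction) on bins {1, 2, 3, 4, ≥5}, with bins empty
in every group dropped (warned) and a zero expected count an error advising
further pooling. All tests are two-tailed. No multiple-testing correction is
applied; the run log records the number of comparisons so readers can adjust
if they wish. If both samples to the Welch test are constant the statistic
is degenerate; equal means report p = 1, unequal means p = 0. The binomial
screen is closed-form: P(all n normal) = (1−p)ⁿ, E[abnormal] = n·p.

## Synthetic data: what it emulates and what it does not

The grid generator tessellates rows × columns of quadrilateral cells
(default cell side 8 µm, a typical early-embryo cell size) with per-vertex
jitter expressed as a fraction of the cell side (< 0.5 keeps every cell
simple), optional anisotropic stretching to a target blade l/w, and an
optional elliptical mask. Jittered lattice vertices are shared by adjacent
cells, so duplicated walls are *exactly* coincident — slightly cleaner than
hand tracing, which the proximity tolerance absorbs. Ground truth (areas,
adjacency, grid combinatorics, blade extents) is derived from the
construction, not from the measurement code.

The division simulator grows a tissue on a unit lattice: cells divide after
gamma-distributed cycle times (mean 26 h; CV 0.2 by default), daughters are
placed at ±y for transverse and ±x for longitudinal planes, and occupied
sites are shoved outward, keeping a compact monolayer. The first division is
always transverse; longitudinal divisions are permitted from 8 cells in
intact mode and from 2 cells in severed mode, then chosen with probability
0.5 (the onset rule is biological, the rate is a modelling choice since only
the onset is characterised). Oblique planes are never generated. For gamma
cycle times the population growth rate follows the Euler–Lotka relation
E[e^(−λT)] = 1/2; at CV 0.2 the population doubling time is ≈ 25.6 h, i.e.
within a few percent of the mean cycle time, which is why recovered τ values
sit near 26 h. (With exponential cycle times the same relation gives
doubling ≈ 18 h — a well-known property of Markov birth processes — which is
why the simulator uses low-CV gamma clocks rather than exponential ones.)
Snapshots carry a small shared-vertex shape jitter (12% of the cell side) so
per-cell metrics have realistic variance.

These tissues reproduce the *direction* of the biological contrasts — intact
simulations are more elongated than severed ones at matched cell counts, and
have relatively more 3-neighbour peripheral cells — but no attempt is made
to fit the simulator to measured magnitudes. Passing tests therefore
establish correctness of the measurement operators and the direction of the
phenotype readout, not quantitative agreement with any particular dataset.
Features of real segmentations that the generator does not emulate: curved
walls, tracing gaps/overlaps beyond the coincidence tolerance, z-projection
distortion, and lineage relationships between time points.

## Problem sizes and numerical choices

Test oracles: Monte Carlo rejection sampling at 10⁶ points (agreement within
3 standard errors), a dense MBR orientation sweep of 10⁵ angles with local
refinement around the kinked minimum, O(n³) hull scans, and exhaustive
Mann–Whitney enumeration. Simulation-based checks use 20 matched seeds at
~60-cell embryos and 2,000-replicate null calibrations; these sizes give
stable verdicts while keeping the default suite fast.

## Known limitations

* The blade main axis is an operational apico-basal axis; the stalk itself is
  not present in segmentations, so basal polarity (which end is the stalk) is
  unresolved — only the axis direction modulo π is used.
* Shared-wall lengths are accurate to roughly the proximity tolerance; walls
  shorter than ~2× the tolerance are unreliable (but fall below the 200 nm
  neighbour criterion anyway).
* The χ² neighbour-count comparison pools at ≥5; very large cells with many
  neighbours are not distinguished.
* Growth fitting assumes a single exponential regime across the fit window;
  growth arrest inside the window biases τ upward.
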