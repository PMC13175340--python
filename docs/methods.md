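# Methods

## The model

`topogaze` analyses a greyscale image as a filtered cubical complex
(V-construction): every pixel is a vertex carrying its intensity, edges join
4-neighbours, and each 2×2 pixel block carries a square; a cell enters the
filtration at the maximum of its vertices.  Two filtrations are computed per
image: **BW** (raw intensities — dark structure enters first) and **WB**
(inverted, `255 − Y` — bright structure enters first).  Persistent homology in
dimensions 0 (connected components) and 1 (holes) records, for each class, the
level at which it appears (birth) and disappears (death).

The greyscale conversion is the CCIR-601 luma, `Y = 0.299R + 0.587G + 0.114B`,
rounded half-up once, so downstream computations always see an integer lattice
on the 256-level scale.  Values are kept as integers throughout (an explicitly
documented convention: a float-valued filtration would shift cycle counts
marginally by splitting plateau ties).

### Algorithms

*Dimension 0* is a union-find sweep over edges in increasing value with the
elder rule: at a merge, the component with the smaller birth survives; ties
break by the lexicographically smallest pixel of the birth plateau.  The
representative of a class is its birth plateau — the connected set of pixels
at the birth level.

*Dimension 1* uses the planar dual: a hole of the sublevel complex is a
bounded complementary region, i.e. a connected set of absent squares (plus
the unbounded outer face) where two faces communicate through an absent edge.
A reverse union-find over faces, processed in decreasing value, yields each
hole's bar: the forward birth is the dual-edge level at which the region
merges into an older one, the forward death the region's maximal square
value.  The representative recorded at birth is the closed loop of lattice
edges bounding the hole region (which is the hole's maximal extent at birth);
the hole's pixel support is kept alongside for spatial matching.  Both passes
are validated per test run against an independent textbook boundary-matrix
reduction over Z/2 (`topogaze.reduction`), kept deliberately separate from
the production path.

Zero-persistence pairs are dropped.  The single essential dimension-0 class
(a full image grid is connected) is reported with its death capped at 255 and
an `essential` flag.  Output ordering is deterministic:
`(dim, birth, death, anchor)`.

### Summaries

Bars are right-open `[b, d)`; the essential bar is counted alive through
level 255 inclusive.  With a unit step per level, the integrated Betti number
`β̄ = Σ_f β(f)` then equals the total persistence of all bars (the essential
bar contributing `256 − b`), which keeps the ADV statistic well defined even
for a constant image.

Persistence landscapes are evaluated on a half-integer grid over `[0, 255]`
(511 points).  Tent functions of integer bars — and every k-th pointwise
maximum of such tents — are piecewise linear with breakpoints on that grid,
so trapezoidal integrals (landscape areas, L1 distances) are **exact**: a
single bar `(b, d)` has area `(d − b)²/4` to machine precision, including
odd-length bars whose peak falls between integer levels.  This is a
deliberate refinement of the nominal 256-point intensity scale.  The default
landscape threshold keeps bars with persistence strictly greater than 5
intensity levels; it applies to landscapes and group summaries only, never to
raw pair lists.  A flag (`essential` bars enter with capped death) and the
`min_persistence=0` escape hatch cover the alternative conventions.

The group permutation test uses the L1 distance between group-mean
landscapes as its statistic (several statistics are defensible here; this
choice is documented and swappable), with
`p = (1 + #{permuted ≥ observed}) / (n_perm + 1)` and a default of 10 000
label permutations.  Hedges' g uses the standard small-sample correction
`J = 1 − 3/(4(n_x + n_y) − 9)`.

### Alexander duality and ADV

For these complexes, dimension-1 classes of one filtration inject into
dimension-0 classes of the reverse filtration with equal persistence; the
exceptions are cycles that comprise or interact with the image frame.  Two
consequences are implemented and tested:

* **Partition identity** — at dual levels `(f, 254 − f)` the 4-connected
  components of the sublevel set and of its complement partition the pixel
  grid, so `n_partitions = β₀(f) + β₀′(254 − f)`; verified by direct
  labelling against the persistence-derived Betti curves.
* **ADV** — `ADV_BW = (β̄₀^BW − β̄₁^WB) / mean(β̄₀^BW, β̄₁^WB)` and its
  BW↔WB counterpart.  It is 0 under perfect duality, is always nonnegative
  (the dimension-0 area dominates), and attains its maximum of 2 on a
  constant image, whose reverse dimension-1 curve is identically zero.

The explicit matching (`match_dual_pairs`) exists to *test* the theory — ADV
never depends on it.  It greedily pairs dimension-1 bars to reverse
dimension-0 bars by descending persistence, requiring equal persistence and
spatial overlap between the dimension-0 birth plateau and the dimension-1
hole region.  The essential dimension-0 class needs special handling: its
death is a cap rather than an event, so strict persistence equality would
orphan it (and its dual) whenever the background sits below 255.  It is
instead matched through the duality index correspondence
`death₁ = 255 − birth₀` (plus overlap), which reduces to persistence equality
exactly when the background is white.  This rule was fixed by brute-force
validation on small instances rather than trusting an index formula, because
the exact birth/death correspondence depends on open/closed threshold
conventions.

### Feature maps

Feature maps summarise dimension-1 cycles (from both filtrations — by
duality, little is lost) on a mesh of non-overlapping windows, 50 px by
default.  Three descriptors: cycle density (count), maximal persistence, and
maximal cycle perimeter (number of distinct pixels on the representative
loop).  The cycle→window assignment is a documented convention, since
"number of cycles in a window" must not double-count while "any cycle lying
within the window" implies spatial overlap: density anchors each cycle to
the window containing its representative's bounding-box centroid; the two
max descriptors contribute to every window the loop touches.  Composite maps
sum densities and take cellwise maxima.  Ragged right/bottom windows are
kept at partial size and can be dropped (`values(drop_ragged=True)`); for
cross-window-size comparisons, `per_unit_area()` divides by the true pixel
area of each window.

### Gaze heatmaps and weighted ECDFs

Fixations lasting more than 75 ms deposit duration-proportional mass at
their (clamped) pixel position; the deposit image is smoothed with an
isotropic Gaussian and normalised to unit sum.  The kernel width defaults to
σ = 50 px (about one grid window) and the "not-looking" region is the set of
windows whose gaze weight is at most 5 % of the maximal window weight —
both are package conventions exposed as configuration, and both are echoed
into every batch run's `config.json`.

A feature map plus a weight field (uniform, gaze, or complement) yields a
weighted ECDF; pairs of ECDFs are compared on their merged supports by MSE,
signed mean error (ME) and the KS statistic.  **Sign convention:**
`me_ecdf(e_looking, e_not_looking) > 0` means the looked-at regions carry
*higher* feature values (the looking ECDF lies below and to the right); the
implementation computes `mean(e_not − e_looking)` and pins the convention
with a one-atom unit test.

## The synthetic generator

`topogaze.synthetic` renders scenes whose exact barcodes are known by
construction: hard-edged axis-aligned primitives (disk, rectangle, annulus,
frame-crossing stripe) at exact integer intensities on a constant
background, separated by at least one background pixel.  A dark blob of
intensity `p` on background `b` yields a BW dimension-0 bar `(p, b)` and,
unless frame-touching, a WB dimension-1 bar `(255 − b, 255 − p)` — its dual.
An annulus adds the dual hole pair in the other orientation.  A
frame-crossing stripe splits the background and has no dimension-1 partner
in either filtration: each stripe raises the unmatched count by exactly one
on both sides.  The generator's `GroundTruth` lists every expected bar, and
the suite asserts bit-exact agreement with the computed persistence — the
module's core contract.

The speckle texture scatters non-overlapping 2×2 dark squares (one-pixel
halo, so each is an isolated component/hole).  Its default spatial law is a
*stationary random-rate* process: acceptance follows a smoothed-noise rate
field with a long correlation length, producing patches of dense texture
next to smooth regions.  This emulates the salient property of pictorial
texture that motivates feature maps in the first place — richly textured
areas have many cycles per unit area, smooth areas few.  A homogeneous
scatter (`patchiness=0`) is also available, but note that per-window density
of a homogeneous field has a sampling standard deviation inversely
proportional to the window side, so its density ECDFs at window sizes 51 and
101 differ by a KS distance of ≈ 0.16 *by construction*; window-size
stability of density ECDFs is a property of spatially heterogeneous texture,
and the robustness check therefore uses the patchy default (1020 px scene,
10 000 speckles, 400 px correlation length — sizes chosen to mirror the
~1080 px stimuli and tens-of-cycles-per-window densities the method targets).

Synthetic fixations pick a window with probability ∝ `(1 + value)^bias`,
uniform position within the window and uniform duration, deterministically
per seed.  `bias = 0` is uniform scanning; large bias degenerates to the
argmax window.

What the generator does **not** emulate: anti-aliased or noisy edges (an
optional noise stage exists but marks the ground truth approximate),
photorealistic content, saccade dynamics, or observer idiosyncrasies.
Passing tests therefore certify the machinery — exactness of the homology,
duality bookkeeping, statistical plumbing — not any empirical claim about
real paintings or real observers.

## Problem sizes and numerical choices

The test suite runs everything at desk scale: oracle comparisons on 8×8
images (100 per run), duality and partition properties on up to 96×96
scenes, the gaze closure on a 300×300 scene with 100 seeded replicates, and
the window-robustness check on a single 1020×1020 textured scene.  The
union-find passes are near-linear, so a 1-megapixel image takes seconds in
pure Python; representative extraction can be switched off
(`representatives=False`) where only bar multisets are needed.

Degenerate inputs are defined, not avoided: a constant image has one
essential bar and ADV exactly 2; a 1×N image has no squares and hence no
dimension-1 classes; an empty fixation list (or none above threshold) yields
a flagged all-zero heatmap that weight functions refuse; a gaze field
covering every window has no complement and raises.  Ties are resolved by
fixed lexicographic orders everywhere, making every output — including the
CLI's batch tables — byte-reproducible under a fixed seed.

## Known limitations

* Dimension-1 representatives are the hole boundary at birth, not minimal
  cycles; representatives are not unique, and perimeter values depend on
  this convention.
* The dual-matching rule for the essential class is a convention calibrated
  on small instances, not a theorem-backed index formula.
* ADV on very small images is dominated by the essential bar's `256 − b`
  contribution; comparisons across images assume comparable sizes.
* The permutation test statistic (L1 between mean landscapes) is one of
  several defensible choices; swapping it changes p-values.
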