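# Methods

This note documents the models, conventions and numerical choices behind
`plotalign`, and what the synthetic fixtures do and do not establish.

## Observation domains

A domain holds the ids shown on one discrete layout axis, a display order
(permutation of `0..n-1`), an optional grouping, and lock flags. Invariants
enforced on every mutation: ids unique and non-empty; the order is a valid
permutation; grouped observations occupy contiguous display positions with
group blocks in `group_order`. `set_groups` performs a *stable partition*
of the current display order — within-group relative order is preserved and
the default group order is first appearance in the prior display order.

Conflict policy: a locked order or grouping rejects any differing request
with an error (`DomainConflictError`), naming both sources when the clash
arises during unification; *unlocked* differing impositions resolve
last-writer-wins with a logged warning. The engine therefore never renders
two aligned panels with silently different orders. Whether a later unlocked
reorder should override an earlier one is genuinely open; log-and-override
was chosen because it keeps interactive layout building forgiving while the
lock flag provides strictness on demand.

Positions: observation at display position *i* of *n* occupies
`[lo + i·w, lo + (i+1)·w)` with `w = (hi−lo)/n`; intervals are half-open and
tile the extent exactly (tested to 1e-12). Figure coordinates are
normalized to `[0,1]²`, origin bottom-left. On the **y axis the display
order runs top-down** (matrix reading order, row 0 at top); dendrogram and
link coordinates depend on this convention and use the same helpers, so the
flip cannot drift between subsystems.

## Agglomerative clustering

The agglomeration is the Lance–Williams recurrence on a full dissimilarity
matrix (Euclidean metric, or a precomputed matrix). Supported linkages:
single, complete, average, ward.d2. For ward.d2 the working distances are
squared and reported heights are square roots, so two singletons at
distance *d* merge at height *d*. Tie-break: among minimal-distance active
pairs, merge the pair with the lowest first node index, then lowest second
(leaves `0..n-1`, merge *i* creates node `n+i`) — deterministic and
testable. Leaf order: at each merge the left child is the child containing
the lowest original leaf index; no optimal leaf ordering is attempted.
Default linkage is complete, matching the surrounding ecosystem's common
default; ward.d2 is first-class because clustered-matrix figures typically
use it.

Tests compare the full merge table against an independent naive
agglomerator that recomputes every inter-cluster distance from the original
coordinates (min/max/mean of pairwise distances; for ward.d2 the closed
form `sqrt(2|A||B|/(|A|+|B|)) · ‖μ_A − μ_B‖`). Because that closed form
requires coordinates, oracle inputs are random point configurations and
their Euclidean distance matrices. Agreement is exact in merge pairs and
within 1e-9 in heights over hundreds of random inputs per linkage (n ≤ 6,
where the oracle is cheap and exhaustively trustworthy).

Group-constrained clustering runs independently within each group and
concatenates the per-group subtrees in group order (a forest; one
`MergeTable` per group). No parent dendrogram is drawn over group means:
its construction is unspecified in the figures this emulates, so it is
omitted rather than guessed.

`kmeans_groups` delegates to scikit-learn's Lloyd algorithm with seeded
random initialization from the data rows and 10 restarts, keeping the best
within-cluster sum of squares; empty clusters are handled by the library's
point-relocation rather than a full re-draw. Cluster labels are renamed by
first appearance so results are deterministic and ready for grouping.

## Dendrogram geometry and Newick

Canonical coordinates: leaf at display position *i* sits at `x = i + 0.5`,
`y = 0`; an internal node at the midpoint of its children's x with `y` equal
to the merge height. Each merge contributes one 4-point U-shaped polyline
(two risers, one crossbar). Orientation (top/bottom/left/right panel) is an
axis swap/flip at draw time; the geometry itself is orientation-free.
Newick branch lengths are `parent height − node height` (leaves at 0); a
single leaf serializes to the documented degenerate `label:0;`. Round-trips
through a standard Newick parser preserve topology and root-to-leaf path
lengths to 1e-9.

## Composition and schemes

A `Patch` wraps a rendered display list with a size request, per-axis
alignment flags carrying declared limits, and border allowances. The grid
composer solves column widths / row heights (absolute sizes are fractions
of the figure; relative sizes share the remainder proportionally), then
unifies limits: aligned panels in a column share the union of their
declared x-limits, in a row the union of y-limits; free-aligned axes keep
their own limits. The unified limits are the exact union; an optional
per-axis `expand` fraction (0 by default, 0.05 typical for continuous
scatter axes) adds a drawing margin without changing the reported limits.
Legends equal on (title, labels, swatch kind) collapse to one, ordered by
first appearance, collected to one side or kept per panel.

Schemes merge field-wise (child set wins, unset inherits); data transforms
compose parent-first. When both a layout and a plot set alignment options
the plot wins — a package decision, as precedence is otherwise unspecified.

## Layout systems

All three layouts run the same pipeline: unify domains, apply reorder/group
operators in addition order, solve geometry, render each slot with the
final domain, apply schemes, merge guides, emit the figure. Free slots skip
domain alignment, optionally carrying their own local order of the same ids
— that is what makes crosswise links between differently-ordered panels
possible.

- Stack: slots tile the extent with fixed gaps; vertical stacks share the
  x domain (slot 0 on top), horizontal stacks the y domain.
- Quad: two independent 1-D solves (x and y); every top/bottom annotation
  inherits the central panel's x extent *exactly*, left/right its y extent.
  Corner cells are empty spacers.
- Circle: slots are concentric annuli, first-added innermost, thickness
  proportional to size over `[r_inner, r_outer]` of the unit disc. Sectors
  start at 12 o'clock and run clockwise; with k ≥ 2 groups an angular gap
  is inserted at every boundary *including the wrap-around* one, so usable
  angle is `2π − k·gap` split equally. Panel content is rendered in the
  unit square and polar-transformed: rectangles become annular-sector
  polygons with arcs sampled at `max(8, ceil(Δθ/0.05))` points per edge;
  degenerate zero-area shapes are dropped with a warning. Polar dendrograms
  and genomic coordinate tracks are out of scope.

Whether the innermost or outermost ring should receive the first-added plot
is a convention, fixed here (innermost) for determinism and documented
rather than claimed canonical.

## Linking

Each link side resolves its selection against its own panel's domain into
maximal runs of display positions. Line geometry emits one segment per pair
(by-id: matching identifiers, count = |left ∩ right|; product: every left
to every right, count = |left|·|right|; or explicit pairs) from interval
center to interval center. Polygon geometry emits quadrilateral ribbons
spanning full intervals (per id for by-id pairing, per run-pair for product
pairing). Links are drawn above panel backgrounds and below borders;
straight by default, with an optional quadratic easing curve. Mark panels
hold the selected subset in main-display order; each maximal source run
contributes one ribbon from its interval on the main edge to the matching
interval on the annotation edge, which the ribbons jointly tile.

## Plot kit details

Heatmap cells are one rectangle per (row interval × column interval) with a
two-point linear color interpolation between declared anchors (values
clamped, NaN mapped to the missing fill). Oncoprint cells draw a background
plus one overlay per alteration type, thickest first — full = cell, mid =
central 40 % of cell height, thin = central 15 % (legibility choice,
configurable). The waterfall order ("memo-sort") ranks genes by alteration
count descending (ties keep input order) and sorts samples descending
lexicographically on their binary vectors read in gene-rank order, stably;
it is checked against an independent binary-integer-key implementation over
all 2⁹ binary 3×3 matrices. Box glyphs use linear-interpolation quantiles
(NumPy's default, the common "type 7"), whiskers to the farthest point
within 1.5·IQR, outliers as markers; a single-value box degenerates to a
line glyph.

## Synthetic fixtures

Generators are pure functions of an integer seed (one `default_rng` per
call; no global state), hence bit-reproducible.

- `synth_block_matrix`: cell = block mean + Gaussian noise; block means
  spaced by `effect` (default 10) with noise SD 0.1, rows/columns assigned
  to blocks in a seeded shuffle so recovery is non-trivial. These defaults
  give cleanly separable blocks: ward.d2 clustering cut at the planted k
  recovers the labels with adjusted Rand index 1.
- `synth_alterations`: Bernoulli alteration per (sample, gene) at per-gene
  rates, types drawn from a normalized mix.
- `synth_abundance`: per-sample phylum compositions are Dirichlet draws
  whose concentrations carry multiplicative group effects (the planted
  differential-abundance signal); each phylum's mass is split among its
  genera by a second Dirichlet, so genus-to-phylum aggregation is exact by
  construction.

These fixtures emulate the *shapes* of real cohort data — block structure,
sparse alteration tables, compositional hierarchies — but not its messiness:
no batch effects, missingness patterns, overdispersion or label noise.
Passing tests therefore demonstrate the engine's geometric and algorithmic
guarantees on such data shapes, not biological conclusions about any real
cohort.

## Problem sizes and numerics

Default test and acceptance sizes are desk-scale — oracle clustering at
n ≤ 6 (where exhaustive checking is meaningful), registration at 30×20,
recovery at n = 60, 100-seed blob recovery at n = 40 — chosen so every
check runs in seconds while still exercising each code path. Geometric
identities (tiling, angular conservation, registration, link endpoints) are
asserted at 1e-9 in normalized figure units; interval tiling at 1e-12. SVG
coordinates are written at fixed 4-decimal precision with no timestamps or
environment metadata, which is what makes byte-identity a usable
determinism check.

## Known limitations

Static output only (SVG/PNG; no interactivity). No conversion of foreign
plot objects beyond wrapping an opaque display list with free sides. No
optimal leaf ordering, alternative metrics (hookable but not built-in),
UpSet or 3-D matrix plot types, statistical annotation layers, or genomic
coordinate tracks. Text layout is minimal: labels are placed at interval
centers, upright, with no collision avoidance or rotation engine beyond a
per-label angle.
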