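# plotalign

Composable, data-aware multi-panel visualization for high-dimensional
biological data: aligned plot stacks, quadrant layouts around a central
matrix, circular (annulus) layouts, and observation-level links between
panels.

## The problem

Multi-omics figures juxtapose many views of the same entities — a heatmap of
samples, the dendrogram that ordered them, per-sample mutation burdens, a
cluster band, genus-level abundances under their phyla. Generic figure
composers place panels next to each other but know nothing about the data,
so a reordered heatmap silently stops matching its annotations. `plotalign`
makes the shared **observation domain** a first-class object: every panel
aligned on an axis draws each observation at exactly the same relative
position, and reorderings or groupings applied anywhere (hierarchical
clustering, k-means, manual weights) propagate everywhere. On top of that
sits a linking subsystem that draws one-to-one, one-to-many, many-to-many
and *crosswise* connections (the same observation at different display
positions in two panels, bump-chart style), and mark panels that annotate a
selected subset with connector ribbons.

It is a library first (importable API plus `examples/`), with a thin CLI for
rendering YAML layout specs and regenerating the fixture gallery.

## Core model

- **ObservationDomain** — ids, a display order (a permutation of `0..n-1`),
  optional grouping with contiguous group blocks, and lock flags. Two locked,
  conflicting impositions of order raise an error instead of producing a
  misaligned figure. Observation *i* of *n* occupies the half-open interval
  `[lo + i·w, lo + (i+1)·w)`, `w = (hi−lo)/n`, on any panel extent — the
  intervals tile the extent exactly, which is what makes cross-panel
  registration checkable to 1e-9.
- **Reordering operators** — Lance–Williams agglomerative clustering
  (single, complete, average, ward.d2; deterministic lowest-index
  tie-break), with dendrogram geometry in leaf-index × height space and
  Newick export; seeded k-means grouping; weight-based custom ordering.
- **Layouts** — `StackLayout` (panels along one direction, aligned on the
  perpendicular axis), `QuadLayout` (central matrix with annotation stacks
  whose extents equal the central panel's exactly), `CircleLayout`
  (concentric annuli sharing an angular domain; sectors start at 12 o'clock,
  clockwise, with angular gaps at group boundaries).
- **Linking** — selections resolve to maximal display-position runs on each
  panel's *own* domain; line geometry connects interval centers, polygon
  geometry spans full intervals with ribbons.
- **Plot kit** — heatmap, oncoprint with the memo-sort waterfall rule
  (genes by frequency, samples descending-lexicographic on their alteration
  vectors), aligned bar/box/point/line summaries, dendrograms, group bands,
  labels, free scatter panels.
- **Output** — deterministic SVG (byte-identical for identical inputs) and
  PNG.

## Worked example

```python
from plotalign import (QuadLayout, Heatmap, Summary, GroupBar,
                       agglomerative_order, cut_clusters, synth_block_matrix,
                       write_svg)

bm = synth_block_matrix(n_rows=18, n_cols=8, k_row_blocks=3,
                        effect=10.0, noise_sd=0.1, seed=7)
m = bm.matrix
res = agglomerative_order(m.values, ids=m.row_ids, linkage="ward.d2")
clusters = cut_clusters(res.tree, 3)

q = QuadLayout(Heatmap(m.values, row_ids=m.row_ids, col_ids=m.col_ids))
q.add_dendrogram("left", linkage="ward.d2", size=0.25)
q.group_rows({i: f"C{clusters[i] + 1}" for i in m.row_ids})
q.annotate("right", GroupBar(), size=0.06)
fig = q.assemble()
write_svg(fig, "clustered_heatmap.svg")
print(" ".join(fig.panels["central"].y_domain.display_ids))
```

Running `python examples/01_clustered_heatmap.py` prints:

```
leaf order (top to bottom): r000 r013 r004 r008 r015 r006 r001 r009 r010 r012 r011 r014 r002 r016 r007 r005 r003 r017
cluster sizes: {'C1': 6, 'C2': 6, 'C3': 6}
newick: (((r000:0.2758301783,r013:0.2758301783):0.2460187015,((r004:0.36992030 ...
```

The leaf order is the ward.d2 dendrogram's left-to-right leaf sequence; it
recovers the three planted 6-row blocks as contiguous runs, and the same
order positions the rows in the heatmap, the dendrogram and the annotations.
The other scripts in `examples/` each demonstrate one capability (oncoprint
waterfall, crosswise rank links, one-to-many taxa fans, circular layouts,
data-free composition with limit unification) and print the numbers they
compute.

## Command line

```bash
plotalign render spec.yaml -o figure.svg --seed 1
plotalign gallery -o gallery/ --seed 1      # all archetype figures
```

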