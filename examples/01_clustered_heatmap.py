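"""Clustered heatmap with aligned annotations.

Builds a block-structured matrix, clusters its rows with ward.d2, cuts the
dendrogram into the planted number of clusters, and assembles a quadrant
layout: the heatmap in the center, the dendrogram on the left, a cluster
band and per-row mean bars on the right. The printed leaf order shows the
ordering every aligned panel shares; the Newick string is the same tree in
interchange form.
"""

from pathlib import Path

from plotalign import (
    Heatmap,
    QuadLayout,
    Summary,
    GroupBar,
    agglomerative_order,
    cut_clusters,
    newick_serialize,
    synth_block_matrix,
    write_svg,
)

out = Path("scratch")
out.mkdir(exist_ok=True)

bm = synth_block_matrix(n_rows=18, n_cols=8, k_row_blocks=3, effect=10.0,
                        noise_sd=0.1, seed=7)
m = bm.matrix

res = agglomerative_order(m.values, ids=m.row_ids, linkage="ward.d2")
clusters = cut_clusters(res.tree, 3)

q = QuadLayout(Heatmap(m.values, row_ids=m.row_ids, col_ids=m.col_ids))
q.add_dendrogram("left", linkage="ward.d2", size=0.25)
q.group_rows({i: f"C{clusters[i] + 1}" for i in m.row_ids})
q.annotate("right", GroupBar(), size=0.06)
q.annotate("right", Summary({i: float(m.values[k].mean())
                             for k, i in enumerate(m.row_ids)}, geom="bar"),
           size=0.25)
fig = q.assemble()
write_svg(fig, out / "clustered_heatmap.svg")

rows = fig.panels["central"].y_domain
print("leaf order (top to bottom):", " ".join(rows.display_ids))
print("cluster sizes:", {f"C{c + 1}": list(clusters.values()).count(c)
                         for c in range(3)})
print("newick:", newick_serialize(res.tree)[:70], "...")
print("wrote", out / "clustered_heatmap.svg")
# The leaf order groups the three planted row blocks contiguously; the same
# order positions rows in the heatmap, the dendrogram and both annotations.
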