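"""Fixture gallery: one figure per layout/linking archetype the engine
supports, built from seeded synthetic data at desk scale.

Archetypes: grouped stacks with within-group clustering; rank-transition
(bump-chart) crosswise links; a scatter panel with axis-aligned marginal
summaries; a one-to-many taxonomic fan; a clustered heatmap with cluster
annotations; an oncoprint with a mark panel; and a circular layout with
grouped sectors. ``build_gallery`` renders them all to SVG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cluster import agglomerative_order, cut_clusters
from .composition import AxisSpec, ComposedFigure, Patch, compose_grid
from .domains import create_domain
from .fixtures import synth_abundance, synth_alterations, synth_block_matrix
from .layouts import CircleLayout, QuadLayout, StackLayout
from .linking import mark_panel
from .plots import (
    ContinuousScale,
    DiscretePalette,
    GroupBar,
    Heatmap,
    Labels,
    Oncoprint,
    Scatter,
    Summary,
    _box_stats,
)
from .primitives import DisplayList, Rect, Segment

__all__ = ["build_gallery", "GALLERY"]

_TAXA = {
    "Bacteroidetes": ("Bacteroides", "Prevotella", "Alistipes"),
    "Firmicutes": ("Clostridium", "Lactobacillus", "Faecalibacterium"),
    "Proteobacteria": ("Escherichia", "Pseudomonas"),
    "Fusobacteria": ("Fusobacterium",),
}


def fig_grouped_stack(seed: int = 0) -> ComposedFigure:
    """Grouped sample stacks: taxa heatmap over samples grouped by cohort,
    reordered by hierarchical clustering within each group."""
    ab = synth_abundance(
        n_samples_per_group=10,
        groups=("COAD", "STAD", "READ"),
        taxa=_TAXA,
        group_effect={"STAD": {"Fusobacteria": 3.0}},
        seed=seed,
    )
    samples = ab.phylum.row_ids
    stack = StackLayout("vertical", ids=samples, gap=0.015, name="grouped_stack")
    stack.group_by(ab.sample_groups)
    stack.hclust(ab.phylum.values, linkage="average")
    stack.add(GroupBar(), size=0.12, name="cohort")
    stack.add(
        Heatmap(ab.phylum.values.T, row_ids=ab.phylum.col_ids, col_ids=samples,
                scale=ContinuousScale(0.0, 0.8, "#f7fbff", "#08306b",
                                      title="abundance")),
        size=1.0,
        name="phyla",
    )
    stack.add(
        Summary({s: float(ab.phylum.values[i].max())
                 for i, s in enumerate(samples)}, geom="bar",
                fill="#76b7b2"),
        size=0.35,
        name="dominance",
    )
    return stack.assemble(size_in=(7.0, 4.0))


def fig_rank_links(seed: int = 0) -> ComposedFigure:
    """Rank transitions across cohorts: each panel orders the same taxa by
    within-cohort mean abundance; crosswise ribbons trace the rank shifts."""
    ab = synth_abundance(
        n_samples_per_group=12,
        groups=("COAD", "STAD"),
        taxa=_TAXA,
        group_effect={"STAD": {"Fusobacteria": 4.0, "Bacteroidetes": 0.4}},
        seed=seed,
    )
    phyla = list(ab.phylum.col_ids)
    means = {}
    for grp in ("COAD", "STAD"):
        rows = [i for i, s in enumerate(ab.phylum.row_ids)
                if ab.sample_groups[s] == grp]
        means[grp] = {p: float(ab.phylum.values[rows, j].mean())
                      for j, p in enumerate(phyla)}
    orders = {g: sorted(phyla, key=lambda p: -means[g][p]) for g in means}
    pal = DiscretePalette.for_labels(phyla, title="phylum")

    stack = StackLayout("horizontal", ids=phyla, gap=0.25, name="rank_links")
    for grp in ("COAD", "STAD"):
        panel = Summary({p: means[grp][p] for p in phyla}, geom="bar",
                        fill={p: pal(p) for p in phyla}, name=grp)
        stack.add_free(panel, order=orders[grp], name=grp)
    stack.link("COAD", "STAD", geometry="polygon", pairing="by_id")
    return stack.assemble(size_in=(6.0, 4.0))


def _marginal_box_patch(data: np.ndarray, limits: tuple[float, float],
                        horizontal: bool) -> Patch:
    """A single box glyph spanning a continuous axis, aligned to a scatter."""
    st = _box_stats(np.asarray(data, float))
    dl = DisplayList()
    if horizontal:  # box along x, panel above the scatter
        dl.add(Segment(st["whisker_lo"], 0.5, st["q1"], 0.5))
        dl.add(Segment(st["q3"], 0.5, st["whisker_hi"], 0.5))
        dl.add(Rect(st["q1"], 0.2, st["q3"], 0.8, fill="#9ecae1",
                    stroke="#000000", stroke_width=0.6))
        dl.add(Segment(st["median"], 0.2, st["median"], 0.8, width=1.4))
        x_axis = AxisSpec(aligned=True, limits=limits, expand=0.05)
        y_axis = AxisSpec(aligned=False)
    else:
        dl.add(Segment(0.5, st["whisker_lo"], 0.5, st["q1"]))
        dl.add(Segment(0.5, st["q3"], 0.5, st["whisker_hi"]))
        dl.add(Rect(0.2, st["q1"], 0.8, st["q3"], fill="#9ecae1",
                    stroke="#000000", stroke_width=0.6))
        dl.add(Segment(0.2, st["median"], 0.8, st["median"], width=1.4))
        x_axis = AxisSpec(aligned=False)
        y_axis = AxisSpec(aligned=True, limits=limits, expand=0.05)
    return Patch(display=dl, x_axis=x_axis, y_axis=y_axis, name="marginal")


def fig_marginal_scatter(seed: int = 0) -> ComposedFigure:
    """An ordination-style scatter with marginal boxplots aligned to each
    axis (data-free composition with limit unification)."""
    rng = np.random.default_rng(seed)
    n = 60
    grp = rng.integers(0, 2, n)
    x = rng.normal(0, 1, n) + grp * 2.2
    y = rng.normal(0, 1, n) - grp * 1.4
    pal = ("#4e79a7", "#e15759")
    sc = Scatter(x, y, color=[pal[g] for g in grp], name="pcoa")
    patch = sc.to_patch()
    top = _marginal_box_patch(x, patch.own_limits("x"), horizontal=True)
    right = _marginal_box_patch(y, patch.own_limits("y"), horizontal=False)
    return compose_grid(
        [[top, None], [patch, right]],
        widths=[1.0, 0.22],
        heights=[0.22, 1.0],
        gap=0.02,
        size_in=(5.5, 5.5),
    )


def fig_taxa_fan(seed: int = 0) -> ComposedFigure:
    """One-to-many fan: differentially abundant phyla linked to every genus
    they contain (product pairing, ribbon geometry)."""
    ab = synth_abundance(
        n_samples_per_group=10, groups=("COAD", "STAD"), taxa=_TAXA,
        group_effect={"STAD": {"Fusobacteria": 3.0, "Proteobacteria": 2.0}},
        seed=seed,
    )
    phyla = list(ab.phylum.col_ids)
    genera = list(ab.genus.col_ids)
    pal = DiscretePalette.for_labels(phyla, title="phylum")
    phy_means = {p: float(ab.phylum.values[:, j].mean())
                 for j, p in enumerate(phyla)}
    gen_means = {g: float(ab.genus.values[:, j].mean())
                 for j, g in enumerate(genera)}

    stack = StackLayout("horizontal", ids=phyla, gap=0.3, name="taxa_fan")
    stack.add(Summary(phy_means, geom="bar",
                      fill={p: pal(p) for p in phyla}, name="phyla"), name="phyla")
    genus_fill = {g: pal(p) for p, gs in ab.hierarchy.items() for g in gs}
    stack.add_free(Summary(gen_means, geom="bar", fill=genus_fill, name="genera"),
                   order=genera, name="genera")
    for p in ("Fusobacteria", "Proteobacteria"):
        pairs = tuple((p, g) for g in ab.hierarchy[p])
        stack.link("phyla", "genera", geometry="polygon", pairing=pairs,
                   ids=None)
    return stack.assemble(size_in=(6.0, 4.5))


def fig_clustered_heatmap(seed: int = 0) -> ComposedFigure:
    """Clustered heatmap: ward.d2 row dendrogram, rows cut into k clusters
    and annotated with a group band, plus per-row mean bars."""
    bm = synth_block_matrix(n_rows=24, n_cols=10, k_row_blocks=3,
                            k_col_blocks=2, effect=10.0, noise_sd=0.1,
                            seed=seed)
    m = bm.matrix
    res = agglomerative_order(m.values, ids=m.row_ids, linkage="ward.d2")
    labels = cut_clusters(res.tree, 3)
    hm = Heatmap(m.values, row_ids=m.row_ids, col_ids=m.col_ids)
    q = QuadLayout(hm, gap=0.012, name="clustered_heatmap")
    q.add_dendrogram("left", linkage="ward.d2", size=0.25)
    q.group_rows({i: f"C{labels[i] + 1}" for i in m.row_ids})
    q.annotate("right", GroupBar(), size=0.06, name="clusters")
    q.annotate(
        "right",
        Summary({i: float(m.values[k].mean()) for k, i in enumerate(m.row_ids)},
                geom="bar", fill="#9c755f"),
        size=0.25,
        name="row_mean",
    )
    q.annotate(
        "top",
        Summary({c: float(m.values[:, j].mean())
                 for j, c in enumerate(m.col_ids)}, geom="bar", fill="#59a14f"),
        size=0.2,
        name="col_mean",
    )
    return q.assemble(size_in=(7.0, 6.0))


def fig_oncoprint(seed: int = 0) -> ComposedFigure:
    """Oncoprint in waterfall order with marginal alteration counts and a
    mark panel annotating selected genes."""
    genes = {"TP53": 0.6, "PTEN": 0.4, "SPOP": 0.3, "FOXA1": 0.25,
             "ATM": 0.2, "BRCA2": 0.15}
    all_samples = tuple(f"S{i:04d}" for i in range(40))
    records = synth_alterations(40, genes, seed=seed)
    onco = Oncoprint(records, genes=tuple(genes), samples=all_samples)
    sample_order, gene_order = onco.waterfall_order()
    q = QuadLayout(onco, gap=0.012, name="oncoprint")
    q.reorder_cols(sample_order)
    q.reorder_rows(gene_order)
    from .plots import alteration_counts

    gene_counts, sample_counts = alteration_counts(
        records, create_domain(tuple(genes)), create_domain(all_samples))
    q.annotate("top", Summary({s: float(sample_counts[s])
                               for s in all_samples}, geom="bar",
                              fill="#4e79a7"), size=0.2, name="tmb")
    q.annotate("right", Summary({g: float(gene_counts[g]) for g in genes},
                                geom="bar", fill="#f28e2b"),
               size=0.25, name="gene_freq")
    q.add_mark(mark_panel(("TP53", "ATM"), Labels(size=8.0), side="left"),
               size=0.18)
    return q.assemble(size_in=(8.0, 4.5))


def fig_circle(seed: int = 0) -> ComposedFigure:
    """Circular layout: grouped sectors with angular gaps, a heatmap annulus
    and an outer bar annulus sharing the angular domain."""
    rng = np.random.default_rng(seed)
    n = 24
    ids = tuple(f"t{i:02d}" for i in range(n))
    values = rng.normal(0, 1, (4, n))
    groups = {t: f"g{(i * 3) // n + 1}" for i, t in enumerate(ids)}
    c = CircleLayout(ids=ids, r_inner=0.3, gap_angle=0.06, radial_gap=0.015,
                     name="circle")
    c.group_by(groups)
    c.hclust(values.T, linkage="complete")
    c.add(GroupBar(), size=0.18, name="groups")
    c.add(Heatmap(values, row_ids=tuple(f"v{k}" for k in range(4)),
                  col_ids=ids), size=1.0, name="rings")
    c.add(Summary({t: float(abs(values[:, i]).mean())
                   for i, t in enumerate(ids)}, geom="bar", fill="#b07aa1"),
          size=0.6, name="outer")
    return c.assemble(size_in=(6.0, 6.0))


GALLERY = {
    "grouped_stack": fig_grouped_stack,
    "rank_links": fig_rank_links,
    "marginal_scatter": fig_marginal_scatter,
    "taxa_fan": fig_taxa_fan,
    "clustered_heatmap": fig_clustered_heatmap,
    "oncoprint": fig_oncoprint,
    "circle": fig_circle,
}


def build_gallery(outdir: str | Path, seed: int = 0, dpi: float = 96.0,
                  png: bool = False) -> dict[str, Path]:
    """Render every gallery figure to ``outdir``; returns name -> SVG path."""
    from .render import write_png, write_svg

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, builder in GALLERY.items():
        fig = builder(seed=seed)
        path = outdir / f"{name}.svg"
        write_svg(fig, path, dpi=dpi)
        if png:
            write_png(fig, outdir / f"{name}.png", dpi=dpi)
        paths[name] = path
    return paths
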