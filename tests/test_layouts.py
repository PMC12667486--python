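"""Layout assembly: domain propagation, the cross-panel registration
contract, quad extent contract, circle conservation, and scheme inheritance."""

import numpy as np
import pytest

from plotalign.domains import create_domain
from plotalign.fixtures import synth_block_matrix
from plotalign.layouts import CircleLayout, QuadLayout, StackLayout
from plotalign.plots import (
    Heatmap,
    Labels,
    Scatter,
    Summary,
)
from plotalign.primitives import Polygon, Polyline, Rect, Text
from plotalign.scheme import scheme_theme


def _heat_and_bar_stack(n=6, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"c{i}" for i in range(n)]
    hm = Heatmap(rng.normal(size=(3, n)), col_ids=ids)
    bar = Summary({i: float(k + 1) for k, i in enumerate(ids)}, geom="bar")
    stack = StackLayout("vertical", ids=ids, gap=0.03)
    stack.add(hm, size=1.0, name="hm").add(bar, size=0.4, name="bar")
    return stack, ids


def _rects_in(fig, panel_name):
    r = fig.panels[panel_name].rect
    eps = 1e-9
    return [p for p in fig.display.primitives
            if isinstance(p, Rect)
            and r.x0 - eps <= p.x0 and p.x1 <= r.x1 + eps
            and r.y0 - eps <= p.y0 and p.y1 <= r.y1 + eps]


class TestStack:
    def test_dendrogram_order_propagates_to_heatmap(self):
        rng = np.random.default_rng(1)
        ids = [f"c{i}" for i in range(5)]
        data = rng.normal(size=(5, 3))
        stack = StackLayout("vertical", ids=ids)
        stack.add_dendrogram(data, linkage="complete", size=0.3)
        stack.add(Heatmap(data.T, col_ids=ids), name="hm")
        fig = stack.assemble()
        domain = fig.panels["hm"].x_domain
        from plotalign.cluster import agglomerative_order

        expected = agglomerative_order(data, ids=ids, linkage="complete").order
        assert domain.display_ids == expected

    def test_free_panel_does_not_alter_shared_domain(self):
        stack, ids = _heat_and_bar_stack()
        stack.add_free(Scatter([0, 1], [0, 1]), name="sc")
        stack.reorder(list(reversed(ids)))
        fig = stack.assemble()
        assert fig.panels["hm"].x_domain.display_ids == tuple(reversed(ids))

    def test_rendered_centers_register_across_panels(self):
        """The core alignment claim: each observation's rendered interval
        center is identical across every aligned panel."""
        stack, ids = _heat_and_bar_stack(n=8)
        fig = stack.assemble()
        hm_cols = sorted({round(0.5 * (p.x0 + p.x1), 12)
                          for p in _rects_in(fig, "hm")})
        bar_cols = sorted(round(0.5 * (p.x0 + p.x1), 12)
                          for p in _rects_in(fig, "bar"))
        assert len(hm_cols) == len(bar_cols) == 8
        for a, b in zip(hm_cols, bar_cols):
            assert a == pytest.approx(b, abs=1e-9)

    def test_layout_scheme_inherited_by_plots(self):
        ids = ["a", "b"]
        stack = StackLayout("vertical", ids=ids,
                            scheme=scheme_theme(font_size=13.0))
        stack.add(Labels(), name="lab")
        fig = stack.assemble()
        texts = [p for p in fig.display.primitives if isinstance(p, Text)]
        assert texts and all(t.size == 13.0 for t in texts)

    def test_slot_scheme_overrides_layout_scheme(self):
        ids = ["a", "b"]
        stack = StackLayout("vertical", ids=ids,
                            scheme=scheme_theme(font_size=13.0))
        stack.add(Labels(), name="lab", scheme=scheme_theme(font_size=5.0))
        fig = stack.assemble()
        texts = [p for p in fig.display.primitives if isinstance(p, Text)]
        assert texts and all(t.size == 5.0 for t in texts)

    def test_mark_panel_inserted_as_slot_with_connectors(self):
        stack, ids = _heat_and_bar_stack()
        from plotalign.linking import mark_panel

        stack.add_mark(mark_panel([ids[1], ids[4]], Labels()), after="bar")
        fig = stack.assemble()
        polys = [p for p in fig.display.primitives if isinstance(p, Polygon)]
        assert len(polys) == 2  # one ribbon per selected run


class TestQuad:
    def test_extent_contract_and_registration(self):
        bm = synth_block_matrix(n_rows=10, n_cols=6, seed=4)
        hm = Heatmap(bm.matrix.values, row_ids=bm.matrix.row_ids,
                     col_ids=bm.matrix.col_ids)
        q = QuadLayout(hm)
        q.add_dendrogram("left", linkage="average")
        q.annotate("top", Summary({c: 1.0 for c in bm.matrix.col_ids},
                                  geom="bar"), size=0.2, name="topbar")
        fig = q.assemble()
        c = fig.panels["central"].rect
        assert fig.panels["topbar"].rect.x_extent == c.x_extent
        assert fig.panels["dendro_left"].rect.y_extent == c.y_extent
        # column registration between central heatmap and top bars
        hm_cols = sorted({round(0.5 * (p.x0 + p.x1), 12)
                          for p in _rects_in(fig, "central")})
        bar_cols = sorted(round(0.5 * (p.x0 + p.x1), 12)
                          for p in _rects_in(fig, "topbar"))
        assert hm_cols == pytest.approx(bar_cols, abs=1e-9)

    def test_row_hclust_and_col_kmeans_domains(self):
        """Rows ordered per dendrogram and columns contiguously grouped, each
        matching independently computed domain states."""
        bm = synth_block_matrix(n_rows=12, n_cols=8, k_row_blocks=3,
                                k_col_blocks=2, seed=9)
        m = bm.matrix
        hm = Heatmap(m.values, row_ids=m.row_ids, col_ids=m.col_ids)
        q = QuadLayout(hm)
        q.hclust_rows(linkage="ward.d2")
        q.kmeans_cols(k=2, seed=0)
        fig = q.assemble()
        rows = fig.panels["central"].y_domain
        cols = fig.panels["central"].x_domain
        from plotalign.cluster import agglomerative_order, kmeans_groups
        from plotalign.domains import create_domain, set_groups

        expected_rows = agglomerative_order(m.values, ids=m.row_ids,
                                            linkage="ward.d2").order
        assert rows.display_ids == expected_rows
        mapping = kmeans_groups(m.values.T, m.col_ids, k=2, seed=0)
        expected_cols = set_groups(create_domain(m.col_ids), mapping)
        assert cols.display_ids == expected_cols.display_ids
        labels = [cols.groups[i] for i in cols.display_ids]
        # contiguous group blocks
        changes = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
        assert changes == len(set(labels)) - 1

    def test_dendrogram_leaves_register_with_heatmap_rows(self):
        bm = synth_block_matrix(n_rows=9, n_cols=5, seed=3)
        m = bm.matrix
        hm = Heatmap(m.values, row_ids=m.row_ids, col_ids=m.col_ids)
        q = QuadLayout(hm)
        q.add_dendrogram("left", linkage="complete")
        fig = q.assemble()
        hm_rows = sorted({round(0.5 * (p.y0 + p.y1), 12)
                          for p in _rects_in(fig, "central")})
        dend = fig.panels["dendro_left"]
        leaf_ys = set()
        for p in fig.display.primitives:
            if isinstance(p, Polyline):
                x0, y0 = p.points[0]
                x1, y1 = p.points[-1]
                for x, y in ((x0, y0), (x1, y1)):
                    if abs(x - dend.rect.x1) < 1e-9:  # riser foot at leaf edge
                        leaf_ys.add(round(y, 12))
        assert leaf_ys <= set(hm_rows)


class TestCircle:
    def test_radial_bands_disjoint_and_exhaustive(self):
        ids = [f"t{i}" for i in range(6)]
        c = CircleLayout(ids=ids, r_inner=0.3, radial_gap=0.0)
        c.add(Heatmap(np.ones((1, 6)), col_ids=ids), size=1.0)
        c.add(Summary({i: 1.0 for i in ids}, geom="bar"), size=0.5)
        from plotalign.geometry import circle_geometry

        bands = circle_geometry([1.0, 0.5], r_inner=0.3)
        assert bands[0].r1 == pytest.approx(bands[1].r0)
        fig = c.assemble()
        assert len(fig.panels) == 2

    def test_sector_polygons_stay_on_annulus_radii(self):
        ids = [f"t{i}" for i in range(4)]
        c = CircleLayout(ids=ids, r_inner=0.5)
        c.add(Heatmap(np.ones((1, 4)), col_ids=ids), size=1.0)
        fig = c.assemble()
        polys = [p for p in fig.display.primitives if isinstance(p, Polygon)]
        assert len(polys) == 4
        for poly in polys:
            radii = {round(np.hypot(x - 0.5, y - 0.5), 9) for x, y in poly.points}
            assert radii == {0.25, 0.5}
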