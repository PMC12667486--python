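"""Built-in plot types: heatmap tiles, oncoprint with waterfall sort,
aligned summary glyphs."""

import itertools

import numpy as np
import pytest

from plotalign.domains import create_domain, set_order
from plotalign.plots import (
    AlterationRecord,
    ContinuousScale,
    Oncoprint,
    aligned_summary_geoms,
    alteration_counts,
    heatmap_tiles,
    memo_sort,
    oncoprint_tiles,
    _box_stats,
)
from plotalign.primitives import Rect, Segment

from ._oracles import waterfall_order_by_binary_keys


class TestHeatmap:
    def test_two_by_two_cell_placement(self):
        dl = heatmap_tiles(np.array([[1.0, 2.0], [3.0, 4.0]]),
                           create_domain(["r0", "r1"]),
                           create_domain(["c0", "c1"]))
        rects = [p for p in dl.primitives if isinstance(p, Rect)]
        assert len(rects) == 4
        # cell (0,0): first column x [0,0.5), first row at the top y [0.5,1)
        assert (rects[0].x0, rects[0].y0, rects[0].x1, rects[0].y1) == (
            0.0, 0.5, 0.5, 1.0)

    def test_row_reorder_swaps_fills_not_geometry(self):
        vals = np.array([[0.0], [10.0]])
        rd = create_domain(["r0", "r1"])
        base = heatmap_tiles(vals, rd, create_domain(["c0"]),
                             scale=ContinuousScale(0, 10))
        swapped = heatmap_tiles(vals, set_order(rd, ["r1", "r0"]),
                                create_domain(["c0"]),
                                scale=ContinuousScale(0, 10))
        b = {(p.y0, p.y1): p.fill for p in base.primitives if isinstance(p, Rect)}
        s = {(p.y0, p.y1): p.fill for p in swapped.primitives
             if isinstance(p, Rect)}
        assert set(b) == set(s)
        assert all(b[k] != s[k] for k in b)

    def test_linear_color_interpolation_midpoint(self):
        scale = ContinuousScale(0.0, 10.0, "#000000", "#ffffff")
        dl = heatmap_tiles(np.array([[0.0], [5.0], [10.0]]),
                           create_domain(["a", "b", "c"]),
                           create_domain(["x"]), scale=scale)
        fills = [p.fill for p in dl.primitives if isinstance(p, Rect)]
        assert fills == ["#000000", "#808080", "#ffffff"]

    def test_missing_values_use_missing_fill(self):
        scale = ContinuousScale(0.0, 1.0, missing="#cccccc")
        dl = heatmap_tiles(np.array([[np.nan]]), create_domain(["r"]),
                           create_domain(["c"]), scale=scale)
        assert dl.primitives[0].fill == "#cccccc"

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            heatmap_tiles(np.ones((2, 3)), create_domain("ab"),
                          create_domain("cd"))


class TestMemoSort:
    def test_worked_example(self):
        binary = np.array([[1, 0], [1, 1], [0, 1]])
        samples, genes = memo_sort(binary, ["S1", "S2", "S3"], ["G1", "G2"])
        assert samples == ["S2", "S1", "S3"]
        assert genes == ["G1", "G2"]

    def test_all_zero_matrix_keeps_input_order(self):
        samples, _ = memo_sort(np.zeros((4, 3)), list("abcd"), list("xyz"))
        assert samples == list("abcd")

    def test_single_sample_unchanged(self):
        samples, _ = memo_sort(np.array([[1, 0]]), ["s"], ["g1", "g2"])
        assert samples == ["s"]

    def test_matches_binary_key_oracle_exhaustively_3x3(self):
        for bits in itertools.product([0, 1], repeat=9):
            b = np.array(bits).reshape(3, 3)
            samples, _ = memo_sort(b, ["s0", "s1", "s2"], ["g0", "g1", "g2"])
            expected = [f"s{i}" for i in waterfall_order_by_binary_keys(b)]
            assert samples == expected

    def test_invariant_to_row_permutation_up_to_ties(self, rng):
        b = (rng.random((6, 4)) < 0.4).astype(int)
        samples = [f"s{i}" for i in range(6)]
        base, _ = memo_sort(b, samples, [f"g{j}" for j in range(4)])
        for _ in range(20):
            perm = rng.permutation(6)
            got, _ = memo_sort(b[perm], [samples[i] for i in perm],
                               [f"g{j}" for j in range(4)])
            # same multiset of binary vectors in the same sorted sequence
            key = {s: tuple(b[int(s[1:])]) for s in samples}
            assert [key[s] for s in got] == [key[s] for s in base]


class TestOncoprint:
    def _domains(self):
        return create_domain(["G1", "G2"]), create_domain(["S1", "S2", "S3"])

    def test_single_mid_overlay(self):
        gd, sd = create_domain(["G1"]), create_domain(["S1"])
        dl = oncoprint_tiles([AlterationRecord("S1", "G1", "MUT")], gd, sd)
        rects = [p for p in dl.primitives if isinstance(p, Rect)]
        assert len(rects) == 2  # background + one overlay
        bg, ov = rects
        assert (ov.y1 - ov.y0) == pytest.approx(0.4 * (bg.y1 - bg.y0))

    def test_thickest_drawn_first(self):
        gd, sd = create_domain(["G1"]), create_domain(["S1"])
        dl = oncoprint_tiles(
            [AlterationRecord("S1", "G1", "MUT"),
             AlterationRecord("S1", "G1", "AMP")], gd, sd)
        rects = [p for p in dl.primitives if isinstance(p, Rect)]
        assert len(rects) == 3
        heights = [r.y1 - r.y0 for r in rects[1:]]
        assert heights[0] > heights[1]  # AMP (full) below MUT (mid)

    def test_overlays_stay_inside_cells(self, rng):
        genes = [f"G{i}" for i in range(3)]
        samples = [f"S{i}" for i in range(5)]
        records = [AlterationRecord(s, g, t)
                   for s in samples for g in genes
                   for t in (["MUT"] if rng.random() < 0.5 else [])]
        gd, sd = create_domain(genes), create_domain(samples)
        dl = oncoprint_tiles(records, gd, sd)
        rects = [p for p in dl.primitives if isinstance(p, Rect)]
        for r in rects:
            assert -1e-12 <= r.x0 <= r.x1 <= 1 + 1e-12
            assert -1e-12 <= r.y0 <= r.y1 <= 1 + 1e-12

    def test_marginal_counts(self):
        gd, sd = self._domains()
        records = [AlterationRecord("S1", "G1", "MUT"),
                   AlterationRecord("S2", "G1", "AMP"),
                   AlterationRecord("S2", "G2", "MUT"),
                   AlterationRecord("S3", "G2", "DEL")]
        gene_counts, sample_counts = alteration_counts(records, gd, sd)
        assert gene_counts == {"G1": 2, "G2": 2}
        assert sample_counts == {"S1": 1, "S2": 2, "S3": 1}

    def test_unknown_type_lists_vocabulary(self):
        gd, sd = self._domains()
        with pytest.raises(ValueError, match="vocabulary"):
            oncoprint_tiles([AlterationRecord("S1", "G1", "WEIRD")], gd, sd)

    def test_waterfall_order_through_plot(self):
        records = [AlterationRecord("S1", "G1", "MUT"),
                   AlterationRecord("S2", "G1", "MUT"),
                   AlterationRecord("S2", "G2", "MUT"),
                   AlterationRecord("S3", "G2", "MUT")]
        onco = Oncoprint(records, genes=["G1", "G2"],
                         samples=["S1", "S2", "S3"])
        samples, genes = onco.waterfall_order()
        assert samples == ["S2", "S1", "S3"]


class TestSummaries:
    def test_bar_centers_and_heights(self):
        d = create_domain(["a", "b"])
        dl = aligned_summary_geoms({"a": 1.0, "b": 2.0}, d, geom="bar")
        bars = [p for p in dl.primitives if isinstance(p, Rect)]
        centers = [0.5 * (b.x0 + b.x1) for b in bars]
        assert centers == pytest.approx([0.25, 0.75])
        assert bars[0].y1 / bars[1].y1 == pytest.approx(0.5)

    def test_box_statistics_with_outlier(self):
        st = _box_stats(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert st["median"] == 3.0
        assert st["q1"] == 2.0 and st["q3"] == 4.0
        assert st["whisker_hi"] == 4.0  # largest point within Q3 + 1.5 IQR
        assert st["outliers"] == [100.0]

    def test_single_value_box_degenerates_to_line(self):
        d = create_domain(["a"])
        dl = aligned_summary_geoms({"a": [5.0]}, d, geom="box")
        assert all(isinstance(p, Segment) for p in dl.primitives)

    def test_missing_id_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            aligned_summary_geoms({"a": 1.0}, create_domain("ab"), geom="bar")

    def test_line_geom_follows_display_order(self):
        d = set_order(create_domain("abc"), ["c", "a", "b"])
        dl = aligned_summary_geoms({"a": 1.0, "b": 2.0, "c": 3.0}, d,
                                   geom="line")
        [poly] = dl.primitives
        xs = [x for x, _ in poly.points]
        assert xs == sorted(xs)  # follows display positions left to right

    def test_registration_with_heatmap_columns(self):
        """Bar centers coincide with heatmap column centers for one domain."""
        d = create_domain([f"c{i}" for i in range(5)])
        hm = heatmap_tiles(np.ones((1, 5)), create_domain(["r"]), d)
        bars = aligned_summary_geoms({i: 1.0 for i in d.ids}, d, geom="bar")
        hm_centers = sorted({0.5 * (p.x0 + p.x1)
                             for p in hm.primitives if isinstance(p, Rect)})
        bar_centers = sorted(0.5 * (p.x0 + p.x1)
                             for p in bars.primitives if isinstance(p, Rect))
        assert hm_centers == pytest.approx(bar_centers)
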