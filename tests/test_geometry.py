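"""Stack/quad/circle geometry solvers, angular sector placement, and the
polar transform; conservation properties over random specifications."""

import math

import pytest

from plotalign.domains import create_domain, set_groups
from plotalign.geometry import (
    AnnulusBand,
    absolute,
    angular_map,
    angular_position,
    circle_geometry,
    polar_shape,
    quad_geometry,
    rel,
    stack_geometry,
)

TWO_PI = 2 * math.pi


class TestStack:
    def test_equal_split(self):
        assert stack_geometry([1, 1]) == [(0.0, 0.5), (0.5, 1.0)]

    def test_proportional_split(self):
        assert stack_geometry([1, 3]) == [(0.0, 0.25), (0.25, 1.0)]

    def test_three_slots_with_gaps(self):
        ivs = stack_geometry([1, 1, 1], gap=0.05)
        width = (1 - 2 * 0.05) / 3
        assert ivs[0] == pytest.approx((0.0, width))
        assert ivs[1] == pytest.approx((width + 0.05, 2 * width + 0.05))
        assert ivs[2] == pytest.approx((2 * width + 0.1, 1.0))

    def test_absolute_and_relative_mix(self):
        ivs = stack_geometry([absolute(0.3), rel(1)])
        assert ivs == [(0.0, 0.3), (0.3, 1.0)]

    def test_overconstrained_absolute_sizes_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            stack_geometry([absolute(0.8), absolute(0.8)])

    @pytest.mark.parametrize("trial", range(20))
    def test_tiling_sums_to_extent(self, trial, rng):
        n = int(rng.integers(1, 6))
        sizes = rng.uniform(0.2, 3.0, n)
        gap = float(rng.uniform(0, 0.4 / max(n, 2)))
        ivs = stack_geometry(list(sizes), gap=gap)
        total = sum(b - a for a, b in ivs) + gap * (n - 1)
        assert total == pytest.approx(1.0, abs=1e-9)


class TestQuad:
    def test_central_only(self):
        g = quad_geometry()
        assert (g["central"].x0, g["central"].y0, g["central"].x1,
                g["central"].y1) == (0.0, 0.0, 1.0, 1.0)

    def test_single_top_annotation(self):
        g = quad_geometry(central=(1.0, 0.8), top=[0.2])
        assert g["central"].y_extent == pytest.approx((0.0, 0.8))
        assert g[("top", 0)].y_extent == pytest.approx((0.8, 1.0))
        assert g[("top", 0)].x_extent == g["central"].x_extent

    def test_left_plus_top_leaves_corner_empty(self):
        g = quad_geometry(central=(0.8, 0.8), top=[0.2], left=[0.2])
        c = g["central"]
        assert c.x_extent == pytest.approx((0.2, 1.0))
        assert c.y_extent == pytest.approx((0.0, 0.8))
        assert g[("top", 0)].x_extent == c.x_extent
        assert g[("top", 0)].y_extent == pytest.approx((0.8, 1.0))
        assert g[("left", 0)].x_extent == pytest.approx((0.0, 0.2))
        assert g[("left", 0)].y_extent == c.y_extent

    def test_alignment_contract_exact(self, rng):
        for _ in range(10):
            g = quad_geometry(
                central=(1.0, 1.0),
                top=list(rng.uniform(0.1, 0.4, int(rng.integers(0, 3)))),
                bottom=list(rng.uniform(0.1, 0.4, int(rng.integers(0, 3)))),
                left=list(rng.uniform(0.1, 0.4, int(rng.integers(0, 3)))),
                right=list(rng.uniform(0.1, 0.4, int(rng.integers(0, 3)))),
                gap=0.01,
            )
            c = g["central"]
            for key, rect in g.items():
                if key == "central":
                    continue
                side = key[0]
                if side in ("top", "bottom"):
                    assert rect.x_extent == c.x_extent
                else:
                    assert rect.y_extent == c.y_extent


class TestCircle:
    def test_two_equal_bands(self):
        bands = circle_geometry([1, 1], r_inner=0.3, r_outer=1.0)
        assert bands[0].r0 == pytest.approx(0.3)
        assert bands[0].r1 == pytest.approx(0.65)
        assert bands[1].r1 == pytest.approx(1.0)

    def test_single_slot_fills_range(self):
        [band] = circle_geometry([2.0], r_inner=0.4)
        assert (band.r0, band.r1) == (0.4, 1.0)

    def test_proportional_bands(self):
        bands = circle_geometry([1, 2, 1], r_inner=0.2)
        assert [(b.r0, b.r1) for b in bands] == pytest.approx(
            [(0.2, 0.4), (0.4, 0.8), (0.8, 1.0)])

    def test_invalid_radial_range(self):
        with pytest.raises(ValueError):
            circle_geometry([1], r_inner=0.9, r_outer=0.5)

    @pytest.mark.parametrize("trial", range(20))
    def test_bands_disjoint_and_exhaustive(self, trial, rng):
        n = int(rng.integers(1, 5))
        r0 = float(rng.uniform(0, 0.5))
        bands = circle_geometry(list(rng.uniform(0.3, 2.0, n)), r_inner=r0)
        assert bands[0].r0 == pytest.approx(r0, abs=1e-9)
        assert bands[-1].r1 == pytest.approx(1.0, abs=1e-9)
        for a, b in zip(bands, bands[1:]):
            assert a.r1 == pytest.approx(b.r0, abs=1e-9)


class TestAngular:
    def test_four_sectors_no_groups(self):
        d = create_domain("wxyz")
        s, e = angular_position(d, "w")
        assert s == pytest.approx(math.pi / 2)
        assert e == pytest.approx(0.0)
        for i in d.ids:
            s, e = angular_position(d, i)
            assert s - e == pytest.approx(math.pi / 2)

    def test_two_groups_with_gap(self):
        d = set_groups(create_domain("ab"), {"a": "g1", "b": "g2"})
        s, e = angular_position(d, "a", gap_angle=0.2)
        assert s - e == pytest.approx((TWO_PI - 0.4) / 2)

    def test_single_observation_full_circle(self):
        d = create_domain(["a"])
        s, e = angular_position(d, "a")
        assert s - e == pytest.approx(TWO_PI)

    def test_excessive_gaps_rejected(self):
        d = set_groups(create_domain("ab"), {"a": "g1", "b": "g2"})
        with pytest.raises(ValueError):
            angular_position(d, "a", gap_angle=math.pi)

    @pytest.mark.parametrize("trial", range(25))
    def test_angular_conservation(self, trial, rng):
        """Sector widths plus gaps always sum to a full turn."""
        n = int(rng.integers(1, 12))
        ids = [f"i{k}" for k in range(n)]
        d = create_domain(ids)
        k = int(rng.integers(1, n + 1))
        gap = 0.0
        if k >= 2:
            d = set_groups(d, {i: f"g{j % k}" for j, i in enumerate(ids)})
            gap = float(rng.uniform(0, TWO_PI / (4 * k)))
        widths = [angular_position(d, i, gap)[0] - angular_position(d, i, gap)[1]
                  for i in ids]
        n_bound = len({d.groups[i] for i in ids}) if d.groups else 0
        n_bound = n_bound if n_bound >= 2 else 0
        assert sum(widths) + n_bound * gap == pytest.approx(TWO_PI, abs=1e-9)


class TestPolar:
    def test_full_annulus_vertex_radii(self):
        d = create_domain(["a"])
        theta = angular_map(d)
        poly = polar_shape((0.0, 0.0, 1.0, 1.0), AnnulusBand(0.5, 1.0), theta)
        radii = {round(math.hypot(x - 0.5, y - 0.5), 9) for x, y in poly}
        assert radii == {0.25, 0.5}

    def test_zero_width_shape_dropped_with_warning(self):
        d = create_domain(["a"])
        with pytest.warns(UserWarning, match="degenerate"):
            out = polar_shape((0.3, 0.0, 0.3, 1.0), AnnulusBand(0.5, 1.0),
                              angular_map(d))
        assert out is None

    def test_quarter_sector_sampling_density(self):
        d = create_domain("wxyz")  # each sector is a quarter turn
        theta = angular_map(d)
        poly = polar_shape((0.0, 0.0, 0.25, 1.0), AnnulusBand(0.2, 0.9), theta)
        # two arc edges, each sampled at >= ceil((pi/2)/0.05)+1 = 33 points
        assert len(poly) >= 66
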