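"""Built-in aligned plot types: heatmaps, oncoprints (with waterfall
memo-sort), bar/box/point/line summaries, dendrogram panels, observation
labels, and a free scatter for data-free composition.

All aligned plots render into the unit square of their panel using the
shared observation domains, so that the same entity occupies the same
relative position in every panel of a layout. Display convention: on the
x axis display position runs left to right; on the y axis it runs top to
bottom (matrix reading order, row 0 at top) — dendrogram and link
coordinates depend on this and use the same helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cluster import HClustResult
from .composition import AxisSpec, Patch
from .dendrogram import DendrogramGeometry, dendrogram_geometry
from .domains import ObservationDomain, create_domain, observation_interval
from .primitives import (
    DisplayList,
    LegendKey,
    Marker,
    Polyline,
    Rect,
    Segment,
    Text,
)
from .scheme import Scheme

__all__ = [
    "AlterationRecord",
    "ContinuousScale",
    "DiscretePalette",
    "Heatmap",
    "Oncoprint",
    "Summary",
    "DendrogramPlot",
    "Labels",
    "Scatter",
    "GroupBar",
    "heatmap_tiles",
    "oncoprint_tiles",
    "memo_sort",
    "alteration_counts",
    "aligned_summary_geoms",
    "x_interval",
    "y_interval",
]

DEFAULT_PALETTE = (
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f",
    "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
)


# ---------------------------------------------------------------- intervals
def x_interval(domain: ObservationDomain, id_: str) -> tuple[float, float]:
    """Unit-panel x interval of an observation (left to right)."""
    return observation_interval(domain, id_, (0.0, 1.0))


def y_interval(domain: ObservationDomain, id_: str) -> tuple[float, float]:
    """Unit-panel y interval of an observation, row 0 at top."""
    lo, hi = observation_interval(domain, id_, (0.0, 1.0))
    return (1.0 - hi, 1.0 - lo)


# ---------------------------------------------------------------- color
def _hex_to_rgb(c: str) -> tuple[int, int, int]:
    c = c.lstrip("#")
    return (int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16))


def _rgb_to_hex(r: float, g: float, b: float) -> str:
    return "#{:02x}{:02x}{:02x}".format(
        int(round(min(max(r, 0), 255))),
        int(round(min(max(g, 0), 255))),
        int(round(min(max(b, 0), 255))),
    )


@dataclass(frozen=True)
class ContinuousScale:
    """Two-point linear color interpolation between declared anchors.

    Values outside [v0, v1] are clamped; ``NaN`` maps to ``missing``.
    """

    v0: float = 0.0
    v1: float = 1.0
    c0: str = "#2166ac"
    c1: str = "#b2182b"
    missing: str = "#cccccc"
    title: str = "value"

    def __call__(self, v: float) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return self.missing
        t = 0.0 if self.v1 == self.v0 else (v - self.v0) / (self.v1 - self.v0)
        t = min(max(t, 0.0), 1.0)
        r0, g0, b0 = _hex_to_rgb(self.c0)
        r1, g1, b1 = _hex_to_rgb(self.c1)
        return _rgb_to_hex(r0 + t * (r1 - r0), g0 + t * (g1 - g0), b0 + t * (b1 - b0))

    def legend(self) -> LegendKey:
        return LegendKey(
            title=self.title,
            labels=(f"{self.v0:g}", f"{self.v1:g}"),
            colors=(self.c0, self.c1),
            kind="fill",
        )


@dataclass(frozen=True)
class DiscretePalette:
    """Declared label -> color mapping for categorical encodings."""

    mapping: tuple[tuple[str, str], ...]
    title: str = "group"

    @classmethod
    def for_labels(cls, labels: Sequence[str], title: str = "group") -> "DiscretePalette":
        return cls(
            mapping=tuple(
                (lab, DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)])
                for i, lab in enumerate(labels)
            ),
            title=title,
        )

    def __call__(self, label: str) -> str:
        for lab, col in self.mapping:
            if lab == label:
                return col
        raise KeyError(f"label {label!r} not in palette "
                       f"{[lab for lab, _ in self.mapping]}")

    def legend(self) -> LegendKey:
        labs, cols = zip(*self.mapping)
        return LegendKey(title=self.title, labels=labs, colors=cols, kind="fill")


# ---------------------------------------------------------------- base plot
class AlignedPlot:
    """Base class: renders into the unit square given the shared domains.

    ``x_ids`` / ``y_ids`` let a layout infer the shared domain from the
    first aligned plot added to it.
    """

    name: str = "plot"

    def x_ids(self) -> tuple[str, ...] | None:
        return None

    def y_ids(self) -> tuple[str, ...] | None:
        return None

    def render(
        self,
        x_domain: ObservationDomain | None = None,
        y_domain: ObservationDomain | None = None,
        scheme: Scheme | None = None,
    ) -> DisplayList:
        raise NotImplementedError

    def to_patch(self, scheme: Scheme | None = None) -> Patch:
        """Render standalone (own domains) and wrap as a compose_grid patch."""
        xd = create_domain(self.x_ids()) if self.x_ids() else None
        yd = create_domain(self.y_ids()) if self.y_ids() else None
        dl = self.render(xd, yd, scheme)
        return Patch(
            display=dl,
            x_axis=AxisSpec(aligned=True, limits=(0.0, 1.0), discrete=True),
            y_axis=AxisSpec(aligned=True, limits=(0.0, 1.0), discrete=True),
            name=self.name,
        )


# ---------------------------------------------------------------- heatmap
def heatmap_tiles(
    values: np.ndarray,
    row_domain: ObservationDomain,
    col_domain: ObservationDomain,
    scale: ContinuousScale | None = None,
    border: str | None = None,
) -> DisplayList:
    """One rectangle per cell at (column interval x row interval) in the
    current display orders; missing (NaN) cells get the scale's missing fill.
    Row 0 of the matrix corresponds to the first row id and is drawn at the
    top when the row domain is in identity order."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(row_domain), len(col_domain)):
        raise ValueError(
            f"matrix shape {values.shape} does not match domains "
            f"({len(row_domain)} rows x {len(col_domain)} cols)"
        )
    if scale is None:
        finite = values[np.isfinite(values)]
        lo = float(finite.min()) if finite.size else 0.0
        hi = float(finite.max()) if finite.size else 1.0
        scale = ContinuousScale(v0=lo, v1=hi)
    dl = DisplayList()
    for i, rid in enumerate(row_domain.ids):
        ylo, yhi = y_interval(row_domain, rid)
        for j, cid in enumerate(col_domain.ids):
            xlo, xhi = x_interval(col_domain, cid)
            dl.add(Rect(xlo, ylo, xhi, yhi, fill=scale(values[i, j]),
                        stroke=border, stroke_width=0.3 if border else 0.0))
    dl.add_legend(scale.legend())
    return dl


@dataclass
class Heatmap(AlignedPlot):
    """A matrix panel; rows/columns follow the shared domains when aligned."""

    values: np.ndarray
    row_ids: Sequence[str] | None = None
    col_ids: Sequence[str] | None = None
    scale: ContinuousScale | None = None
    border: str | None = None
    name: str = "heatmap"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        nr, nc = self.values.shape
        if self.row_ids is None:
            self.row_ids = tuple(f"r{i}" for i in range(nr))
        if self.col_ids is None:
            self.col_ids = tuple(f"c{j}" for j in range(nc))

    def x_ids(self):
        return tuple(self.col_ids)

    def y_ids(self):
        return tuple(self.row_ids)

    def render(self, x_domain=None, y_domain=None, scheme=None) -> DisplayList:
        values = self.values
        if scheme is not None:
            values = np.asarray(scheme.apply_transform(values), dtype=float)
        rd = y_domain if y_domain is not None else create_domain(self.row_ids)
        cd = x_domain if x_domain is not None else create_domain(self.col_ids)
        # reindex matrix to the domains' id order (not display order; geometry
        # handles display positions)
        ri = [list(self.row_ids).index(i) for i in rd.ids]
        ci = [list(self.col_ids).index(j) for j in cd.ids]
        return heatmap_tiles(values[np.ix_(ri, ci)], rd, cd, self.scale, self.border)


# ---------------------------------------------------------------- oncoprint
@dataclass(frozen=True)
class AlterationRecord:
    """One alteration event: sample, gene, and a type from a declared
    vocabulary (e.g. MUT, AMP, DEL, FUS). A (sample, gene) cell may carry
    several records of different types."""

    sample: str
    gene: str
    type: str

    def __post_init__(self) -> None:
        if not self.sample or not self.gene:
            raise ValueError("sample and gene ids must be non-empty")


THICKNESS = {"full": 1.0, "mid": 0.4, "thin": 0.15}

DEFAULT_ONCO_STYLE = {
    "AMP": ("#d62728", "full"),
    "DEL": ("#1f77b4", "full"),
    "MUT": ("#2ca02c", "mid"),
    "FUS": ("#9467bd", "thin"),
}


def memo_sort(
    binary: np.ndarray,
    sample_ids: Sequence[str],
    gene_ids: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Waterfall ordering of an oncoprint.

    Genes are ranked by alteration count descending (ties keep input order);
    samples are then sorted descending lexicographically on their binary
    alteration vectors read in gene rank order (stable for ties). Returns
    (sample order, gene order).
    """
    b = (np.asarray(binary) != 0).astype(int)
    if b.shape != (len(sample_ids), len(gene_ids)):
        raise ValueError("binary matrix shape must be (n_samples, n_genes)")
    gene_rank = sorted(range(len(gene_ids)), key=lambda j: (-b[:, j].sum(), j))
    keys = [tuple(b[i, j] for j in gene_rank) for i in range(len(sample_ids))]
    sample_rank = sorted(range(len(sample_ids)), key=lambda i: (tuple(-k for k in keys[i]), i))
    return (
        [sample_ids[i] for i in sample_rank],
        [gene_ids[j] for j in gene_rank],
    )


def alteration_counts(
    records: Sequence[AlterationRecord],
    gene_domain: ObservationDomain,
    sample_domain: ObservationDomain,
) -> tuple[dict[str, int], dict[str, int]]:
    """Marginal counts of altered cells per gene and per sample (a cell with
    several alteration types counts once)."""
    cells = {(r.sample, r.gene) for r in records}
    genes = {g: 0 for g in gene_domain.ids}
    samples = {s: 0 for s in sample_domain.ids}
    for s, g in cells:
        genes[g] += 1
        samples[s] += 1
    return genes, samples


def oncoprint_tiles(
    records: Sequence[AlterationRecord],
    gene_domain: ObservationDomain,
    sample_domain: ObservationDomain,
    style: Mapping[str, tuple[str, str]] = DEFAULT_ONCO_STYLE,
    background: str = "#ececec",
) -> DisplayList:
    """Gene x sample grid with one overlay rectangle per alteration type.

    Overlays are drawn thickest-first so thinner classes stay visible
    (full = whole cell, mid = central 40% of cell height, thin = central
    15%). Genes are rows, samples are columns."""
    vocab = set(style)
    for r in records:
        if r.type not in vocab:
            raise ValueError(
                f"unknown alteration type {r.type!r}; vocabulary: {sorted(vocab)}"
            )
        if r.gene not in set(gene_domain.ids):
            raise ValueError(f"record gene {r.gene!r} not in gene domain")
        if r.sample not in set(sample_domain.ids):
            raise ValueError(f"record sample {r.sample!r} not in sample domain")
    by_cell: dict[tuple[str, str], list[str]] = {}
    for r in records:
        by_cell.setdefault((r.sample, r.gene), []).append(r.type)

    dl = DisplayList()
    pad = 0.03  # fractional inset of the cell background
    for g in gene_domain.ids:
        ylo, yhi = y_interval(gene_domain, g)
        ch = yhi - ylo
        for s in sample_domain.ids:
            xlo, xhi = x_interval(sample_domain, s)
            ix, iy = pad * (xhi - xlo), pad * ch
            dl.add(Rect(xlo + ix, ylo + iy, xhi - ix, yhi - iy, fill=background))
            types = by_cell.get((s, g), [])
            types = sorted(set(types), key=lambda t: -THICKNESS[style[t][1]])
            for t in types:
                color, thickness = style[t]
                frac = THICKNESS[thickness]
                cy = 0.5 * (ylo + yhi)
                h = frac * (ch - 2 * iy)
                dl.add(Rect(xlo + ix, cy - h / 2, xhi - ix, cy + h / 2, fill=color))
    labs = tuple(sorted(style))
    dl.add_legend(LegendKey(title="alteration", labels=labs,
                            colors=tuple(style[t][0] for t in labs), kind="fill"))
    return dl


@dataclass
class Oncoprint(AlignedPlot):
    records: Sequence[AlterationRecord]
    genes: Sequence[str] | None = None
    samples: Sequence[str] | None = None
    style: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_ONCO_STYLE)
    )
    background: str = "#ececec"
    name: str = "oncoprint"

    def __post_init__(self) -> None:
        if self.genes is None:
            seen: list[str] = []
            for r in self.records:
                if r.gene not in seen:
                    seen.append(r.gene)
            self.genes = tuple(seen)
        if self.samples is None:
            seen = []
            for r in self.records:
                if r.sample not in seen:
                    seen.append(r.sample)
            self.samples = tuple(seen)

    def x_ids(self):
        return tuple(self.samples)

    def y_ids(self):
        return tuple(self.genes)

    def incidence(self) -> np.ndarray:
        """Binary sample x gene incidence matrix in input id order."""
        b = np.zeros((len(self.samples), len(self.genes)), dtype=int)
        si = {s: i for i, s in enumerate(self.samples)}
        gi = {g: j for j, g in enumerate(self.genes)}
        for r in self.records:
            b[si[r.sample], gi[r.gene]] = 1
        return b

    def waterfall_order(self) -> tuple[list[str], list[str]]:
        return memo_sort(self.incidence(), list(self.samples), list(self.genes))

    def render(self, x_domain=None, y_domain=None, scheme=None) -> DisplayList:
        gd = y_domain if y_domain is not None else create_domain(self.genes)
        sd = x_domain if x_domain is not None else create_domain(self.samples)
        return oncoprint_tiles(self.records, gd, sd, self.style, self.background)


# ---------------------------------------------------------------- summaries
def _box_stats(sample: np.ndarray) -> dict:
    q1, med, q3 = np.quantile(sample, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = sample[(sample >= lo_fence) & (sample <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_lo": float(inliers.min()),
        "whisker_hi": float(inliers.max()),
        "outliers": [float(v) for v in sample[(sample < lo_fence) | (sample > hi_fence)]],
    }


def aligned_summary_geoms(
    values: Mapping[str, float | Sequence[float]],
    domain: ObservationDomain,
    geom: str = "bar",
    orient: str = "v",
    vlim: tuple[float, float] | None = None,
    fill: str | Mapping[str, str] = "#4e79a7",
    width: float = 0.8,
) -> DisplayList:
    """Per-observation summary glyphs registered on the domain's intervals.

    geom 'bar': a rectangle per id from the value-axis origin to its value;
    'box': median/quartile glyph with 1.5*IQR whiskers and outlier markers;
    'point': one marker per id; 'line': a polyline through the per-id values
    in display order (rank/bump-chart style). ``orient`` 'v' puts the domain
    on x (values upward), 'h' on y (values rightward, row 0 at top).
    """
    missing = [i for i in domain.ids if i not in values]
    if missing:
        raise ValueError(f"values missing for ids: {missing}")
    if geom not in ("bar", "box", "point", "line"):
        raise ValueError(f"unknown geom {geom!r}")

    flat: list[float] = []
    for i in domain.ids:
        v = values[i]
        flat.extend(np.atleast_1d(np.asarray(v, dtype=float)).tolist())
    if vlim is None:
        lo = min(0.0, min(flat))
        hi = max(flat)
        if hi == lo:
            hi = lo + 1.0
        vlim = (lo, hi)

    def norm(v: float) -> float:
        return (v - vlim[0]) / (vlim[1] - vlim[0])

    def color(i: str) -> str:
        return fill if isinstance(fill, str) else fill[i]

    dl = DisplayList()

    def interval(i: str) -> tuple[float, float]:
        return x_interval(domain, i) if orient == "v" else y_interval(domain, i)

    def place_rect(i: str, a: float, b: float, v0: float, v1: float, **kw) -> Rect:
        # a..b along the domain axis, v0..v1 along the value axis
        if orient == "v":
            return Rect(a, v0, b, v1, **kw)
        return Rect(v0, a, v1, b, **kw)

    def place_seg(a: float, v0: float, v1: float, **kw) -> Segment:
        if orient == "v":
            return Segment(a, v0, a, v1, **kw)
        return Segment(v0, a, v1, a, **kw)

    def place_cross_seg(a0: float, a1: float, v: float, **kw) -> Segment:
        if orient == "v":
            return Segment(a0, v, a1, v, **kw)
        return Segment(v, a0, v, a1, **kw)

    if geom == "line":
        pts = []
        for i in domain.display_ids:
            lo_i, hi_i = interval(i)
            c = 0.5 * (lo_i + hi_i)
            v = norm(float(np.atleast_1d(values[i]).mean()))
            pts.append((c, v) if orient == "v" else (v, c))
        dl.add(Polyline(points=tuple(pts), stroke="#333333", width=1.2))
        return dl

    for i in domain.ids:
        lo_i, hi_i = interval(i)
        c = 0.5 * (lo_i + hi_i)
        half = 0.5 * width * (hi_i - lo_i)
        v = np.atleast_1d(np.asarray(values[i], dtype=float))
        if geom == "bar":
            dl.add(place_rect(i, c - half, c + half, norm(0.0), norm(float(v.mean())),
                              fill=color(i)))
        elif geom == "point":
            x, y = (c, norm(float(v.mean())))
            dl.add(Marker(*((x, y) if orient == "v" else (y, x)), radius=2.0,
                          fill=color(i)))
        elif geom == "box":
            st = _box_stats(v)
            if v.size == 1:  # degenerate: a line glyph at the value
                dl.add(place_cross_seg(c - half, c + half, norm(st["median"]),
                                       stroke="#000000", width=1.2))
                continue
            dl.add(place_seg(c, norm(st["whisker_lo"]), norm(st["q1"]),
                             stroke="#000000", width=0.8))
            dl.add(place_seg(c, norm(st["q3"]), norm(st["whisker_hi"]),
                             stroke="#000000", width=0.8))
            dl.add(place_rect(i, c - half, c + half, norm(st["q1"]), norm(st["q3"]),
                              fill=color(i), stroke="#000000", stroke_width=0.6))
            dl.add(place_cross_seg(c - half, c + half, norm(st["median"]),
                                   stroke="#000000", width=1.2))
            for o in st["outliers"]:
                x, y = c, norm(o)
                dl.add(Marker(*((x, y) if orient == "v" else (y, x)), radius=1.5,
                              fill="#000000"))
    return dl


@dataclass
class Summary(AlignedPlot):
    """Aligned bar/box/point/line annotation panel over the shared domain."""

    values: Mapping[str, float | Sequence[float]]
    geom: str = "bar"
    fill: str | Mapping[str, str] = "#4e79a7"
    vlim: tuple[float, float] | None = None
    name: str = "summary"

    def x_ids(self):
        return tuple(self.values)

    def y_ids(self):
        return tuple(self.values)

    def render(self, x_domain=None, y_domain=None, scheme=None) -> DisplayList:
        values = self.values
        if scheme is not None and scheme.data_transform is not None:
            values = {k: scheme.apply_transform(v) for k, v in values.items()}
        if x_domain is not None:
            return aligned_summary_geoms(values, x_domain, self.geom, "v",
                                         self.vlim, self.fill)
        if y_domain is not None:
            return aligned_summary_geoms(values, y_domain, self.geom, "h",
                                         self.vlim, self.fill)
        return aligned_summary_geoms(values, create_domain(tuple(values)),
                                     self.geom, "v", self.vlim, self.fill)


# ---------------------------------------------------------------- dendrogram
@dataclass
class DendrogramPlot(AlignedPlot):
    """Draws the dendrogram of the layout's clustering operator.

    ``side`` states where the panel sits relative to the panel it annotates:
    'top' (leaves at the bottom edge), 'bottom', 'left' (leaves at the right
    edge) or 'right'. The geometry itself is orientation-free; drawing swaps
    and flips axes.
    """

    result: HClustResult | None = None
    side: str = "top"
    stroke: str = "#333333"
    name: str = "dendrogram"

    def render(self, x_domain=None, y_domain=None, scheme=None) -> DisplayList:
        if self.result is None:
            raise ValueError(
                "dendrogram has no clustering result; add it through a layout "
                "hclust operator or pass result= explicitly"
            )
        domain = x_domain if x_domain is not None else y_domain
        if domain is None:
            domain = create_domain(self.result.order)
        geom = dendrogram_geometry(self.result, domain)
        return dendrogram_display(geom, side=self.side, stroke=self.stroke)


def dendrogram_display(
    geom: DendrogramGeometry, side: str = "top", stroke: str = "#333333"
) -> DisplayList:
    """Scale canonical dendrogram coordinates into the unit square for the
    given side. Leaf axis maps to leaf-fraction; height axis spans the panel
    with the root at the panel's outer edge."""
    if side not in ("top", "bottom", "left", "right"):
        raise ValueError(f"invalid side {side!r}")
    n = geom.n_leaves
    hmax = geom.max_height if geom.max_height > 0 else 1.0
    dl = DisplayList()

    def to_panel(x: float, y: float) -> tuple[float, float]:
        u = x / n          # leaf fraction, 0..1 left to right
        v = y / hmax       # height fraction, 0 at leaves
        if side == "top":
            return (u, v)
        if side == "bottom":
            return (u, 1.0 - v)
        if side == "left":  # leaves adjacent to the panel on the right
            return (1.0 - v, 1.0 - u)  # y-domain runs top-down
        return (v, 1.0 - u)  # right

    for seg in geom.segments:
        dl.add(Polyline(points=tuple(to_panel(x, y) for x, y in seg),
                        stroke=stroke, width=0.9))
    return dl


# ---------------------------------------------------------------- labels
@dataclass
class Labels(AlignedPlot):
    """Observation id labels, one per interval center."""

    ids: Sequence[str] | None = None
    size: float | None = None
    rotate: float = 0.0
    name: str = "labels"

    def x_ids(self):
        return tuple(self.ids) if self.ids else None

    def y_ids(self):
        return tuple(self.ids) if self.ids else None

    def render(self, x_domain=None, y_domain=None, scheme=None) -> DisplayList:
        size = self.size or (scheme.resolved_font_size() if scheme else 7.0)
        dl = DisplayList()
        if x_domain is not None:
            for i in x_domain.ids:
                lo, hi = x_interval(x_domain, i)
                dl.add(Text(0.5 * (lo + hi), 0.5, i, size=size, rotate=self.rotate))
        elif y_domain is not None:
            for i in y_domain.ids:
                lo, hi = y_interval(y_domain, i)
                dl.add(Text(0.5, 0.5 * (lo + hi), i, size=size, rotate=self.rotate))
        return dl


# ---------------------------------------------------------------- group bar
@dataclass
class GroupBar(AlignedPlot):
    """A thin colored band showing each observation's group membership."""

    palette: DiscretePalette | None = None
    name: str = "groups"

    def render(self, x_domain=None, y_domain=None, scheme=None) -> DisplayList:
        domain = x_domain if x_domain is not None else y_domain
        if domain is None or domain.groups is None:
            raise ValueError("group bar requires a grouped domain")
        pal = self.palette or DiscretePalette.for_labels(domain.group_order or
                                                         tuple(dict.fromkeys(
                                                             domain.groups[i]
                                                             for i in domain.display_ids)))
        dl = DisplayList()
        for i in domain.ids:
            g = domain.groups[i]
            if x_domain is not None:
                lo, hi = x_interval(domain, i)
                dl.add(Rect(lo, 0.0, hi, 1.0, fill=pal(g)))
            else:
                lo, hi = y_interval(domain, i)
                dl.add(Rect(0.0, lo, 1.0, hi, fill=pal(g)))
        dl.add_legend(pal.legend())
        return dl


# ---------------------------------------------------------------- free scatter
@dataclass
class Scatter:
    """A free (not observation-aligned) scatter panel with continuous limits,
    for data-free composition alongside aligned layouts."""

    x: Sequence[float]
    y: Sequence[float]
    color: str | Sequence[str] = "#4e79a7"
    radius: float = 2.0
    name: str = "scatter"

    def limits(self) -> tuple[tuple[float, float], tuple[float, float]]:
        xs, ys = np.asarray(self.x, float), np.asarray(self.y, float)
        return ((float(xs.min()), float(xs.max())),
                (float(ys.min()), float(ys.max())))

    def to_patch(self, scheme: Scheme | None = None) -> Patch:
        xs, ys = np.asarray(self.x, float), np.asarray(self.y, float)
        (xlo, xhi), (ylo, yhi) = self.limits()
        dl = DisplayList()
        for k in range(xs.size):
            c = self.color if isinstance(self.color, str) else self.color[k]
            dl.add(Marker(float(xs[k]), float(ys[k]), radius=self.radius, fill=c))
        return Patch(
            display=dl,
            x_axis=AxisSpec(aligned=True, limits=(xlo, xhi), expand=0.05),
            y_axis=AxisSpec(aligned=True, limits=(ylo, yhi), expand=0.05),
            name=self.name,
        )
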