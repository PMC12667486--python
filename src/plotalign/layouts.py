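"""Data-aware layout systems: StackLayout, QuadLayout and CircleLayout.

Each layout owns one observation domain per shared axis and runs the same
assembly pipeline: (1) unify the domains contributed by its panels, (2)
apply reordering/grouping operators in the order they were added, (3) solve
the panel geometry, (4) render every slot with the final domain, (5) apply
schemes (layout-level controls inherited by plots, plot-level overrides
winning), (6) merge legends, (7) emit a composed figure. Free slots skip
domain alignment on the shared axis, which is what enables crosswise
(bump-chart) links between panels ordering the same ids differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cluster import agglomerative_order, custom_order, kmeans_groups
from .composition import ComposedFigure, PanelInfo
from .domains import (
    ObservationDomain,
    create_domain,
    set_groups,
    set_order,
    unify_domains,
)
from .geometry import (
    PanelRect,
    Size,
    angular_map,
    circle_geometry,
    polar_point,
    polar_shape,
    quad_geometry,
    stack_geometry,
)
from .linking import LinkShape, LinkSpec, MarkPanel, PanelEdge, Selection, link_shapes
from .plots import AlignedPlot, DendrogramPlot
from .primitives import (
    DisplayList,
    Marker,
    Polygon,
    Polyline,
    Rect,
    Segment,
    Text,
    map_display_list,
)
from .scheme import Scheme, scheme_merge

__all__ = ["StackLayout", "QuadLayout", "CircleLayout", "assemble_layout"]


def _as_size(s) -> Size:
    return s if isinstance(s, Size) else Size(float(s))


@dataclass
class _Slot:
    plot: object
    size: Size
    name: str
    aligned: bool = True
    own_domain: ObservationDomain | None = None
    scheme: Scheme | None = None
    mark: MarkPanel | None = None
    mark_after: str | None = None  # name of the slot the mark annotates


class _OperatorMixin:
    """Shared reorder/group operator queue; applied in addition order."""

    def _init_ops(self) -> None:
        self._operators: list[tuple] = []
        self._pending_dendros: list[DendrogramPlot] = []

    def _apply_operators(
        self,
        domain: ObservationDomain,
        operators: list[tuple],
        dendros: list[DendrogramPlot] | None = None,
    ) -> ObservationDomain:
        if dendros is None:
            dendros = self._pending_dendros
        for op in operators:
            kind = op[0]
            if kind == "hclust":
                _, data, linkage, metric, lock = op
                groups = domain.groups
                res = agglomerative_order(
                    data,
                    ids=domain.ids,
                    linkage=linkage,
                    metric=metric,
                    groups=groups,
                    group_order=domain.group_order or None if groups else None,
                )
                domain = set_order(domain, res.order, lock=lock, source="hclust")
                for dendro in dendros:
                    if dendro.result is None:
                        dendro.result = res
            elif kind == "kmeans":
                _, data, k, seed = op
                mapping = kmeans_groups(data, domain.ids, k, seed)
                domain = set_groups(domain, mapping, source="kmeans")
            elif kind == "group":
                _, mapping, group_order, lock = op
                domain = set_groups(domain, mapping, group_order, lock=lock,
                                    source="group")
            elif kind == "order_by":
                _, weights, decreasing = op
                domain = set_order(domain, custom_order(domain, weights, decreasing),
                                   source="order_by")
            elif kind == "set_order":
                _, ids, lock = op
                domain = set_order(domain, ids, lock=lock, source="set_order")
            else:  # pragma: no cover
                raise ValueError(f"unknown operator {kind!r}")
        return domain


def _render_slot(
    plot: object,
    x_domain: ObservationDomain | None,
    y_domain: ObservationDomain | None,
    scheme: Scheme | None,
) -> tuple[DisplayList, tuple[float, float], tuple[float, float]]:
    """Render a slot's plot; returns (display list, x limits, y limits)."""
    if plot is None:
        return DisplayList(), (0.0, 1.0), (0.0, 1.0)
    if isinstance(plot, AlignedPlot):
        return plot.render(x_domain, y_domain, scheme), (0.0, 1.0), (0.0, 1.0)
    if hasattr(plot, "to_patch"):  # free panel with its own limits
        patch = plot.to_patch(scheme=scheme)
        return patch.display, patch.own_limits("x"), patch.own_limits("y")
    raise TypeError(f"slot holds an unrenderable object: {type(plot).__name__}")


def _link_layer(shapes: Sequence[LinkShape], fill: str = "#999999",
                opacity: float = 0.45) -> DisplayList:
    dl = DisplayList()
    for shp in shapes:
        for poly in shp.polygons:
            dl.add(Polygon(points=tuple(poly), fill=fill, opacity=opacity))
        for pts in shp.polylines:
            dl.add(Polyline(points=pts, stroke="#555555", width=0.9))
        for p0, p1 in shp.segments:
            dl.add(Segment(p0[0], p0[1], p1[0], p1[1], stroke="#555555", width=0.9))
    return dl


@dataclass
class _LinkRequest:
    a: str
    b: str
    spec_kw: dict


class StackLayout(_OperatorMixin):
    """Plots stacked along one direction, aligned on the perpendicular axis.

    direction 'vertical': panels are stacked top-to-bottom in addition order
    and share the observation domain on x. direction 'horizontal': panels run
    left-to-right and share the domain on y (top-down display order).
    """

    def __init__(
        self,
        direction: str = "vertical",
        ids: Sequence[str] | None = None,
        gap: float = 0.02,
        name: str = "stack",
        scheme: Scheme | None = None,
    ) -> None:
        if direction not in ("vertical", "horizontal"):
            raise ValueError("direction must be 'vertical' or 'horizontal'")
        self.direction = direction
        self.ids = tuple(ids) if ids is not None else None
        self.gap = gap
        self.name = name
        self.scheme = scheme or Scheme()
        self.slots: list[_Slot] = []
        self.links: list[_LinkRequest] = []
        self._init_ops()

    # -- building ------------------------------------------------------
    def add(self, plot, size: Size | float = 1.0, name: str | None = None,
            scheme: Scheme | None = None) -> "StackLayout":
        name = name or getattr(plot, "name", f"slot{len(self.slots)}")
        if isinstance(plot, DendrogramPlot):
            self._pending_dendros.append(plot)
            if plot.side == "top":
                plot.side = self._auto_dendro_side()
        self.slots.append(_Slot(plot=plot, size=_as_size(size), name=name,
                                scheme=scheme))
        return self

    def add_free(self, plot, size: Size | float = 1.0, name: str | None = None,
                 order: Sequence[str] | None = None,
                 scheme: Scheme | None = None) -> "StackLayout":
        """Add a freely positioned panel: it occupies a slot but does not
        participate in domain alignment. ``order`` gives it its own local
        display order of the shared ids (crosswise links use it)."""
        name = name or getattr(plot, "name", f"slot{len(self.slots)}")
        own = None
        if order is not None:
            own = set_order(create_domain(sorted(order), name=name), order)
        self.slots.append(_Slot(plot=plot, size=_as_size(size), name=name,
                                aligned=False, own_domain=own, scheme=scheme))
        return self

    def _auto_dendro_side(self) -> str:
        return "top" if self.direction == "vertical" else "left"

    # -- operators -----------------------------------------------------
    def hclust(self, data, linkage: str = "complete", metric: str = "euclidean",
               lock: bool = False) -> "StackLayout":
        self._operators.append(("hclust", np.asarray(data, float), linkage, metric,
                                lock))
        return self

    def add_dendrogram(self, data=None, linkage: str = "complete",
                       metric: str = "euclidean", size: Size | float = 0.3,
                       name: str = "dendrogram") -> "StackLayout":
        """Cluster the shared observations and draw the dendrogram in its own
        slot; the resulting leaf order propagates to every aligned panel."""
        if data is not None:
            self.hclust(data, linkage=linkage, metric=metric)
        dendro = DendrogramPlot(side=self._auto_dendro_side(), name=name)
        self.add(dendro, size=size, name=name)
        return self

    def kmeans(self, data, k: int, seed: int = 0) -> "StackLayout":
        self._operators.append(("kmeans", np.asarray(data, float), k, seed))
        return self

    def group_by(self, mapping: Mapping[str, str],
                 group_order: Sequence[str] | None = None,
                 lock: bool = False) -> "StackLayout":
        self._operators.append(("group", dict(mapping), group_order, lock))
        return self

    def order_by(self, weights: Mapping[str, float],
                 decreasing: bool = False) -> "StackLayout":
        self._operators.append(("order_by", dict(weights), decreasing))
        return self

    def reorder(self, ids: Sequence[str], lock: bool = False) -> "StackLayout":
        self._operators.append(("set_order", tuple(ids), lock))
        return self

    # -- links / marks --------------------------------------------------
    def link(self, a: str, b: str, ids: Sequence[str] | None = None,
             geometry: str = "polygon", pairing="by_id",
             style: str = "straight") -> "StackLayout":
        """Connect observations across the gap between slots ``a`` and ``b``
        (names). ``ids`` defaults to all shared ids."""
        self.links.append(_LinkRequest(a=a, b=b, spec_kw=dict(
            ids=ids, geometry=geometry, pairing=pairing, style=style)))
        return self

    def add_mark(self, mark: MarkPanel, after: str | None = None,
                 size: Size | float | None = None) -> "StackLayout":
        """Insert a mark-annotation panel as a new slot joined by connector
        ribbons to the slot named ``after`` (default: the last slot)."""
        anchor = after or (self.slots[-1].name if self.slots else None)
        if anchor is None:
            raise ValueError("add a plot before attaching a mark panel")
        self.slots.append(_Slot(
            plot=mark.plot, size=_as_size(size if size is not None else mark.size),
            name=f"mark:{anchor}", aligned=False, mark=mark, mark_after=anchor))
        return self

    # -- assembly --------------------------------------------------------
    def _shared_ids(self) -> tuple[str, ...]:
        if self.ids is not None:
            return self.ids
        for s in self.slots:
            if s.aligned and isinstance(s.plot, AlignedPlot):
                ids = (s.plot.x_ids() if self.direction == "vertical"
                       else s.plot.y_ids())
                if ids:
                    return tuple(ids)
        raise ValueError(f"stack {self.name!r}: no shared ids; pass ids= or add "
                         "an aligned plot that declares them")

    def resolve_domain(self) -> ObservationDomain:
        """Unified, operator-applied domain (pipeline steps 1-2)."""
        base = create_domain(self._shared_ids(), name=self.name)
        contributed = [base] + [
            s.own_domain for s in self.slots if s.aligned and s.own_domain is not None
        ]
        domain = unify_domains(contributed)
        return self._apply_operators(domain, self._operators)

    def assemble(self, size_in: tuple[float, float] = (6.0, 6.0),
                 extent: PanelRect | None = None) -> ComposedFigure:
        domain = self.resolve_domain()
        extent = extent or PanelRect(0.0, 0.0, 1.0, 1.0)
        ivs = stack_geometry([s.size for s in self.slots], gap=self.gap)
        rects: dict[str, PanelRect] = {}
        for s, (lo, hi) in zip(self.slots, ivs):
            if self.direction == "vertical":  # slot 0 on top
                rects[s.name] = PanelRect(
                    extent.x0, extent.y1 - hi * extent.height,
                    extent.x1, extent.y1 - lo * extent.height)
            else:
                rects[s.name] = PanelRect(
                    extent.x0 + lo * extent.width, extent.y0,
                    extent.x0 + hi * extent.width, extent.y1)

        fig = DisplayList()
        panels: dict = {}
        shapes: list[LinkShape] = []
        slot_domains: dict[str, ObservationDomain | None] = {}
        for s in self.slots:
            sch = scheme_merge(self.scheme, s.scheme or Scheme())
            if s.mark is not None:
                sub_ids = s.mark.sub_domain_ids(domain)
                sd = create_domain(sub_ids, name=s.name)
                slot_domains[s.name] = sd
                xd, yd = ((sd, None) if self.direction == "vertical" else (None, sd))
            elif s.aligned:
                slot_domains[s.name] = domain
                xd, yd = ((domain, None) if self.direction == "vertical"
                          else (None, domain))
            else:
                slot_domains[s.name] = s.own_domain
                xd, yd = ((s.own_domain, None) if self.direction == "vertical"
                          else (None, s.own_domain))
            dl, xlim, ylim = _render_slot(s.plot, xd, yd, sch)
            rect = rects[s.name]
            if sch.background:
                fig.add(Rect(rect.x0, rect.y0, rect.x1, rect.y1,
                             fill=sch.background))
            fig.extend(map_display_list(dl, xlim, ylim, rect.x_extent,
                                        rect.y_extent))
            panels[s.name] = PanelInfo(
                rect=rect, xlim=xlim, ylim=ylim, name=s.name,
                x_domain=xd, y_domain=yd)

        # mark connectors
        for s in self.slots:
            if s.mark is None:
                continue
            main = rects[s.mark_after]
            own = rects[s.name]
            main_edge, annot_edge = self._facing_edges(
                s.mark_after, s.name, main, own,
                slot_domains[s.mark_after], slot_domains[s.name])
            for poly in s.mark.connectors(main_edge, annot_edge):
                fig.add(Polygon(points=poly, fill=s.mark.fill,
                                opacity=s.mark.opacity))

        # links
        for req in self.links:
            ra, rb = rects[req.a], rects[req.b]
            da, db = slot_domains[req.a], slot_domains[req.b]
            if da is None or db is None:
                raise ValueError("linked slots must carry a domain")
            kw = dict(req.spec_kw)
            ids = kw.pop("ids", None)
            members_a = tuple(ids) if ids else da.display_ids
            members_b = tuple(ids) if ids else db.display_ids
            edge_a, edge_b = self._facing_edges(req.a, req.b, ra, rb, da, db)
            spec = LinkSpec(left=Selection(members_a), right=Selection(members_b),
                            **kw)
            shp = link_shapes(spec, edge_a, edge_b)
            shapes.append(shp)
        fig.extend(_link_layer(shapes))

        legends = _collect_legends(fig)
        return ComposedFigure(display=fig, panels=panels, legends=legends,
                              width_in=size_in[0], height_in=size_in[1])

    def _facing_edges(self, name_a, name_b, ra: PanelRect, rb: PanelRect,
                      da, db) -> tuple[PanelEdge, PanelEdge]:
        order = [s.name for s in self.slots]
        if order.index(name_a) > order.index(name_b):
            ra, rb, da, db = rb, ra, db, da
        if self.direction == "horizontal":
            return (
                PanelEdge(domain=da, orientation="vertical", coord=ra.x1,
                          extent=ra.y_extent),
                PanelEdge(domain=db, orientation="vertical", coord=rb.x0,
                          extent=rb.y_extent),
            )
        # vertical stack: a above b; facing edges horizontal
        return (
            PanelEdge(domain=da, orientation="horizontal", coord=ra.y0,
                      extent=ra.x_extent),
            PanelEdge(domain=db, orientation="horizontal", coord=rb.y1,
                      extent=rb.x_extent),
        )


def _collect_legends(fig: DisplayList):
    seen: dict[tuple, object] = {}
    for key in fig.legends:
        seen.setdefault(key.identity(), key)
    return list(seen.values())


class QuadLayout(_OperatorMixin):
    """A central matrix-like plot with annotation stacks on its four sides.

    Top/bottom annotations align to the column domain, left/right to the row
    domain; the alignment contract is that every top/bottom panel shares the
    central panel's x extent exactly, and left/right its y extent.
    """

    def __init__(self, central: AlignedPlot, row_ids=None, col_ids=None,
                 gap: float = 0.015, name: str = "quad",
                 scheme: Scheme | None = None) -> None:
        self.central = central
        self.row_ids = tuple(row_ids) if row_ids is not None else tuple(
            central.y_ids() or ())
        self.col_ids = tuple(col_ids) if col_ids is not None else tuple(
            central.x_ids() or ())
        if not self.row_ids or not self.col_ids:
            raise ValueError("central plot must declare row and column ids")
        self.gap = gap
        self.name = name
        self.scheme = scheme or Scheme()
        self.sides: dict[str, list[_Slot]] = {
            "top": [], "bottom": [], "left": [], "right": []}
        self._init_ops()
        self._row_ops: list[tuple] = []
        self._col_ops: list[tuple] = []
        self._row_dendros: list[DendrogramPlot] = []
        self._col_dendros: list[DendrogramPlot] = []
        self.marks: list[MarkPanel] = []

    # -- building ------------------------------------------------------
    def annotate(self, side: str, plot, size: Size | float = 0.25,
                 name: str | None = None,
                 scheme: Scheme | None = None) -> "QuadLayout":
        """Add an annotation panel; index 0 is adjacent to the central panel."""
        if side not in self.sides:
            raise ValueError(f"invalid side {side!r}")
        name = name or f"{side}{len(self.sides[side])}"
        if isinstance(plot, DendrogramPlot):
            plot.side = side
            if side in ("left", "right"):
                self._row_dendros.append(plot)
            else:
                self._col_dendros.append(plot)
        self.sides[side].append(_Slot(plot=plot, size=_as_size(size), name=name,
                                      scheme=scheme))
        return self

    def add_dendrogram(self, side: str, data=None, linkage: str = "complete",
                       metric: str = "euclidean",
                       size: Size | float = 0.2) -> "QuadLayout":
        if data is None:
            data = self._central_matrix(side)
        if side in ("left", "right"):
            self._row_ops.append(("hclust", np.asarray(data, float), linkage,
                                  metric, False))
        else:
            self._col_ops.append(("hclust", np.asarray(data, float), linkage,
                                  metric, False))
        return self.annotate(side, DendrogramPlot(side=side), size=size,
                             name=f"dendro_{side}")

    def _central_matrix(self, side: str) -> np.ndarray:
        values = getattr(self.central, "values", None)
        if values is None:
            raise ValueError("pass data= explicitly; the central plot holds no matrix")
        return np.asarray(values, float) if side in ("left", "right") else \
            np.asarray(values, float).T

    def hclust_rows(self, data=None, linkage="complete", metric="euclidean",
                    lock=False) -> "QuadLayout":
        data = self._central_matrix("left") if data is None else data
        self._row_ops.append(("hclust", np.asarray(data, float), linkage, metric,
                              lock))
        return self

    def hclust_cols(self, data=None, linkage="complete", metric="euclidean",
                    lock=False) -> "QuadLayout":
        data = self._central_matrix("top") if data is None else data
        self._col_ops.append(("hclust", np.asarray(data, float), linkage, metric,
                              lock))
        return self

    def kmeans_rows(self, k: int, seed: int = 0, data=None) -> "QuadLayout":
        data = self._central_matrix("left") if data is None else data
        self._row_ops.append(("kmeans", np.asarray(data, float), k, seed))
        return self

    def kmeans_cols(self, k: int, seed: int = 0, data=None) -> "QuadLayout":
        data = self._central_matrix("top") if data is None else data
        self._col_ops.append(("kmeans", np.asarray(data, float), k, seed))
        return self

    def group_rows(self, mapping, group_order=None, lock=False) -> "QuadLayout":
        self._row_ops.append(("group", dict(mapping), group_order, lock))
        return self

    def group_cols(self, mapping, group_order=None, lock=False) -> "QuadLayout":
        self._col_ops.append(("group", dict(mapping), group_order, lock))
        return self

    def order_rows(self, weights, decreasing=False) -> "QuadLayout":
        self._row_ops.append(("order_by", dict(weights), decreasing))
        return self

    def order_cols(self, weights, decreasing=False) -> "QuadLayout":
        self._col_ops.append(("order_by", dict(weights), decreasing))
        return self

    def reorder_rows(self, ids: Sequence[str], lock: bool = False) -> "QuadLayout":
        self._row_ops.append(("set_order", tuple(ids), lock))
        return self

    def reorder_cols(self, ids: Sequence[str], lock: bool = False) -> "QuadLayout":
        self._col_ops.append(("set_order", tuple(ids), lock))
        return self

    def add_mark(self, mark: MarkPanel, size: Size | float = 0.25) -> "QuadLayout":
        """Annotate a selected subset of rows (side left/right) or columns
        (side top/bottom) with its own panel plus connector ribbons. The panel
        is appended as the outermost slot of that side's stack."""
        self.marks.append(mark)
        self.sides[mark.side].append(_Slot(
            plot=mark.plot, size=_as_size(size), name=f"mark_{mark.side}",
            aligned=False, mark=mark))
        return self

    # -- assembly --------------------------------------------------------
    def resolve_domains(self) -> tuple[ObservationDomain, ObservationDomain]:
        rows = create_domain(self.row_ids, name=f"{self.name}.rows")
        cols = create_domain(self.col_ids, name=f"{self.name}.cols")
        rows = self._apply_operators(rows, self._row_ops, self._row_dendros)
        cols = self._apply_operators(cols, self._col_ops, self._col_dendros)
        return rows, cols

    def assemble(self, size_in: tuple[float, float] = (7.0, 7.0),
                 central_size: tuple[float, float] = (1.0, 1.0)) -> ComposedFigure:
        rows, cols = self.resolve_domains()
        geom = quad_geometry(
            central=central_size,
            top=[s.size for s in self.sides["top"]],
            bottom=[s.size for s in self.sides["bottom"]],
            left=[s.size for s in self.sides["left"]],
            right=[s.size for s in self.sides["right"]],
            gap=self.gap,
        )
        fig = DisplayList()
        panels: dict = {}

        def emit(key, slot_name, plot, xd, yd, scheme):
            rect = geom[key]
            sch = scheme_merge(self.scheme, scheme or Scheme())
            dl, xlim, ylim = _render_slot(plot, xd, yd, sch)
            if sch.background:
                fig.add(Rect(rect.x0, rect.y0, rect.x1, rect.y1, fill=sch.background))
            fig.extend(map_display_list(dl, xlim, ylim, rect.x_extent, rect.y_extent))
            panels[slot_name] = PanelInfo(rect=rect, xlim=xlim, ylim=ylim,
                                          name=slot_name, x_domain=xd, y_domain=yd)

        emit("central", "central", self.central, cols, rows, None)
        mark_jobs: list[tuple[MarkPanel, str]] = []
        for side, slots in self.sides.items():
            for i, s in enumerate(slots):
                if s.mark is not None:
                    main_domain = rows if side in ("left", "right") else cols
                    sub = create_domain(s.mark.sub_domain_ids(main_domain),
                                        name=s.name)
                    xd, yd = ((None, sub) if side in ("left", "right")
                              else (sub, None))
                    mark_jobs.append((s.mark, s.name))
                elif side in ("left", "right"):
                    xd, yd = None, rows
                else:
                    xd, yd = cols, None
                emit((side, i), s.name, s.plot, xd, yd, s.scheme)

        # mark connector ribbons between the mark panel and its neighbor panel
        for mark, slot_name in mark_jobs:
            side = mark.side
            idx = [s.name for s in self.sides[side]].index(slot_name)
            neighbor_key = (side, idx - 1) if idx > 0 else "central"
            neighbor_name = (self.sides[side][idx - 1].name if idx > 0
                             else "central")
            nrect, orect = geom[neighbor_key], geom[(side, idx)]
            main_domain = rows if side in ("left", "right") else cols
            sub_domain = (panels[slot_name].y_domain
                          if side in ("left", "right")
                          else panels[slot_name].x_domain)
            if side == "right":
                main_edge = PanelEdge(main_domain, "vertical", nrect.x1,
                                      nrect.y_extent)
                annot_edge = PanelEdge(sub_domain, "vertical", orect.x0,
                                       orect.y_extent)
            elif side == "left":
                main_edge = PanelEdge(main_domain, "vertical", nrect.x0,
                                      nrect.y_extent)
                annot_edge = PanelEdge(sub_domain, "vertical", orect.x1,
                                       orect.y_extent)
            elif side == "top":
                main_edge = PanelEdge(main_domain, "horizontal", nrect.y1,
                                      nrect.x_extent)
                annot_edge = PanelEdge(sub_domain, "horizontal", orect.y0,
                                       orect.x_extent)
            else:
                main_edge = PanelEdge(main_domain, "horizontal", nrect.y0,
                                      nrect.x_extent)
                annot_edge = PanelEdge(sub_domain, "horizontal", orect.y1,
                                       orect.x_extent)
            for poly in mark.connectors(main_edge, annot_edge):
                fig.add(Polygon(points=poly, fill=mark.fill, opacity=mark.opacity))

        legends = _collect_legends(fig)
        return ComposedFigure(display=fig, panels=panels, legends=legends,
                              width_in=size_in[0], height_in=size_in[1])


class CircleLayout(_OperatorMixin):
    """Plots as concentric annuli sharing one angular observation domain.

    Slots are added inner to outer; sectors start at 12 o'clock and run
    clockwise. With a grouped domain, an angular gap separates the groups at
    every boundary including the wrap-around one.
    """

    def __init__(self, ids: Sequence[str] | None = None, r_inner: float = 0.25,
                 gap_angle: float = 0.0, radial_gap: float = 0.02,
                 name: str = "circle", scheme: Scheme | None = None) -> None:
        self.ids = tuple(ids) if ids is not None else None
        self.r_inner = r_inner
        self.gap_angle = gap_angle
        self.radial_gap = radial_gap
        self.name = name
        self.scheme = scheme or Scheme()
        self.slots: list[_Slot] = []
        self._init_ops()

    def add(self, plot, size: Size | float = 1.0, name: str | None = None,
            scheme: Scheme | None = None) -> "CircleLayout":
        name = name or getattr(plot, "name", f"slot{len(self.slots)}")
        self.slots.append(_Slot(plot=plot, size=_as_size(size), name=name,
                                scheme=scheme))
        return self

    hclust = StackLayout.hclust
    kmeans = StackLayout.kmeans
    group_by = StackLayout.group_by
    order_by = StackLayout.order_by
    reorder = StackLayout.reorder

    def _shared_ids(self) -> tuple[str, ...]:
        if self.ids is not None:
            return self.ids
        for s in self.slots:
            if isinstance(s.plot, AlignedPlot):
                ids = s.plot.x_ids()
                if ids:
                    return tuple(ids)
        raise ValueError(f"circle {self.name!r}: no shared ids")

    def resolve_domain(self) -> ObservationDomain:
        domain = create_domain(self._shared_ids(), name=self.name)
        return self._apply_operators(domain, self._operators)

    def assemble(self, size_in: tuple[float, float] = (6.0, 6.0)) -> ComposedFigure:
        domain = self.resolve_domain()
        bands = circle_geometry([s.size for s in self.slots],
                                r_inner=self.r_inner, r_outer=1.0,
                                gap=self.radial_gap)
        theta = angular_map(domain, self.gap_angle)
        fig = DisplayList()
        panels: dict = {}
        for s, band in zip(self.slots, bands):
            sch = scheme_merge(self.scheme, s.scheme or Scheme())
            dl, _, _ = _render_slot(s.plot, domain, None, sch)
            fig.extend(_polar_display(dl, band, theta))
            panels[s.name] = PanelInfo(
                rect=PanelRect(0.0, 0.0, 1.0, 1.0), xlim=(0.0, 1.0),
                ylim=(0.0, 1.0), name=s.name, x_domain=domain, y_domain=None)
        legends = _collect_legends(fig)
        return ComposedFigure(display=fig, panels=panels, legends=legends,
                              width_in=size_in[0], height_in=size_in[1])


def _polar_display(dl: DisplayList, band, theta) -> DisplayList:
    """Map a unit-square display list into an annulus band on the unit disc."""
    out = DisplayList(legends=list(dl.legends))
    for p in dl.primitives:
        if isinstance(p, Rect):
            poly = polar_shape((p.x0, p.y0, p.x1, p.y1), band, theta)
            if poly is not None:
                out.add(Polygon(points=tuple(poly), fill=p.fill, stroke=p.stroke,
                                stroke_width=p.stroke_width, opacity=p.opacity))
        elif isinstance(p, Segment):
            pts = _polar_sample([(p.x0, p.y0), (p.x1, p.y1)], band, theta)
            out.add(Polyline(points=pts, stroke=p.stroke, width=p.width,
                             opacity=p.opacity))
        elif isinstance(p, Polyline):
            out.add(Polyline(points=_polar_sample(list(p.points), band, theta),
                             stroke=p.stroke, width=p.width, opacity=p.opacity))
        elif isinstance(p, Polygon):
            out.add(Polygon(points=_polar_sample(list(p.points), band, theta),
                            fill=p.fill, stroke=p.stroke,
                            stroke_width=p.stroke_width, opacity=p.opacity))
        elif isinstance(p, Text):
            x, y = polar_point(p.x, p.y, band, theta)
            out.add(Text(x, y, p.text, size=p.size, anchor=p.anchor,
                         color=p.color))
        elif isinstance(p, Marker):
            x, y = polar_point(p.x, p.y, band, theta)
            out.add(Marker(x, y, radius=p.radius, fill=p.fill, stroke=p.stroke,
                           opacity=p.opacity))
    return out


def _polar_sample(pts, band, theta, max_step: float = 0.02):
    """Map a polyline point list, subdividing spans in x so arcs stay smooth."""
    out: list[tuple[float, float]] = []
    for k in range(len(pts) - 1):
        (x0, y0), (x1, y1) = pts[k], pts[k + 1]
        m = max(1, int(abs(x1 - x0) / max_step))
        for j in range(m):
            t = j / m
            out.append(polar_point(x0 + t * (x1 - x0), y0 + t * (y1 - y0),
                                   band, theta))
    out.append(polar_point(*pts[-1], band, theta))
    return tuple(out)


def assemble_layout(layout, **kwargs) -> ComposedFigure:
    """Run a layout's assembly pipeline and return the composed figure."""
    return layout.assemble(**kwargs)
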