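"""Observation-level links between panels: selections, pairing rules, and
the segment/ribbon geometry spanning inter-panel gaps.

Each side of a link resolves its selected observations against *its own*
panel's domain, so two panels showing the same ids in different orders
produce crossing shapes naturally (the bump-chart / crosswise case). Line
geometry connects interval centers; polygon geometry spans the full
intervals with quadrilateral ribbons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .domains import DomainError, ObservationDomain, observation_interval

__all__ = [
    "Selection",
    "PanelEdge",
    "LinkSpec",
    "LinkShape",
    "resolve_selection",
    "link_shapes",
    "MarkPanel",
    "mark_panel",
]


@dataclass(frozen=True)
class Selection:
    """A set of observations on one panel, by id; resolved to display ranges
    against the panel's current (possibly reordered) domain."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(str(m) for m in self.members))


def resolve_selection(
    sel: Selection | Sequence[str], domain: ObservationDomain
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive display positions covered by the selection,
    as half-open position ranges [start, end)."""
    members = sel.members if isinstance(sel, Selection) else tuple(sel)
    ids = set(domain.ids)
    for m in members:
        if m not in ids:
            raise DomainError(f"unknown id {m!r} in selection")
    positions = sorted(domain.position(m) for m in members)
    runs: list[tuple[int, int]] = []
    for p in positions:
        if runs and p == runs[-1][1]:
            runs[-1] = (runs[-1][0], p + 1)
        else:
            runs.append((p, p + 1))
    return runs


@dataclass(frozen=True)
class PanelEdge:
    """One panel edge that links attach to.

    ``orientation`` 'vertical' means the edge is a vertical line at
    ``coord`` = x, with the observation domain running along y (top-down,
    matching the matrix display convention); 'horizontal' means a horizontal
    line at ``coord`` = y with the domain running along x (left-right).
    ``extent`` is the edge's span along its own axis in figure units.
    """

    domain: ObservationDomain
    orientation: str  # vertical | horizontal
    coord: float
    extent: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError("orientation must be 'vertical' or 'horizontal'")

    def interval_of(self, id_: str) -> tuple[float, float]:
        """Figure-coordinate interval of one observation along the edge."""
        lo, hi = observation_interval(self.domain, id_, (0.0, 1.0))
        if self.orientation == "vertical":  # domain runs top-down along y
            lo, hi = 1.0 - hi, 1.0 - lo
        e0, e1 = self.extent
        return (e0 + lo * (e1 - e0), e0 + hi * (e1 - e0))

    def interval_of_range(self, run: tuple[int, int]) -> tuple[float, float]:
        """Figure-coordinate interval of a display-position range."""
        n = len(self.domain)
        lo, hi = run[0] / n, run[1] / n
        if self.orientation == "vertical":
            lo, hi = 1.0 - hi, 1.0 - lo
        e0, e1 = self.extent
        return (e0 + lo * (e1 - e0), e0 + hi * (e1 - e0))

    def point(self, along: float) -> tuple[float, float]:
        if self.orientation == "vertical":
            return (self.coord, along)
        return (along, self.coord)


@dataclass(frozen=True)
class LinkSpec:
    """What to connect and how.

    kind 'two_sided' references selections on two panels; 'one_sided'
    connects a selection to an annotation target (see :func:`mark_panel`).
    pairing: 'by_id' (matching identifiers; default for two-sided), 'product'
    (every left to every right; default for one-sided), or explicit
    (left_id, right_id) pairs. geometry: 'line' or 'polygon'.
    """

    left: Selection
    right: Selection
    kind: str = "two_sided"
    geometry: str = "line"
    pairing: str | tuple[tuple[str, str], ...] = "by_id"
    style: str = "straight"  # straight | curve

    def __post_init__(self) -> None:
        if self.geometry not in ("line", "polygon"):
            raise ValueError("geometry must be 'line' or 'polygon'")
        if isinstance(self.pairing, str) and self.pairing not in ("by_id", "product"):
            raise ValueError("pairing must be 'by_id', 'product', or explicit pairs")


@dataclass
class LinkShape:
    """Concrete connector geometry in figure coordinates."""

    segments: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )
    polylines: list[tuple[tuple[float, float], ...]] = field(default_factory=list)
    polygons: list[tuple[tuple[float, float], ...]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.segments) + len(self.polylines) + len(self.polygons)


def _center(iv: tuple[float, float]) -> float:
    return 0.5 * (iv[0] + iv[1])


def _curve(p0, p1, samples: int = 24) -> tuple[tuple[float, float], ...]:
    """Quadratic curve with one control point at the gap midpoint, pulled
    perpendicular-free (pure easing along the gap axis)."""
    cx, cy = 0.5 * (p0[0] + p1[0]), 0.5 * (p0[1] + p1[1])
    pts = []
    for k in range(samples + 1):
        t = k / samples
        x = (1 - t) ** 2 * p0[0] + 2 * (1 - t) * t * cx + t**2 * p1[0]
        y = (1 - t) ** 2 * p0[1] + 2 * (1 - t) * t * cy + t**2 * p1[1]
        pts.append((x, y))
    return tuple(pts)


def link_shapes(
    spec: LinkSpec, left_edge: PanelEdge, right_edge: PanelEdge
) -> LinkShape:
    """Build connector geometry between two facing panel edges.

    Line geometry: one segment per pair, from the left member's interval
    center to the right member's interval center. Polygon geometry: one
    quadrilateral ribbon per (left range, right range) pair spanning the
    full intervals (per-id ribbons for by-id pairing). Positions come from
    each side's own domain, so differing orders cross naturally.
    """
    shape = LinkShape()
    lm, rm = spec.left.members, spec.right.members
    if not lm or not rm:
        warnings.warn("empty selection on a link side; no shapes emitted",
                      stacklevel=2)
        return shape

    if spec.geometry == "line":
        pairs: list[tuple[str, str]]
        if spec.pairing == "by_id":
            common = [m for m in lm if m in set(rm)]
            pairs = [(m, m) for m in common]
        elif spec.pairing == "product":
            pairs = [(a, b) for a in lm for b in rm]
        else:
            pairs = list(spec.pairing)
        for a, b in pairs:
            p0 = left_edge.point(_center(left_edge.interval_of(a)))
            p1 = right_edge.point(_center(right_edge.interval_of(b)))
            if spec.style == "curve":
                shape.polylines.append(_curve(p0, p1))
            else:
                shape.segments.append((p0, p1))
        return shape

    # polygon ribbons
    if spec.pairing == "by_id":
        common = [m for m in lm if m in set(rm)]
        range_pairs = [
            (left_edge.interval_of(m), right_edge.interval_of(m)) for m in common
        ]
    elif spec.pairing == "product":
        lruns = resolve_selection(spec.left, left_edge.domain)
        rruns = resolve_selection(spec.right, right_edge.domain)
        range_pairs = [
            (left_edge.interval_of_range(a), right_edge.interval_of_range(b))
            for a in lruns
            for b in rruns
        ]
    else:
        range_pairs = [
            (left_edge.interval_of(a), right_edge.interval_of(b))
            for a, b in spec.pairing
        ]
    for (l0, l1), (r0, r1) in range_pairs:
        shape.polygons.append(
            (
                left_edge.point(l0),
                left_edge.point(l1),
                right_edge.point(r1),
                right_edge.point(r0),
            )
        )
    return shape


@dataclass
class MarkPanel:
    """An annotation panel for a selected subset of observations, joined to
    the main panel by connector ribbons.

    The annotation panel's internal domain is the selected subset in the main
    panel's display order; each maximal source range contributes one ribbon
    from its interval on the main edge to the matching interval on the
    annotation edge (which the ribbons jointly tile)."""

    selection: Selection
    plot: object  # an AlignedPlot rendered inside the annotation panel
    side: str = "right"
    size: float = 1.0
    fill: str = "#bbbbbb"
    opacity: float = 0.45

    def __post_init__(self) -> None:
        if not self.selection.members:
            raise ValueError("mark panel selection must be non-empty")
        if self.side not in ("left", "right", "top", "bottom"):
            raise ValueError(f"invalid side {self.side!r}")

    def sub_domain_ids(self, main_domain: ObservationDomain) -> tuple[str, ...]:
        members = set(self.selection.members)
        return tuple(i for i in main_domain.display_ids if i in members)

    def connectors(
        self, main_edge: PanelEdge, annot_edge: PanelEdge
    ) -> list[tuple[tuple[float, float], ...]]:
        """Ribbon polygons from the selected ranges to the annotation edge."""
        runs = resolve_selection(self.selection, main_edge.domain)
        sub = annot_edge.domain
        polys: list[tuple[tuple[float, float], ...]] = []
        for run in runs:
            src = main_edge.interval_of_range(run)
            run_ids = [
                main_edge.domain.display_ids[p] for p in range(run[0], run[1])
            ]
            dst_positions = sorted(sub.position(i) for i in run_ids)
            dst = annot_edge.interval_of_range(
                (dst_positions[0], dst_positions[-1] + 1)
            )
            polys.append(
                (
                    main_edge.point(src[0]),
                    main_edge.point(src[1]),
                    annot_edge.point(dst[1]),
                    annot_edge.point(dst[0]),
                )
            )
        return polys


def mark_panel(
    selection: Selection | Sequence[str],
    annotation_plot,
    side: str = "right",
    size: float = 1.0,
) -> MarkPanel:
    """Declare a mark-annotation panel; layouts insert it on the given side."""
    sel = selection if isinstance(selection, Selection) else Selection(tuple(selection))
    return MarkPanel(selection=sel, plot=annotation_plot, side=side, size=size)
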