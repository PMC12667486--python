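"""Data-free composition: wrap rendered plots as patches, arrange patches on
a grid with coordinated axis limits and spacing, and merge legends.

A :class:`Patch` is a rendered panel (display list in its own data
coordinates) plus the metadata a composer needs: a size request, per-axis
alignment flags with declared limits, and per-side border allowances. The
composer solves column widths / row heights, unifies the axis limits of
aligned panels within each column (x) and row (y) to the union of their
declared limits, and maps every display list into figure coordinates.
Panels marked free on an axis keep their own limits; free-space sides are
excluded from border negotiation; free-border sides keep their own borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .geometry import PanelRect, Size, rel, stack_geometry
from .primitives import DisplayList, LegendKey, map_display_list
from .scheme import Scheme

__all__ = [
    "AxisSpec",
    "Patch",
    "to_patch",
    "spacer",
    "ComposedFigure",
    "compose_grid",
    "merge_guides",
]


@dataclass(frozen=True)
class AxisSpec:
    """Alignment contract of one patch axis.

    An aligned axis must declare its limits (they feed limit unification);
    a free axis keeps whatever limits it rendered with.
    """

    aligned: bool = True
    limits: tuple[float, float] | None = None
    discrete: bool = False
    expand: float = 0.0  # fractional margin added on each side when drawing

    def __post_init__(self) -> None:
        if self.aligned and self.limits is None:
            raise ValueError("an aligned axis must declare its limits")


def _default_axis() -> AxisSpec:
    return AxisSpec(aligned=True, limits=(0.0, 1.0))


@dataclass
class Patch:
    """A rendered panel plus alignment-edge metadata."""

    display: DisplayList
    width: Size = field(default_factory=lambda: rel(1.0))
    height: Size = field(default_factory=lambda: rel(1.0))
    x_axis: AxisSpec = field(default_factory=_default_axis)
    y_axis: AxisSpec = field(default_factory=_default_axis)
    borders: Mapping[str, float] = field(default_factory=dict)  # side -> fraction
    free_space: frozenset[str] = frozenset()
    free_border: frozenset[str] = frozenset()
    name: str = "panel"
    is_spacer: bool = False

    def own_limits(self, axis: str) -> tuple[float, float]:
        spec = self.x_axis if axis == "x" else self.y_axis
        return spec.limits if spec.limits is not None else (0.0, 1.0)


def to_patch(
    plot=None,
    *,
    display: DisplayList | None = None,
    width: Size | float = 1.0,
    height: Size | float = 1.0,
    name: str = "panel",
    scheme: Scheme | None = None,
    **axes,
) -> Patch:
    """Convert a plot (anything with ``.to_patch()``), an opaque display list,
    or nothing (a spacer) into a Patch.

    Internal plots declare aligned axes with their data limits; a foreign
    display list is wrapped with all sides free (the composer can size it but
    not coordinate its axes); ``None`` yields a spacer that occupies space and
    draws nothing.
    """
    w = width if isinstance(width, Size) else rel(float(width))
    h = height if isinstance(height, Size) else rel(float(height))
    if plot is not None:
        if not hasattr(plot, "to_patch"):
            raise TypeError(f"cannot convert {type(plot).__name__} to a Patch")
        try:
            patch = plot.to_patch(scheme=scheme)
        except Exception as err:
            raise RuntimeError(f"rendering plot {name!r} failed: {err}") from err
        patch.width, patch.height, patch.name = w, h, name
        return patch
    if display is not None:
        free = AxisSpec(aligned=False)
        return Patch(display=display, width=w, height=h, name=name,
                     x_axis=free, y_axis=free, **axes)
    return spacer(width=w, height=h, name=name)


def spacer(width: Size | float = 1.0, height: Size | float = 1.0,
           name: str = "spacer") -> Patch:
    w = width if isinstance(width, Size) else rel(float(width))
    h = height if isinstance(height, Size) else rel(float(height))
    return Patch(display=DisplayList(), width=w, height=h,
                 x_axis=AxisSpec(aligned=False), y_axis=AxisSpec(aligned=False),
                 name=name, is_spacer=True)


@dataclass
class PanelInfo:
    rect: PanelRect
    xlim: tuple[float, float]
    ylim: tuple[float, float]
    name: str
    # for data-aware layouts: the observation domain shown on each axis
    x_domain: object = None
    y_domain: object = None


@dataclass
class ComposedFigure:
    """A fully laid-out figure: primitives in normalized [0,1]^2 figure
    coordinates (origin bottom-left), per-panel placement records, merged
    legends, and output size."""

    display: DisplayList
    panels: dict = field(default_factory=dict)
    legends: list[LegendKey] = field(default_factory=list)
    width_in: float = 6.0
    height_in: float = 6.0
    guide_policy: str = "collect"

    def panel(self, key) -> PanelInfo:
        return self.panels[key]


def _union(limits: Sequence[tuple[float, float]]) -> tuple[float, float]:
    los, his = zip(*limits)
    return (min(los), max(his))


def merge_guides(patches: Sequence[Patch]) -> list[LegendKey]:
    """Deduplicate legends across patches: keys equal on (title, labels,
    swatch kind) collapse to one; order of first appearance is kept."""
    seen: dict[tuple, LegendKey] = {}
    for p in patches:
        for key in p.display.legends:
            seen.setdefault(key.identity(), key)
    return list(seen.values())


def compose_grid(
    patches: Sequence[Sequence[Patch | None]],
    widths: Sequence[Size | float] | None = None,
    heights: Sequence[Size | float] | None = None,
    gap: float = 0.0,
    guide_policy: str = "collect",
    size_in: tuple[float, float] = (6.0, 6.0),
) -> ComposedFigure:
    """Arrange a rectangular grid of patches (row 0 at top; ``None`` entries
    become spacers) into a composed figure.

    Aligned panels within a column share x-limits (union of declared limits),
    within a row share y-limits; panels marked free on an axis keep their own.
    Panels plus gaps tile [0, 1] on each axis.
    """
    if guide_policy not in ("collect", "keep"):
        raise ValueError("guide_policy must be 'collect' or 'keep'")
    grid = [[p if p is not None else spacer() for p in row] for row in patches]
    n_rows = len(grid)
    n_cols = len(grid[0])
    if any(len(row) != n_cols for row in grid):
        raise ValueError("grid must be rectangular (use None for spacers)")

    if widths is None:
        widths = [max((c.width for c in col if not c.is_spacer),
                      key=lambda s: s.value, default=rel(1.0))
                  for col in zip(*grid)]
    if heights is None:
        heights = [max((p.height for p in row if not p.is_spacer),
                       key=lambda s: s.value, default=rel(1.0))
                   for row in grid]
    x_ivs = stack_geometry(widths, gap=gap)
    y_ivs_down = stack_geometry(heights, gap=gap)
    y_ivs = [(1.0 - b, 1.0 - a) for a, b in y_ivs_down]  # row 0 topmost

    # limit unification
    col_xlim: list[tuple[float, float] | None] = []
    for c in range(n_cols):
        decl = [grid[r][c].x_axis.limits for r in range(n_rows)
                if grid[r][c].x_axis.aligned and grid[r][c].x_axis.limits]
        col_xlim.append(_union(decl) if decl else None)
    row_ylim: list[tuple[float, float] | None] = []
    for r in range(n_rows):
        decl = [grid[r][c].y_axis.limits for c in range(n_cols)
                if grid[r][c].y_axis.aligned and grid[r][c].y_axis.limits]
        row_ylim.append(_union(decl) if decl else None)

    fig = DisplayList()
    panels: dict = {}
    for r in range(n_rows):
        for c in range(n_cols):
            p = grid[r][c]
            rect = PanelRect(x_ivs[c][0], y_ivs[r][0], x_ivs[c][1], y_ivs[r][1])
            xlim = col_xlim[c] if (p.x_axis.aligned and col_xlim[c]) else p.own_limits("x")
            ylim = row_ylim[r] if (p.y_axis.aligned and row_ylim[r]) else p.own_limits("y")
            xlim = _expanded(xlim, p.x_axis)
            ylim = _expanded(ylim, p.y_axis)
            panels[(r, c)] = PanelInfo(rect=rect, xlim=xlim, ylim=ylim, name=p.name)
            if not p.is_spacer:
                mapped = map_display_list(p.display, xlim, ylim,
                                          rect.x_extent, rect.y_extent)
                fig.primitives.extend(mapped.primitives)
                if guide_policy == "keep":
                    fig.legends.extend(p.display.legends)

    legends = merge_guides([p for row in grid for p in row]) if guide_policy == "collect" else []
    return ComposedFigure(display=fig, panels=panels, legends=legends,
                          width_in=size_in[0], height_in=size_in[1],
                          guide_policy=guide_policy)


def _expanded(lim: tuple[float, float], spec: AxisSpec) -> tuple[float, float]:
    if spec.discrete or spec.expand <= 0:
        return lim
    lo, hi = lim
    pad = (hi - lo) * spec.expand
    return (lo - pad, hi + pad)
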