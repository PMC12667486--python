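"""Layout geometry solvers: 1-D stacks, quadrant grids, concentric annuli,
angular sector placement and the polar transform for circular panels.

Conventions fixed across the engine: normalized figure coordinates in
[0, 1] with origin bottom-left and y increasing upward; intervals half-open
[lo, hi); circular layouts start at 12 o'clock and proceed clockwise, with
the first-added slot innermost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

from .domains import ObservationDomain

__all__ = [
    "Size",
    "rel",
    "absolute",
    "PanelRect",
    "AnnulusBand",
    "stack_geometry",
    "quad_geometry",
    "circle_geometry",
    "angular_position",
    "angular_map",
    "polar_shape",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class Size:
    """A slot size: relative (shares leftover space) or absolute (a fixed
    fraction of the figure/extent)."""

    value: float
    is_absolute: bool = False

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("sizes must be positive")


def rel(v: float) -> Size:
    return Size(v, is_absolute=False)


def absolute(v: float) -> Size:
    return Size(v, is_absolute=True)


def _as_size(s: "Size | float") -> Size:
    return s if isinstance(s, Size) else rel(float(s))


@dataclass(frozen=True)
class PanelRect:
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def x_extent(self) -> tuple[float, float]:
        return (self.x0, self.x1)

    @property
    def y_extent(self) -> tuple[float, float]:
        return (self.y0, self.y1)


@dataclass(frozen=True)
class AnnulusBand:
    r0: float
    r1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r0 < self.r1 <= 1.0 + 1e-12:
            raise ValueError(f"invalid annulus band [{self.r0}, {self.r1}]")


def stack_geometry(
    sizes: Sequence[Size | float],
    gap: float = 0.0,
    extent: tuple[float, float] = (0.0, 1.0),
) -> list[tuple[float, float]]:
    """Tile an interval with slots in order, separated by a fixed gap.

    Absolute sizes are fractions of the whole figure axis; relative sizes
    share the remaining space proportionally. Raises if absolute sizes plus
    gaps exceed the extent.
    """
    sizes = [_as_size(s) for s in sizes]
    lo, hi = extent
    span = hi - lo
    total_gap = gap * (len(sizes) - 1) if len(sizes) > 1 else 0.0
    abs_total = sum(s.value for s in sizes if s.is_absolute)
    rel_total = sum(s.value for s in sizes if not s.is_absolute)
    remainder = span - total_gap - abs_total
    if remainder < -1e-12 or (rel_total > 0 and remainder < 0):
        raise ValueError(
            f"absolute sizes ({abs_total}) plus gaps ({total_gap}) exceed extent span {span}"
        )
    unit = remainder / rel_total if rel_total > 0 else 0.0
    out: list[tuple[float, float]] = []
    cur = lo
    for i, s in enumerate(sizes):
        w = s.value if s.is_absolute else s.value * unit
        out.append((cur, cur + w))
        cur += w
        if i < len(sizes) - 1:
            cur += gap
    return out


def quad_geometry(
    central: tuple[Size | float, Size | float] = (1.0, 1.0),
    top: Sequence[Size | float] = (),
    bottom: Sequence[Size | float] = (),
    left: Sequence[Size | float] = (),
    right: Sequence[Size | float] = (),
    gap: float = 0.0,
) -> dict[str | tuple[str, int], PanelRect]:
    """Solve a quadrant layout: a central panel with annotation stacks on its
    four sides; two independent 1-D stack solves (x and y) whose central
    extents are shared by the facing stacks. Corner cells stay empty.

    Keys: ``"central"`` and ``(side, i)`` with i in addition order
    (outward-in for top/left so index 0 is adjacent to the central panel).
    """
    cw, ch = _as_size(central[0]), _as_size(central[1])
    # x solve: left slots (outermost first), central, right slots
    xs = stack_geometry([*left[::-1], cw, *right], gap=gap)
    nl = len(left)
    x_left = xs[:nl][::-1]  # index 0 adjacent to central
    x_central = xs[nl]
    x_right = xs[nl + 1 :]
    # y solve top-down: top slots (outermost first), central, bottom slots;
    # y axis increases upward so map stack order top->bottom onto [0,1] reversed
    ys_down = stack_geometry([*top[::-1], ch, *bottom], gap=gap)
    ys = [(1.0 - b, 1.0 - a) for a, b in ys_down]
    nt = len(top)
    y_top = ys[:nt][::-1]
    y_central = ys[nt]
    y_bottom = ys[nt + 1 :]

    out: dict[str | tuple[str, int], PanelRect] = {
        "central": PanelRect(x_central[0], y_central[0], x_central[1], y_central[1])
    }
    for i, (a, b) in enumerate(y_top):
        out[("top", i)] = PanelRect(x_central[0], a, x_central[1], b)
    for i, (a, b) in enumerate(y_bottom):
        out[("bottom", i)] = PanelRect(x_central[0], a, x_central[1], b)
    for i, (a, b) in enumerate(x_left):
        out[("left", i)] = PanelRect(a, y_central[0], b, y_central[1])
    for i, (a, b) in enumerate(x_right):
        out[("right", i)] = PanelRect(a, y_central[0], b, y_central[1])
    return out


def circle_geometry(
    sizes: Sequence[Size | float],
    r_inner: float = 0.0,
    r_outer: float = 1.0,
    gap: float = 0.0,
) -> list[AnnulusBand]:
    """Allocate radial thickness to slots proportionally, inner to outer in
    addition order, over the radial range [r_inner, r_outer] of the unit disc."""
    if not 0.0 <= r_inner < r_outer <= 1.0:
        raise ValueError(f"invalid radial range [{r_inner}, {r_outer}]")
    ivs = stack_geometry(sizes, gap=gap, extent=(r_inner, r_outer))
    return [AnnulusBand(a, b) for a, b in ivs]


def _n_gap_boundaries(domain: ObservationDomain) -> int:
    """Number of angular gap insertions: one per group boundary including the
    wrap-around boundary between last and first group (when >= 2 groups)."""
    if domain.groups is None:
        return 0
    n_groups = len({domain.groups[i] for i in domain.ids})
    return n_groups if n_groups >= 2 else 0


def angular_position(
    domain: ObservationDomain, id_: str, gap_angle: float = 0.0
) -> tuple[float, float]:
    """Angle interval (start, end) of an observation's sector, in radians.

    Sectors start at 12 o'clock (pi/2) and proceed clockwise, so start > end
    and angles decrease with display position. The usable angle is
    ``2*pi - n_boundaries * gap_angle`` split equally among observations,
    with a gap at every group boundary (wrap-around included).
    """
    nb = _n_gap_boundaries(domain)
    total_gaps = nb * gap_angle
    if total_gaps >= TWO_PI:
        raise ValueError(f"group gaps ({total_gaps:.4f} rad) must total less than 2*pi")
    n = len(domain)
    w = (TWO_PI - total_gaps) / n
    pos = domain.position(id_)
    gaps_before = sum(1 for b in domain.group_boundaries() if b <= pos)
    start = math.pi / 2 - pos * w - gaps_before * gap_angle
    return (start, start - w)


def angular_map(
    domain: ObservationDomain, gap_angle: float = 0.0
) -> Callable[[float], float]:
    """Map a panel x-fraction in [0, 1] to an angle, piecewise-linear within
    each observation's sector so cell edges land exactly on sector edges."""
    n = len(domain)
    disp = domain.display_ids
    sectors = [angular_position(domain, i, gap_angle) for i in disp]

    def theta(x: float) -> float:
        t = min(max(x, 0.0), 1.0) * n
        i = min(int(t), n - 1)
        frac = t - i
        s, e = sectors[i]
        return s + frac * (e - s)

    return theta


def polar_shape(
    rect: tuple[float, float, float, float],
    band: AnnulusBand,
    theta: Callable[[float], float],
    max_step: float = 0.05,
) -> list[tuple[float, float]] | None:
    """Transform a rectangle in (observation-fraction x radial-fraction) panel
    space into an annular-sector polygon on the unit disc of its circle panel.

    The disc is centered at (0.5, 0.5) with radius 0.5 in panel units. Arcs
    are sampled at ``max(8, ceil(dtheta / max_step))`` points per edge.
    Degenerate (zero-area) shapes are dropped with a warning.
    """
    x0, y0, x1, y1 = rect
    if abs(x1 - x0) <= 0.0 or abs(y1 - y0) <= 0.0:
        warnings.warn("degenerate zero-area shape dropped in polar transform",
                      stacklevel=2)
        return None
    t0, t1 = theta(x0), theta(x1)
    r_in = band.r0 + y0 * (band.r1 - band.r0)
    r_out = band.r0 + y1 * (band.r1 - band.r0)
    m = max(8, math.ceil(abs(t1 - t0) / max_step))

    def pt(r: float, t: float) -> tuple[float, float]:
        return (0.5 + 0.5 * r * math.cos(t), 0.5 + 0.5 * r * math.sin(t))

    outer = [pt(r_out, t0 + (t1 - t0) * k / m) for k in range(m + 1)]
    inner = [pt(r_in, t1 + (t0 - t1) * k / m) for k in range(m + 1)]
    return outer + inner


def polar_point(
    x: float, y: float, band: AnnulusBand, theta: Callable[[float], float]
) -> tuple[float, float]:
    """Map a single panel-space point into disc coordinates."""
    t = theta(x)
    r = band.r0 + y * (band.r1 - band.r0)
    return (0.5 + 0.5 * r * math.cos(t), 0.5 + 0.5 * r * math.sin(t))
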