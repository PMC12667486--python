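"""Backend-neutral drawing primitives and the DisplayList container.

A rendered panel is an ordered list of primitives (rectangles, segments,
polylines, polygons, text, points) in the panel's own coordinate space, plus
the legend keys its visual encodings produced. Z-order is list order.
Primitives carry only style attributes a vector backend needs; no backend
objects leak in, which is what keeps SVG output deterministic and diffable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

__all__ = [
    "Rect",
    "Segment",
    "Polyline",
    "Polygon",
    "Text",
    "Marker",
    "LegendKey",
    "DisplayList",
    "affine_map",
]

Coord = tuple[float, float]


def _check_finite(*vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise ValueError(f"non-finite coordinate {v!r} in display primitive")


@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float
    fill: str | None = "#000000"
    stroke: str | None = None
    stroke_width: float = 0.0
    opacity: float = 1.0

    def __post_init__(self) -> None:
        _check_finite(self.x0, self.y0, self.x1, self.y1)


@dataclass(frozen=True)
class Segment:
    x0: float
    y0: float
    x1: float
    y1: float
    stroke: str = "#000000"
    width: float = 1.0
    opacity: float = 1.0

    def __post_init__(self) -> None:
        _check_finite(self.x0, self.y0, self.x1, self.y1)


@dataclass(frozen=True)
class Polyline:
    points: tuple[Coord, ...]
    stroke: str = "#000000"
    width: float = 1.0
    opacity: float = 1.0

    def __post_init__(self) -> None:
        for x, y in self.points:
            _check_finite(x, y)


@dataclass(frozen=True)
class Polygon:
    points: tuple[Coord, ...]
    fill: str | None = "#000000"
    stroke: str | None = None
    stroke_width: float = 0.0
    opacity: float = 1.0

    def __post_init__(self) -> None:
        for x, y in self.points:
            _check_finite(x, y)


@dataclass(frozen=True)
class Text:
    x: float
    y: float
    text: str
    size: float = 8.0  # points
    anchor: str = "middle"  # start | middle | end
    color: str = "#000000"
    rotate: float = 0.0  # degrees, counter-clockwise

    def __post_init__(self) -> None:
        _check_finite(self.x, self.y)


@dataclass(frozen=True)
class Marker:
    """A point marker; radius is in output pixels, not data units."""

    x: float
    y: float
    radius: float = 2.0
    fill: str = "#000000"
    stroke: str | None = None
    opacity: float = 1.0

    def __post_init__(self) -> None:
        _check_finite(self.x, self.y)


Primitive = Rect | Segment | Polyline | Polygon | Text | Marker


@dataclass(frozen=True)
class LegendKey:
    """A deduplicatable legend: title, ordered labels, swatch colors and kind."""

    title: str
    labels: tuple[str, ...]
    colors: tuple[str, ...]
    kind: str = "fill"  # fill | line | point

    def identity(self) -> tuple:
        return (self.title, self.labels, self.kind)


@dataclass
class DisplayList:
    """Ordered primitives plus legend keys; z-order = list order."""

    primitives: list[Primitive] = field(default_factory=list)
    legends: list[LegendKey] = field(default_factory=list)

    def add(self, *prims: Primitive) -> "DisplayList":
        self.primitives.extend(prims)
        return self

    def add_legend(self, key: LegendKey) -> "DisplayList":
        self.legends.append(key)
        return self

    def extend(self, other: "DisplayList") -> "DisplayList":
        self.primitives.extend(other.primitives)
        self.legends.extend(other.legends)
        return self

    def transform(self, fx: Callable[[float], float], fy: Callable[[float], float]) -> "DisplayList":
        """Apply coordinate maps x -> fx(x), y -> fy(y) to every primitive."""
        out: list[Primitive] = []
        for p in self.primitives:
            if isinstance(p, Rect):
                x0, x1 = sorted((fx(p.x0), fx(p.x1)))
                y0, y1 = sorted((fy(p.y0), fy(p.y1)))
                out.append(replace(p, x0=x0, y0=y0, x1=x1, y1=y1))
            elif isinstance(p, Segment):
                out.append(
                    replace(p, x0=fx(p.x0), y0=fy(p.y0), x1=fx(p.x1), y1=fy(p.y1))
                )
            elif isinstance(p, (Polyline, Polygon)):
                out.append(
                    replace(p, points=tuple((fx(x), fy(y)) for x, y in p.points))
                )
            elif isinstance(p, (Text, Marker)):
                out.append(replace(p, x=fx(p.x), y=fy(p.y)))
            else:  # pragma: no cover
                raise TypeError(f"unknown primitive {p!r}")
        return DisplayList(primitives=out, legends=list(self.legends))


def affine_map(
    src: tuple[float, float], dst: tuple[float, float]
) -> Callable[[float], float]:
    """1-D affine map sending interval ``src`` onto interval ``dst``."""
    (s0, s1), (d0, d1) = src, dst
    if s1 == s0:
        raise ValueError("degenerate source interval")
    scale = (d1 - d0) / (s1 - s0)
    return lambda v: d0 + (v - s0) * scale


def map_display_list(
    dl: DisplayList,
    src_x: tuple[float, float],
    src_y: tuple[float, float],
    dst_x: tuple[float, float],
    dst_y: tuple[float, float],
) -> DisplayList:
    """Map a display list from source limits onto a destination rectangle."""
    return dl.transform(affine_map(src_x, dst_x), affine_map(src_y, dst_y))
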