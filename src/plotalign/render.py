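"""Figure output: deterministic SVG (primary, textual, diffable) and PNG.

The SVG emitter writes primitives in z-order with fixed-precision
coordinates and no timestamps or environment metadata, so identical figures
serialize to byte-identical files. Figure coordinates ([0, 1]^2, origin
bottom-left) map onto the pixel canvas with y flipped; collected legends are
drawn in a reserved strip on the figure's guide side.
"""

from __future__ import annotations

from pathlib import Path

from .composition import ComposedFigure
from .primitives import (
    DisplayList,
    LegendKey,
    Marker,
    Polygon,
    Polyline,
    Rect,
    Segment,
    Text,
)

__all__ = ["to_svg", "write_svg", "write_png"]

_LEGEND_STRIP = 0.22  # fraction of canvas width reserved when legends exist


def _f(v: float) -> str:
    """Fixed-precision, locale-free float formatting (determinism)."""
    s = f"{v:.4f}"
    return "0.0000" if s in ("-0.0000",) else s


class _Canvas:
    """Maps normalized figure coordinates to pixels; when a legend strip is
    reserved the content box shrinks uniformly (aspect preserved)."""

    def __init__(self, w_px: float, h_px: float, scale: float = 1.0):
        self.w, self.h = w_px, h_px
        self.scale = scale

    def pt(self, x: float, y: float) -> tuple[float, float]:
        pad = 0.5 * (1.0 - self.scale) * self.h
        return (x * self.w * self.scale,
                pad + (1.0 - y) * self.h * self.scale)


def _emit(dl: DisplayList, cv: _Canvas) -> list[str]:
    out: list[str] = []
    for p in dl.primitives:
        if isinstance(p, Rect):
            (x0, y1), (x1, y0) = cv.pt(p.x0, p.y0), cv.pt(p.x1, p.y1)
            attrs = [f'x="{_f(min(x0, x1))}"', f'y="{_f(min(y0, y1))}"',
                     f'width="{_f(abs(x1 - x0))}"', f'height="{_f(abs(y1 - y0))}"']
            attrs.append(f'fill="{p.fill}"' if p.fill else 'fill="none"')
            if p.stroke:
                attrs.append(f'stroke="{p.stroke}" stroke-width="{_f(p.stroke_width)}"')
            if p.opacity < 1.0:
                attrs.append(f'opacity="{_f(p.opacity)}"')
            out.append(f"<rect {' '.join(attrs)}/>")
        elif isinstance(p, Segment):
            (x0, y0), (x1, y1) = cv.pt(p.x0, p.y0), cv.pt(p.x1, p.y1)
            o = f' opacity="{_f(p.opacity)}"' if p.opacity < 1.0 else ""
            out.append(
                f'<line x1="{_f(x0)}" y1="{_f(y0)}" x2="{_f(x1)}" y2="{_f(y1)}" '
                f'stroke="{p.stroke}" stroke-width="{_f(p.width)}"{o}/>'
            )
        elif isinstance(p, Polyline):
            pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in
                           (cv.pt(*q) for q in p.points))
            o = f' opacity="{_f(p.opacity)}"' if p.opacity < 1.0 else ""
            out.append(
                f'<polyline points="{pts}" fill="none" stroke="{p.stroke}" '
                f'stroke-width="{_f(p.width)}"{o}/>'
            )
        elif isinstance(p, Polygon):
            pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in
                           (cv.pt(*q) for q in p.points))
            fill = p.fill if p.fill else "none"
            stroke = (f' stroke="{p.stroke}" stroke-width="{_f(p.stroke_width)}"'
                      if p.stroke else "")
            o = f' opacity="{_f(p.opacity)}"' if p.opacity < 1.0 else ""
            out.append(f'<polygon points="{pts}" fill="{fill}"{stroke}{o}/>')
        elif isinstance(p, Text):
            x, y = cv.pt(p.x, p.y)
            rot = (f' transform="rotate({_f(-p.rotate)} {_f(x)} {_f(y)})"'
                   if p.rotate else "")
            out.append(
                f'<text x="{_f(x)}" y="{_f(y)}" font-size="{_f(p.size)}" '
                f'text-anchor="{p.anchor}" fill="{p.color}" '
                f'dominant-baseline="middle" '
                f'font-family="sans-serif"{rot}>{_escape(p.text)}</text>'
            )
        elif isinstance(p, Marker):
            x, y = cv.pt(p.x, p.y)
            stroke = f' stroke="{p.stroke}"' if p.stroke else ""
            o = f' opacity="{_f(p.opacity)}"' if p.opacity < 1.0 else ""
            out.append(
                f'<circle cx="{_f(x)}" cy="{_f(y)}" r="{_f(p.radius)}" '
                f'fill="{p.fill}"{stroke}{o}/>'
            )
    return out


def _escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _legend_lines(legends: list[LegendKey], w_px: float, h_px: float) -> list[str]:
    out: list[str] = []
    x = w_px * (1.0 - _LEGEND_STRIP) + 10
    y = 20.0
    sw = 10.0
    for key in legends:
        out.append(
            f'<text x="{_f(x)}" y="{_f(y)}" font-size="9.0" text-anchor="start" '
            f'fill="#000000" font-family="sans-serif" '
            f'font-weight="bold">{_escape(key.title)}</text>'
        )
        y += 14.0
        for lab, col in zip(key.labels, key.colors):
            if key.kind == "line":
                out.append(
                    f'<line x1="{_f(x)}" y1="{_f(y - 4)}" x2="{_f(x + sw)}" '
                    f'y2="{_f(y - 4)}" stroke="{col}" stroke-width="1.5"/>'
                )
            elif key.kind == "point":
                out.append(
                    f'<circle cx="{_f(x + sw / 2)}" cy="{_f(y - 4)}" r="3.0" '
                    f'fill="{col}"/>'
                )
            else:
                out.append(
                    f'<rect x="{_f(x)}" y="{_f(y - 9)}" width="{_f(sw)}" '
                    f'height="{_f(sw)}" fill="{col}"/>'
                )
            out.append(
                f'<text x="{_f(x + sw + 4)}" y="{_f(y - 2)}" font-size="8.0" '
                f'text-anchor="start" fill="#000000" '
                f'font-family="sans-serif">{_escape(lab)}</text>'
            )
            y += 13.0
        y += 8.0
    return out


def to_svg(fig: ComposedFigure, dpi: float = 96.0) -> str:
    """Serialize a composed figure as an SVG document string."""
    w_px, h_px = fig.width_in * dpi, fig.height_in * dpi
    has_legends = bool(fig.legends)
    cv = _Canvas(w_px, h_px, scale=(1.0 - _LEGEND_STRIP) if has_legends else 1.0)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(w_px)}" '
        f'height="{_f(h_px)}" viewBox="0 0 {_f(w_px)} {_f(h_px)}">',
        f'<rect x="0" y="0" width="{_f(w_px)}" height="{_f(h_px)}" fill="#ffffff"/>',
    ]
    lines.extend(_emit(fig.display, cv))
    if has_legends:
        lines.extend(_legend_lines(fig.legends, w_px, h_px))
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def write_svg(fig: ComposedFigure, path: str | Path, dpi: float = 96.0) -> None:
    Path(path).write_text(to_svg(fig, dpi=dpi))


def write_png(fig: ComposedFigure, path: str | Path, dpi: float = 96.0) -> None:
    """Rasterize via Pillow. Text is drawn with the default bitmap font; PNG
    output is for quick inspection, SVG is the primary format."""
    from PIL import Image, ImageDraw

    w_px, h_px = int(fig.width_in * dpi), int(fig.height_in * dpi)
    has_legends = bool(fig.legends)
    cv = _Canvas(w_px, h_px, scale=(1.0 - _LEGEND_STRIP) if has_legends else 1.0)
    img = Image.new("RGB", (w_px, h_px), "#ffffff")
    draw = ImageDraw.Draw(img, "RGBA")

    def col(c: str | None, opacity: float = 1.0):
        if c is None:
            return None
        r, g, b = int(c[1:3], 16), int(c[3:5], 16), int(c[5:7], 16)
        return (r, g, b, int(round(255 * opacity)))

    for p in fig.display.primitives:
        if isinstance(p, Rect):
            (x0, y1), (x1, y0) = cv.pt(p.x0, p.y0), cv.pt(p.x1, p.y1)
            draw.rectangle([min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1)],
                           fill=col(p.fill, p.opacity),
                           outline=col(p.stroke),
                           width=max(1, int(p.stroke_width)) if p.stroke else 0)
        elif isinstance(p, Segment):
            draw.line([cv.pt(p.x0, p.y0), cv.pt(p.x1, p.y1)],
                      fill=col(p.stroke, p.opacity), width=max(1, int(p.width)))
        elif isinstance(p, Polyline):
            draw.line([cv.pt(*q) for q in p.points],
                      fill=col(p.stroke, p.opacity), width=max(1, int(p.width)))
        elif isinstance(p, Polygon):
            draw.polygon([cv.pt(*q) for q in p.points],
                         fill=col(p.fill, p.opacity), outline=col(p.stroke))
        elif isinstance(p, Text):
            draw.text(cv.pt(p.x, p.y), p.text, fill=col(p.color), anchor="mm")
        elif isinstance(p, Marker):
            x, y = cv.pt(p.x, p.y)
            r = p.radius
            draw.ellipse([x - r, y - r, x + r, y + r],
                         fill=col(p.fill, p.opacity))
    img.save(path, format="PNG")
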