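"""Schemes: inheritable bundles of theming, data-transform and alignment options.

A scheme set at the layout level is inherited by every plot in the layout;
a plot-level scheme overrides the inherited fields it sets. Merging is
field-wise (child set -> child wins, child unset -> parent), except data
transforms, which compose: the parent transform is applied to the plot's
input first, then the child's.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Any, Callable

__all__ = ["Scheme", "scheme_merge", "scheme_theme", "scheme_data", "scheme_align"]

_UNSET = None


@dataclass(frozen=True)
class Scheme:
    """Visual/structural controls applied from layouts down to plots.

    Unset fields (``None``) inherit from the parent scheme.
    """

    # theming
    font_size: float | None = None
    background: str | None = None
    grid: bool | None = None
    # data transform applied to a plot's input before geometry construction
    data_transform: Callable[[Any], Any] | None = None
    # alignment options
    guide_side: str | None = None  # right | left | top | bottom
    free_axes: frozenset[str] = frozenset()  # axes exempt from limit unification

    def apply_transform(self, data: Any) -> Any:
        return data if self.data_transform is None else self.data_transform(data)

    def resolved_font_size(self) -> float:
        return 8.0 if self.font_size is None else self.font_size

    def resolved_guide_side(self) -> str:
        return "right" if self.guide_side is None else self.guide_side


def scheme_merge(parent: Scheme, child: Scheme) -> Scheme:
    """Field-wise inheritance; transforms compose parent-first."""
    out: dict[str, Any] = {}
    for f in fields(Scheme):
        pv, cv = getattr(parent, f.name), getattr(child, f.name)
        if f.name == "data_transform":
            if pv is None:
                out[f.name] = cv
            elif cv is None:
                out[f.name] = pv
            else:
                out[f.name] = _compose(pv, cv)
        elif f.name == "free_axes":
            out[f.name] = frozenset(pv) | frozenset(cv)
        else:
            out[f.name] = pv if cv is _UNSET else cv
    return Scheme(**out)


def _compose(first: Callable, then: Callable) -> Callable:
    return lambda x: then(first(x))


# convenience constructors mirroring the three built-in scheme kinds
def scheme_theme(font_size: float | None = None, background: str | None = None,
                 grid: bool | None = None) -> Scheme:
    return Scheme(font_size=font_size, background=background, grid=grid)


def scheme_data(transform: Callable[[Any], Any]) -> Scheme:
    return Scheme(data_transform=transform)


def scheme_align(guide_side: str | None = None, free_axes: tuple[str, ...] = ()) -> Scheme:
    return Scheme(guide_side=guide_side, free_axes=frozenset(free_axes))
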