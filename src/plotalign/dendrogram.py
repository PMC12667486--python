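"""Dendrogram geometry in leaf-index x height space, and Newick export.

Coordinates are canonical: the leaf at display position ``i`` sits at
``x = i + 0.5`` (the center of its unit-width column), ``y = 0``; an internal
node sits at the midpoint of its children's x with ``y`` equal to the merge
height. Each merge contributes one U-shaped connector: two risers and a
crossbar, stored as a 4-point polyline. Orientation (drawing the tree above,
below, left or right of a panel) is an axis swap/flip applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import HClustResult, MergeTable
from .domains import DomainError, ObservationDomain

__all__ = ["DendrogramGeometry", "dendrogram_geometry", "newick_serialize"]


@dataclass(frozen=True)
class DendrogramGeometry:
    """Node coordinates and U-shaped connector polylines for a tree or forest.

    ``nodes`` maps node index (per-tree convention; see MergeTable) offset by
    the tree's leaf span to ``(x, y)``. ``segments`` is a list of 4-point
    polylines ``((x_l, y_l), (x_l, h), (x_r, h), (x_r, y_r))``.
    """

    nodes: tuple[tuple[float, float], ...]
    segments: tuple[tuple[tuple[float, float], ...], ...]
    n_leaves: int
    max_height: float


def _tree_geometry(
    table: MergeTable, x_offset: float
) -> tuple[list[tuple[float, float]], list[tuple[tuple[float, float], ...]]]:
    n = table.n_leaves
    pos_of_leaf = {leaf: p for p, leaf in enumerate(table.leaf_order)}
    coords: dict[int, tuple[float, float]] = {
        leaf: (x_offset + pos_of_leaf[leaf] + 0.5, 0.0) for leaf in range(n)
    }
    segments: list[tuple[tuple[float, float], ...]] = []
    for i, (a, b, h) in enumerate(table.merges):
        xa, ya = coords[a]
        xb, yb = coords[b]
        coords[n + i] = (0.5 * (xa + xb), h)
        segments.append(((xa, ya), (xa, h), (xb, h), (xb, yb)))
    return [coords[k] for k in sorted(coords)], segments


def dendrogram_geometry(
    result: HClustResult | MergeTable, domain: ObservationDomain
) -> DendrogramGeometry:
    """Compute node/segment coordinates for a clustering result over a domain.

    The domain's display order must match the dendrogram leaf order exactly:
    the drawn tree may never contradict the order it propagated.
    """
    if isinstance(result, MergeTable):
        result = HClustResult(trees=((None, result),), order=result.ordered_labels())
    if tuple(result.order) != domain.display_ids:
        raise DomainError(
            "dendrogram leaf order does not match the domain display order: "
            f"{result.order} vs {domain.display_ids}"
        )
    nodes: list[tuple[float, float]] = []
    segments: list[tuple[tuple[float, float], ...]] = []
    offset = 0.0
    max_h = 0.0
    for _, table in result.trees:
        tn, ts = _tree_geometry(table, offset)
        nodes.extend(tn)
        segments.extend(ts)
        offset += table.n_leaves
        if table.merges:
            max_h = max(max_h, max(table.heights))
    return DendrogramGeometry(
        nodes=tuple(nodes),
        segments=tuple(segments),
        n_leaves=len(domain),
        max_height=max_h,
    )


def newick_serialize(table: MergeTable) -> str:
    """Serialize a merge table as a Newick tree with branch lengths.

    Branch length of a node = parent merge height - its own height (leaves
    have height 0). A single leaf degenerates to ``label:0;``.
    """
    n = table.n_leaves
    if n == 1:
        return f"{table.leaf_labels[0]}:0;"

    height = {i: 0.0 for i in range(n)}
    for i, (_, _, h) in enumerate(table.merges):
        height[n + i] = h

    def node_str(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{table.leaf_labels[node]}:{_fmt(bl)}"
        a, b, h = table.merges[node - n]
        return f"({node_str(a, h)},{node_str(b, h)}):{_fmt(bl)}"

    a, b, h = table.merges[-1]
    return f"({node_str(a, h)},{node_str(b, h)});"


def _fmt(x: float) -> str:
    s = f"{x:.10g}"
    return s
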