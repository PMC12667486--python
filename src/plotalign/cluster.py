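"""Data-driven reordering operators: agglomerative clustering, k-means grouping,
weight-based custom ordering, and tree cutting.

The agglomerative path is authored here (Lance-Williams recurrence with a
deterministic tie-break) because the dendrogram geometry, the leaf order
propagated to every aligned panel, and the Newick export all depend on the
exact merge sequence; library implementations do not pin the tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .domains import DomainError, ObservationDomain

__all__ = [
    "MergeTable",
    "HClustResult",
    "agglomerative_order",
    "kmeans_groups",
    "custom_order",
    "cut_clusters",
    "LINKAGES",
]

LINKAGES = ("single", "complete", "average", "ward.d2")
METRICS = ("euclidean",)


@dataclass(frozen=True)
class MergeTable:
    """Agglomeration result for one tree.

    Node indexing follows the common convention: leaves are ``0..n-1``;
    the node created by merge ``i`` (0-based) is ``n + i``. ``merges`` has
    ``n - 1`` rows ``(left, right, height)`` where *left* is the child
    containing the lowest original leaf index. ``leaf_order`` is the
    left-to-right leaf sequence of the dendrogram.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaf_labels: tuple[str, ...]
    leaf_order: tuple[int, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(h for _, _, h in self.merges)

    def ordered_labels(self) -> tuple[str, ...]:
        return tuple(self.leaf_labels[i] for i in self.leaf_order)


@dataclass(frozen=True)
class HClustResult:
    """One MergeTable per group (a forest), concatenated in group order.

    For ungrouped clustering there is a single entry under key ``None``.
    """

    trees: tuple[tuple[str | None, MergeTable], ...]
    order: tuple[str, ...]

    @property
    def tree(self) -> MergeTable:
        if len(self.trees) != 1:
            raise ValueError("result holds a forest; access .trees per group")
        return self.trees[0][1]


def _lance_williams_update(
    linkage: str, d_ki: float, d_kj: float, d_ij: float, ni: int, nj: int, nk: int
) -> float:
    if linkage == "single":
        return 0.5 * d_ki + 0.5 * d_kj - 0.5 * abs(d_ki - d_kj)
    if linkage == "complete":
        return 0.5 * d_ki + 0.5 * d_kj + 0.5 * abs(d_ki - d_kj)
    if linkage == "average":
        return (ni * d_ki + nj * d_kj) / (ni + nj)
    if linkage == "ward.d2":
        # recurrence on squared distances
        t = ni + nj + nk
        return ((ni + nk) * d_ki + (nj + nk) * d_kj - nk * d_ij) / t
    raise ValueError(f"unsupported linkage {linkage!r}; choose from {LINKAGES}")


def _agglomerate(dism: np.ndarray, labels: Sequence[str], linkage: str) -> MergeTable:
    """Lance-Williams agglomeration on a full dissimilarity matrix.

    Tie-break: among minimal-distance active pairs, merge the pair with the
    lowest first node index, then lowest second. For ward.d2 the working
    distances are squared; reported heights are their square roots.
    """
    n = dism.shape[0]
    labels = tuple(str(x) for x in labels)
    if n == 1:
        return MergeTable(merges=(), leaf_labels=labels, leaf_order=(0,))

    squared = linkage == "ward.d2"
    work = dism.astype(float) ** 2 if squared else dism.astype(float).copy()

    # active clusters: node id -> matrix slot, size, ordered leaf list
    size = {i: 1 for i in range(n)}
    leaves = {i: [i] for i in range(n)}
    active = list(range(n))  # node ids, kept sorted

    merges: list[tuple[int, int, float]] = []
    slot_of_node = {i: i for i in range(n)}

    for step in range(n - 1):
        best: float | None = None
        best_pair: tuple[int, int] | None = None
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                u, v = active[a_idx], active[b_idx]
                d = work[slot_of_node[u], slot_of_node[v]]
                if best is None or d < best or (d == best and (u, v) < best_pair):
                    best = d
                    best_pair = (u, v)
        u, v = best_pair  # type: ignore[misc]
        d_uv = work[slot_of_node[u], slot_of_node[v]]
        height = float(np.sqrt(d_uv)) if squared else float(d_uv)
        new_node = n + step

        # left child = child containing the lowest original leaf index
        if min(leaves[u]) <= min(leaves[v]):
            left, right = u, v
        else:
            left, right = v, u
        merges.append((left, right, height))

        # update distances into u's slot; retire v's slot
        su, sv = slot_of_node[u], slot_of_node[v]
        for k in active:
            if k in (u, v):
                continue
            sk = slot_of_node[k]
            work[su, sk] = work[sk, su] = _lance_williams_update(
                linkage, work[sk, su], work[sk, sv], d_uv, size[u], size[v], size[k]
            )
        slot_of_node[new_node] = su
        size[new_node] = size[u] + size[v]
        leaves[new_node] = leaves[left] + leaves[right]
        active = [x for x in active if x not in (u, v)] + [new_node]
        active.sort()

    root = n + (n - 2)
    return MergeTable(
        merges=tuple(merges), leaf_labels=labels, leaf_order=tuple(leaves[root])
    )


def _as_dissimilarity(
    data: np.ndarray | None, dissimilarity: np.ndarray | None, metric: str
) -> np.ndarray:
    if metric not in METRICS:
        raise ValueError(f"unsupported metric {metric!r}; choose from {METRICS}")
    if dissimilarity is not None:
        d = np.asarray(dissimilarity, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity must be a square matrix")
    else:
        if data is None:
            raise ValueError("provide data or a precomputed dissimilarity")
        x = np.atleast_2d(np.asarray(data, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in clustering input")
        d = squareform(pdist(x, metric=metric)) if x.shape[0] > 1 else np.zeros((1, 1))
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite values in dissimilarity matrix")
    return d


def agglomerative_order(
    data: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
    *,
    dissimilarity: np.ndarray | None = None,
    metric: str = "euclidean",
    linkage: str = "complete",
    groups: Mapping[str, str] | None = None,
    group_order: Sequence[str] | None = None,
) -> HClustResult:
    """Cluster observations (matrix rows) and return merge tables plus the
    dendrogram leaf order.

    With ``groups``, each group is clustered independently and the per-group
    subtrees are concatenated in ``group_order`` (default: first appearance in
    ``ids``); no merge ever crosses a group boundary.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unsupported linkage {linkage!r}; choose from {LINKAGES}")
    d = _as_dissimilarity(data, dissimilarity, metric)
    n = d.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValueError(f"{len(ids)} ids for {n} observations")

    if groups is None:
        mt = _agglomerate(d, ids, linkage)
        return HClustResult(trees=((None, mt),), order=mt.ordered_labels())

    missing = [i for i in ids if i not in groups]
    if missing:
        raise ValueError(f"group mapping missing ids: {missing}")
    if group_order is None:
        group_order = []
        for i in ids:
            if groups[i] not in group_order:
                group_order.append(groups[i])
    trees: list[tuple[str | None, MergeTable]] = []
    order: list[str] = []
    idx = {i: k for k, i in enumerate(ids)}
    for g in group_order:
        members = [i for i in ids if groups[i] == g]
        sel = [idx[i] for i in members]
        sub = d[np.ix_(sel, sel)]
        mt = _agglomerate(sub, members, linkage)
        trees.append((g, mt))
        order.extend(mt.ordered_labels())
    return HClustResult(trees=tuple(trees), order=tuple(order))


def cut_clusters(table: MergeTable, k: int) -> dict[str, int]:
    """Cut the tree into ``k`` clusters (undo the last ``k - 1`` merges).

    Returns id -> cluster label (0-based, ordered by lowest member leaf index).
    """
    n = table.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    parent = list(range(n + len(table.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _) in enumerate(table.merges[: n - k]):
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, int] = {}
    out: dict[str, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        out[table.leaf_labels[leaf]] = roots[r]
    return out


def kmeans_groups(
    data: np.ndarray,
    ids: Sequence[str],
    k: int,
    seed: int,
    n_init: int = 10,
) -> dict[str, str]:
    """Partition observations into ``k`` groups by k-means (Lloyd iterations,
    seeded random initialization from the data rows, best of ``n_init``
    restarts by within-cluster sum of squares).

    Group labels ``k1..kK`` are assigned by first appearance in input order so
    the result is deterministic and ready for grouping an aligned axis.
    """
    from sklearn.cluster import KMeans

    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[0] == 1 and len(ids) > 1:
        x = x.T
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in k-means input")
    n = x.shape[0]
    if len(ids) != n:
        raise ValueError(f"{len(ids)} ids for {n} observations")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n={n}")
    if k == 1:
        return {str(i): "k1" for i in ids}
    km = KMeans(
        n_clusters=k, init="random", n_init=n_init, random_state=seed, algorithm="lloyd"
    )
    raw = km.fit_predict(x)
    relabel: dict[int, str] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = f"k{len(relabel) + 1}"
    return {str(i): relabel[lab] for i, lab in zip(ids, raw)}


def custom_order(
    domain: ObservationDomain,
    weights: Mapping[str, float] | Sequence[str],
    decreasing: bool = False,
) -> tuple[str, ...]:
    """New display order from per-id weights (stable: ties keep the previous
    display order) or an explicit permutation; group contiguity is respected
    by sorting within each group block.
    """
    disp = domain.display_ids
    if not isinstance(weights, Mapping):
        seq = [str(i) for i in weights]
        if sorted(seq) != sorted(domain.ids):
            raise DomainError("explicit sequence is not a permutation of domain ids")
        if domain.groups is not None:
            # keep group blocks; order members within each block per sequence
            rank = {i: p for p, i in enumerate(seq)}
            out: list[str] = []
            for block in _group_blocks(domain):
                out.extend(sorted(block, key=lambda i: rank[i]))
            return tuple(out)
        return tuple(seq)

    missing = [i for i in domain.ids if i not in weights]
    if missing:
        raise DomainError(f"weights missing ids: {missing}")
    sign = -1.0 if decreasing else 1.0

    def sort_block(block: list[str]) -> list[str]:
        prev = {i: p for p, i in enumerate(disp)}
        return sorted(block, key=lambda i: (sign * float(weights[i]), prev[i]))

    if domain.groups is None:
        return tuple(sort_block(list(disp)))
    out = []
    for block in _group_blocks(domain):
        out.extend(sort_block(block))
    return tuple(out)


def _group_blocks(domain: ObservationDomain) -> list[list[str]]:
    disp = list(domain.display_ids)
    bounds = [0, *domain.group_boundaries(), len(disp)]
    return [disp[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
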