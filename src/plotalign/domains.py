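"""Observation domains: shared identity, order and grouping of entities on a layout axis.

A domain is the set of observations (genes, samples, taxa, ...) placed on one
discrete axis of a layout. Every panel aligned on that axis must show the same
observations in the same display order with the same grouping; the domain is
the single source of truth that makes that guarantee enforceable. Orders and
groupings can be *locked*, in which case a later conflicting request raises
:class:`DomainConflictError` instead of silently producing a misaligned figure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationDomain",
    "DomainError",
    "DomainConflictError",
    "create_domain",
    "set_order",
    "set_groups",
    "unify_domains",
    "observation_interval",
    "observation_intervals",
]


class DomainError(ValueError):
    """Invalid domain construction or manipulation."""


class DomainConflictError(DomainError):
    """Two locked, differing impositions of order/grouping on the same domain."""


@dataclass(frozen=True)
class ObservationDomain:
    """Identity, display order, grouping and lock state of one axis's observations.

    Attributes
    ----------
    ids:
        Unique observation identifiers, in their original (input) order.
    order:
        Permutation of ``0..n-1``; ``order[pos]`` is the index into ``ids`` of
        the observation shown at display position ``pos``.
    groups:
        Optional mapping id -> group label. When set, observations of a group
        occupy contiguous display positions and group blocks appear in
        ``group_order``.
    """

    ids: tuple[str, ...]
    order: tuple[int, ...]
    groups: Mapping[str, str] | None = None
    group_order: tuple[str, ...] = ()
    order_locked: bool = False
    groups_locked: bool = False
    name: str = "domain"
    # provenance of a locked order/grouping, used in conflict messages
    lock_source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if n == 0:
            raise DomainError("empty domain: at least one observation id is required")
        seen: set[str] = set()
        for i in self.ids:
            if i in seen:
                raise DomainError(f"duplicate id {i!r} in domain {self.name!r}")
            seen.add(i)
        if sorted(self.order) != list(range(n)):
            raise DomainError(
                f"order must be a permutation of 0..{n - 1}, got {self.order!r}"
            )
        if self.groups is not None:
            missing = [i for i in self.ids if i not in self.groups]
            unknown = [i for i in self.groups if i not in seen]
            if missing or unknown:
                raise DomainError(
                    f"group mapping must cover ids exactly once; missing={missing}, unknown={unknown}"
                )
            self._check_contiguity(self.order, self.groups, self.group_order)

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def display_ids(self) -> tuple[str, ...]:
        """Ids in current display order."""
        return tuple(self.ids[j] for j in self.order)

    def position(self, id_: str) -> int:
        """Display position (0-based) of an observation."""
        try:
            idx = self.ids.index(id_)
        except ValueError:
            raise DomainError(f"unknown id {id_!r} in domain {self.name!r}") from None
        return self.order.index(idx)

    def group_of(self, id_: str) -> str | None:
        if self.groups is None:
            return None
        return self.groups[id_]

    def group_boundaries(self) -> tuple[int, ...]:
        """Display positions p>0 where the group changes between p-1 and p."""
        if self.groups is None:
            return ()
        disp = self.display_ids
        return tuple(
            p
            for p in range(1, len(disp))
            if self.groups[disp[p]] != self.groups[disp[p - 1]]
        )

    # -- helpers ---------------------------------------------------------

    def _check_contiguity(
        self,
        order: Sequence[int],
        groups: Mapping[str, str],
        group_order: Sequence[str],
    ) -> None:
        disp = [self.ids[j] for j in order]
        labels = [groups[i] for i in disp]
        seen_blocks: list[str] = []
        for lab in labels:
            if not seen_blocks or seen_blocks[-1] != lab:
                if lab in seen_blocks:
                    raise DomainError(
                        f"group {lab!r} is split into non-contiguous blocks in display order"
                    )
                seen_blocks.append(lab)
        if group_order and list(group_order) != seen_blocks:
            raise DomainError(
                f"group blocks appear as {seen_blocks} but group_order is {list(group_order)}"
            )


def create_domain(ids: Iterable[str], name: str = "domain") -> ObservationDomain:
    """Create a fresh domain with identity order, no groups, unlocked."""
    ids = tuple(str(i) for i in ids)
    return ObservationDomain(ids=ids, order=tuple(range(len(ids))), name=name)


def set_order(
    domain: ObservationDomain,
    new_order: Sequence[str],
    lock: bool = False,
    source: str = "",
) -> ObservationDomain:
    """Replace the display order with an explicit permutation of the ids.

    A locked domain rejects any *different* order with
    :class:`DomainConflictError`; requesting the already-locked order is a
    no-op (lock may still be strengthened). If groups are present the new
    order must keep each group's members contiguous.
    """
    new_order = [str(i) for i in new_order]
    want, have = set(new_order), set(domain.ids)
    if want != have or len(new_order) != len(domain.ids):
        missing = sorted(have - want)
        extra = sorted(want - have)
        raise DomainError(
            f"new order is not a permutation of domain ids: missing={missing}, extra={extra}"
        )
    index = {i: k for k, i in enumerate(domain.ids)}
    perm = tuple(index[i] for i in new_order)
    if domain.order_locked and perm != domain.order:
        raise DomainConflictError(
            f"domain {domain.name!r} order is locked"
            + (f" by {domain.lock_source!r}" if domain.lock_source else "")
            + f"; conflicting reorder requested{f' by {source!r}' if source else ''}"
        )
    if domain.groups is not None:
        domain._check_contiguity(perm, domain.groups, ())
    if not domain.order_locked and perm != domain.order and domain.order != tuple(
        range(len(domain.ids))
    ):
        logger.warning(
            "domain %r: unlocked order overridden by a later request%s",
            domain.name,
            f" from {source!r}" if source else "",
        )
    return replace(
        domain,
        order=perm,
        order_locked=domain.order_locked or lock,
        lock_source=domain.lock_source or (source if lock else ""),
    )


def set_groups(
    domain: ObservationDomain,
    mapping: Mapping[str, str],
    group_order: Sequence[str] | None = None,
    lock: bool = False,
    source: str = "",
) -> ObservationDomain:
    """Group observations; display order becomes the stable partition of the
    previous order (groups in ``group_order``, within-group order preserved).

    Default ``group_order`` is first appearance in the previous display order.
    """
    missing = [i for i in domain.ids if i not in mapping]
    unknown = [i for i in mapping if i not in set(domain.ids)]
    if missing or unknown:
        raise DomainError(
            f"group mapping must cover every id exactly once; missing={missing}, unknown={unknown}"
        )
    mapping = {str(k): str(v) for k, v in mapping.items()}
    if domain.groups_locked and dict(domain.groups or {}) != mapping:
        raise DomainConflictError(
            f"domain {domain.name!r} grouping is locked"
            + (f" by {domain.lock_source!r}" if domain.lock_source else "")
            + "; conflicting grouping requested"
        )
    disp = domain.display_ids
    if group_order is None:
        group_order_list: list[str] = []
        for i in disp:
            g = mapping[i]
            if g not in group_order_list:
                group_order_list.append(g)
    else:
        group_order_list = [str(g) for g in group_order]
        labs = set(mapping.values())
        if set(group_order_list) != labs:
            raise DomainError(
                f"group_order {group_order_list} does not match group labels {sorted(labs)}"
            )
    # stable partition of the current display order
    new_disp = [i for g in group_order_list for i in disp if mapping[i] == g]
    index = {i: k for k, i in enumerate(domain.ids)}
    perm = tuple(index[i] for i in new_disp)
    if domain.order_locked and perm != domain.order:
        raise DomainConflictError(
            f"domain {domain.name!r} order is locked; grouping would change the display order"
        )
    return replace(
        domain,
        order=perm,
        groups=dict(mapping),
        group_order=tuple(group_order_list),
        groups_locked=domain.groups_locked or lock,
        lock_source=domain.lock_source or (source if lock else ""),
    )


def _imposes_order(d: ObservationDomain) -> bool:
    return d.order_locked or d.order != tuple(range(len(d.ids)))


def unify_domains(domains: Sequence[ObservationDomain]) -> ObservationDomain:
    """Merge the domains of panels sharing an axis into one consistent domain.

    All domains must carry identical id sets. A domain that imposed an order
    or grouping contributes it; two locked, differing impositions raise
    :class:`DomainConflictError` (this is the engine's misalignment guard).
    Unlocked differing impositions resolve last-writer-wins with a warning.
    """
    if not domains:
        raise DomainError("unify_domains requires at least one domain")
    ref = domains[0]
    refset = set(ref.ids)
    for d in domains[1:]:
        if set(d.ids) != refset:
            diff = sorted(refset.symmetric_difference(set(d.ids)))
            raise DomainError(
                f"domains {ref.name!r} and {d.name!r} have mismatched id sets; "
                f"symmetric difference: {diff}"
            )

    result = create_domain(ref.ids, name=ref.name)

    # grouping first (a later order must respect it)
    grouped = [d for d in domains if d.groups is not None]
    locked_groups = [d for d in grouped if d.groups_locked]
    for a in locked_groups:
        for b in locked_groups:
            if dict(a.groups) != dict(b.groups):
                raise DomainConflictError(
                    f"conflicting locked groupings from {a.name!r} and {b.name!r}"
                )
    if grouped:
        chosen = locked_groups[0] if locked_groups else grouped[-1]
        if len({frozenset(d.groups.items()) for d in grouped}) > 1 and not locked_groups:
            warnings.warn(
                "multiple unlocked groupings on one axis; using the last one",
                stacklevel=2,
            )
        result = set_groups(
            result,
            {i: chosen.groups[i] for i in ref.ids},
            group_order=chosen.group_order or None,
            lock=chosen.groups_locked,
            source=chosen.name,
        )

    imposing = [d for d in domains if _imposes_order(d)]
    locked = [d for d in imposing if d.order_locked]
    for a in locked:
        for b in locked:
            if a.display_ids != b.display_ids:
                raise DomainConflictError(
                    f"conflicting locked orders from {a.name!r} and {b.name!r}: "
                    f"{a.display_ids} vs {b.display_ids}"
                )
    if imposing:
        chosen = locked[0] if locked else imposing[-1]
        if len({d.display_ids for d in imposing}) > 1 and not locked:
            warnings.warn(
                "multiple unlocked orders on one axis; using the last one",
                stacklevel=2,
            )
        result = set_order(
            result, chosen.display_ids, lock=chosen.order_locked, source=chosen.name
        )
    return result


def observation_interval(
    domain: ObservationDomain,
    id_: str,
    extent: tuple[float, float] = (0.0, 1.0),
) -> tuple[float, float]:
    """Half-open interval ``[lo + i*w, lo + (i+1)*w)`` occupied by an observation.

    ``i`` is the display position, ``w = (hi - lo) / n``. The intervals over
    all ids tile the extent exactly.
    """
    lo, hi = extent
    n = len(domain)
    i = domain.position(id_)
    w = (hi - lo) / n
    return (lo + i * w, lo + (i + 1) * w)


def observation_intervals(
    domain: ObservationDomain, extent: tuple[float, float] = (0.0, 1.0)
) -> dict[str, tuple[float, float]]:
    """Intervals for every id, keyed by id."""
    return {i: observation_interval(domain, i, extent) for i in domain.ids}


def interval_center(iv: tuple[float, float]) -> float:
    return 0.5 * (iv[0] + iv[1])
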