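"""Observation-domain semantics: identity, ordering, grouping, locks,
unification and interval tiling."""

import pytest

from plotalign.domains import (
    DomainConflictError,
    DomainError,
    create_domain,
    observation_interval,
    observation_intervals,
    set_groups,
    set_order,
    unify_domains,
)


class TestCreate:
    def test_identity_initialization(self):
        d = create_domain(["a", "b", "c"])
        assert d.order == (0, 1, 2)
        assert d.display_ids == ("a", "b", "c")
        assert d.groups is None and not d.order_locked

    def test_duplicate_id_rejected_by_name(self):
        with pytest.raises(DomainError, match="duplicate id 'a'"):
            create_domain(["a", "a"])

    def test_empty_domain_rejected(self):
        with pytest.raises(DomainError, match="empty"):
            create_domain([])


class TestSetOrder:
    def test_reorder(self):
        d = set_order(create_domain("abc"), ["c", "a", "b"])
        assert d.display_ids == ("c", "a", "b")

    def test_not_a_permutation_lists_difference(self):
        with pytest.raises(DomainError, match="missing.*extra|extra.*missing"):
            set_order(create_domain("abc"), ["a", "b", "d"])

    def test_locked_conflict(self):
        d = set_order(create_domain("abc"), ["a", "b", "c"], lock=True)
        with pytest.raises(DomainConflictError):
            set_order(d, ["c", "b", "a"])

    def test_locked_same_order_is_noop(self):
        d = set_order(create_domain("abc"), ["a", "b", "c"], lock=True)
        assert set_order(d, ["a", "b", "c"]).display_ids == ("a", "b", "c")

    def test_group_contiguity_enforced(self):
        d = set_groups(create_domain("abc"), {"a": "g1", "b": "g2", "c": "g1"})
        with pytest.raises(DomainError, match="split"):
            set_order(d, ["a", "b", "c"])  # splits g1

    def test_idempotent(self):
        d = create_domain("abcde")
        once = set_order(d, ["d", "a", "e", "b", "c"])
        twice = set_order(once, ["d", "a", "e", "b", "c"])
        assert once.order == twice.order


class TestSetGroups:
    def test_stable_partition(self):
        d = set_groups(create_domain("abc"), {"a": "g1", "b": "g2", "c": "g1"},
                       group_order=["g1", "g2"])
        assert d.display_ids == ("a", "c", "b")

    def test_single_group_keeps_order(self):
        d = set_order(create_domain("abc"), ["b", "c", "a"])
        d = set_groups(d, {i: "g" for i in "abc"})
        assert d.display_ids == ("b", "c", "a")

    def test_missing_id_rejected(self):
        with pytest.raises(DomainError, match="missing"):
            set_groups(create_domain("abc"), {"a": "g1", "b": "g2"})

    def test_default_group_order_is_first_appearance(self):
        d = set_order(create_domain("abcd"), ["c", "a", "d", "b"])
        d = set_groups(d, {"a": "x", "b": "y", "c": "y", "d": "x"})
        assert d.group_order == ("y", "x")
        assert d.display_ids == ("c", "b", "a", "d")

    def test_within_group_order_preserved_for_random_permutations(self, rng):
        """Stability: grouping is a stable partition of the display order."""
        ids = [f"i{k}" for k in range(12)]
        groups = {i: f"g{k % 3}" for k, i in enumerate(ids)}
        for _ in range(120):
            perm = list(rng.permutation(ids))
            d = set_order(create_domain(ids), perm)
            g = set_groups(d, groups)
            for lab in ("g0", "g1", "g2"):
                before = [i for i in perm if groups[i] == lab]
                after = [i for i in g.display_ids if groups[i] == lab]
                assert before == after


class TestUnify:
    def test_identity_pair(self):
        a, b = create_domain("abc"), create_domain("abc")
        assert unify_domains([a, b]).display_ids == ("a", "b", "c")

    def test_single_imposition_wins(self):
        a = create_domain("abc")
        b = set_order(create_domain("abc", name="panelB"), ["c", "a", "b"],
                      lock=True)
        assert unify_domains([a, b]).display_ids == ("c", "a", "b")

    def test_locked_conflict_names_both_sources(self):
        a = set_order(create_domain("abc", name="p1"), ["a", "b", "c"], lock=True)
        b = set_order(create_domain("abc", name="p2"), ["c", "b", "a"], lock=True)
        with pytest.raises(DomainConflictError, match="p1.*p2|p2.*p1"):
            unify_domains([a, b])

    def test_id_mismatch_lists_symmetric_difference(self):
        with pytest.raises(DomainError, match="d.*|x.*"):
            unify_domains([create_domain("abc"), create_domain("abd")])

    def test_propagation_is_bit_identical(self):
        imposed = set_order(create_domain("abcd"), ["d", "c", "b", "a"])
        unified = unify_domains([create_domain("abcd"), imposed])
        again = unify_domains([unified, unified])
        assert unified.display_ids == again.display_ids == ("d", "c", "b", "a")
        assert unified.order == again.order


class TestIntervals:
    def test_quarter_interval(self):
        d = create_domain("wxyz")
        lo, hi = observation_interval(d, "y", (0.0, 1.0))  # position 2 of 4
        assert (lo, hi) == (0.5, 0.75)
        assert 0.5 * (lo + hi) == 0.625

    def test_single_observation_fills_extent(self):
        d = create_domain(["a"])
        assert observation_interval(d, "a", (0.0, 1.0)) == (0.0, 1.0)

    def test_affine_extent(self):
        d = create_domain("wxyz")
        lo, hi = observation_interval(d, "y", (0.2, 0.6))
        assert lo == pytest.approx(0.4, abs=1e-15)
        assert hi == pytest.approx(0.5, abs=1e-15)

    def test_unknown_id(self):
        with pytest.raises(DomainError, match="unknown id"):
            observation_interval(create_domain("ab"), "q")

    @pytest.mark.parametrize("n", [1, 2, 7, 31])
    def test_intervals_tile_extent(self, n, rng):
        d = create_domain([f"i{k}" for k in range(n)])
        d = set_order(d, list(rng.permutation(d.ids)))
        lo, hi = 0.13, 0.87
        ivs = sorted(observation_intervals(d, (lo, hi)).values())
        assert ivs[0][0] == pytest.approx(lo, abs=1e-12)
        assert ivs[-1][1] == pytest.approx(hi, abs=1e-12)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            assert a1 == pytest.approx(b0, abs=1e-12)
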