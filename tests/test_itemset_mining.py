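import numpy as np
import pytest

from bic2pam import (
    CostTable,
    MinerParams,
    alpha_reduce,
    build_tree,
    mine_closed,
    mu_reduce,
    parse_constraint,
)
from bic2pam.preprocess import ItemsetDatabase, format_item, value_item
from conftest import random_itemset_db
from oracles import closed_itemsets_bruteforce


def names(fp):
    return frozenset(format_item(i) for i in fp.items)


def result_set(fps):
    return {(names(fp), fp.coverage) for fp in fps}


class TestTreeConstruction:
    def test_shared_prefix_with_two_branches(self, worked_db):
        tree = build_tree(worked_db, MinerParams(min_support=1, min_length=1))
        # support order a(3) > b=c=d(2), lexicographic ties: a,b,c,d
        assert [i[1] for i in tree.order] == ["a", "b", "c", "d"]
        (a_node,) = tree.root.children.values()
        assert a_node.item[1] == "a"
        assert sorted(c.item[1] for c in a_node.children.values()) == ["b", "d"]

    def test_single_transaction_single_path_with_tid(self):
        tree = build_tree({"t1": {"a", "b"}}, MinerParams(min_support=1, min_length=1))
        node = tree.root
        while node.children:
            (node,) = node.children.values()
        assert node.tids == {"t1"}

    def test_min_support_three_keeps_only_shared_item(self, worked_db):
        tree = build_tree(worked_db, MinerParams(min_support=3, min_length=1))
        assert [i[1] for i in tree.order] == ["a"]

    def test_terminal_tid_sets_partition_database(self, worked_db):
        tree = build_tree(worked_db, MinerParams(min_support=1, min_length=1))
        assert tree.n_transactions() == len(worked_db)


class TestReductions:
    def _network_db(self):
        return ItemsetDatabase({
            "x1": frozenset({value_item("y1", -1), value_item("y2", 3),
                             value_item("y3", 1)}),
            "x2": frozenset({value_item("y1", 0), value_item("y2", 2),
                             value_item("y3", 1)}),
            "x3": frozenset({value_item("y1", 1), value_item("y2", 0),
                             value_item("y3", 2)}),
            "x4": frozenset({value_item("y1", 1), value_item("y2", -1),
                             value_item("y3", 2)}),
        })

    def test_mu_removes_transactions_that_cannot_satisfy(self):
        out = mu_reduce(self._network_db(), parse_constraint("min(pattern) = 0"))
        assert sorted(out.transactions) == ["x2", "x3"]

    def test_mu_identity_when_all_satisfy(self):
        db = self._network_db()
        out = mu_reduce(db, parse_constraint("max(pattern) >= -5"))
        assert out.transactions == db.transactions

    def test_mu_range_requirement_can_empty_database(self):
        db = ItemsetDatabase({
            "t1": frozenset({value_item("y1", 0), value_item("y2", 1)}),
            "t2": frozenset({value_item("y1", 1), value_item("y2", 2)}),
        })
        out = mu_reduce(db, parse_constraint("range(pattern) >= 4"))
        assert len(out) == 0

    def test_alpha_removes_conflicting_items(self):
        out = alpha_reduce(self._network_db(), parse_constraint("min(pattern) = 0"))
        assert value_item("y1", -1) not in out.transactions["x1"]
        assert value_item("y2", -1) not in out.transactions["x4"]

    def test_alpha_identity_without_conflicts(self):
        db = self._network_db()
        out = alpha_reduce(db, parse_constraint("range(pattern) >= 1"))
        assert out.transactions == db.transactions

    def test_alpha_drops_transactions_below_min_length(self):
        db = ItemsetDatabase({
            "t1": frozenset({value_item("y1", -1), value_item("y2", 5)}),
            "t2": frozenset({value_item("y1", 2), value_item("y2", 3)}),
        })
        out = alpha_reduce(db, parse_constraint("min(pattern) >= 0"), min_length=2)
        assert sorted(out.transactions) == ["t2"]


class TestWorkedExamples:
    """The printed three-transaction database under each constraint class."""

    def run(self, worked_db, worked_costs, text):
        cons = (parse_constraint(text),) if text else ()
        fps, stats = mine_closed(worked_db, MinerParams(
            min_support=1, min_length=2, constraints=cons, costs=worked_costs))
        return fps, stats

    def test_monotone_range_gives_three_patterns(self, worked_db, worked_costs):
        fps, _ = self.run(worked_db, worked_costs, "range(pattern) >= 2")
        assert len(fps) == 3

    def test_anti_monotone_sum_gives_ab(self, worked_db, worked_costs):
        fps, _ = self.run(worked_db, worked_costs, "sum(pattern) <= 1")
        assert result_set(fps) == {(frozenset({"a", "b"}), frozenset({"x1", "x2"}))}

    def test_succinct_superset_gives_abcd(self, worked_db, worked_costs):
        fps, _ = self.run(worked_db, worked_costs, "pattern superset {c,d}")
        assert result_set(fps) == {
            (frozenset({"a", "b", "c", "d"}), frozenset({"x2"}))}

    def test_convertible_avg_gives_bcd(self, worked_db, worked_costs):
        fps, _ = self.run(worked_db, worked_costs, "avg(pattern) >= 2")
        assert result_set(fps) == {(frozenset({"b", "c", "d"}), frozenset({"x2"}))}

    def test_unconstrained_closed_set(self, worked_db, worked_costs):
        fps, _ = self.run(worked_db, worked_costs, None)
        assert result_set(fps) == {
            (frozenset({"a", "b", "c"}), frozenset({"x1", "x2"})),
            (frozenset({"a", "d"}), frozenset({"x2", "x3"})),
            (frozenset({"a", "b", "c", "d"}), frozenset({"x2"})),
        }

    def test_reported_support_matches_recomputed_coverage(self, worked_db,
                                                          worked_costs):
        fps, _ = self.run(worked_db, worked_costs, None)
        for fp in fps:
            recomputed = {t for t, its in worked_db.items()
                          if {i[1] for i in fp.items} <= its}
            assert fp.support == len(recomputed)
            assert fp.coverage == frozenset(recomputed)


CONSTRAINT_CLASSES = [
    None,
    "sum(pattern) <= 4",          # anti-monotone
    "max(pattern) <= 3",          # anti-monotone (value bound)
    "range(pattern) >= 2",        # monotone
    "countVal(pattern) >= 2",     # monotone
    "pattern superset {a,b}",     # succinct required items
    "pattern excludes {c}",       # succinct forbidden items
    "avg(pattern) >= 2",          # convertible
    "avg(pattern) <= 2",          # convertible, opposite direction
    "min(pattern) = 1",           # succinct equality
    "rows superset {t1}",         # coverage constraint
    "pattern contains {a} or pattern contains {f}",  # succinct disjunction
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("text", CONSTRAINT_CLASSES,
                             ids=[str(t) for t in CONSTRAINT_CLASSES])
    @pytest.mark.parametrize("tau", [1, 2, 5])
    def test_matches_bruteforce_on_random_databases(self, text, tau):
        rng = np.random.default_rng(abs(hash((text, tau))) % 2**31)
        cons = (parse_constraint(text),) if text else ()
        for trial in range(12):
            db = random_itemset_db(rng, n_trans=int(rng.integers(3, 9)),
                                   n_items=int(rng.integers(3, 7)))
            costs = CostTable({c: int(rng.integers(0, 5))
                               for c in "abcdefgh"})
            minsup = int(rng.integers(1, 3))
            params = MinerParams(min_support=minsup, min_length=2,
                                 constraints=cons, costs=costs, tau=tau)
            got = {(frozenset(i[1] for i in fp.items), fp.coverage)
                   for fp in mine_closed(db, params)[0]}
            want = {(frozenset(i[1] for i in p), cov)
                    for p, cov in closed_itemsets_bruteforce(
                        db, minsup, 2, cons, costs)}
            assert got == want, (db, text, minsup)

    @pytest.mark.parametrize("text", [t for t in CONSTRAINT_CLASSES if t])
    def test_pushing_never_changes_results_and_prunes(self, text):
        rng = np.random.default_rng(abs(hash(("push", text))) % 2**31)
        cons = (parse_constraint(text),)
        for trial in range(10):
            db = random_itemset_db(rng, n_trans=7, n_items=6)
            costs = CostTable({c: int(rng.integers(0, 5)) for c in "abcdefgh"})
            pushed, st_pushed = mine_closed(db, MinerParams(
                min_support=1, min_length=2, constraints=cons, costs=costs))
            plain, st_plain = mine_closed(db, MinerParams(
                min_support=1, min_length=2, constraints=cons, costs=costs,
                push=False))
            assert result_set(pushed) == result_set(plain)
            assert st_pushed.visited_nodes <= st_plain.visited_nodes


class TestMiningDetails:
    def test_fraction_support_converts_to_count(self, worked_db):
        fps, _ = mine_closed(worked_db, MinerParams(min_support=0.6, min_length=2))
        # ceil(0.6 * 3) = 2 supporting transactions required
        assert all(fp.support >= 2 for fp in fps)

    def test_empty_database(self):
        fps, _ = mine_closed({}, MinerParams(min_support=1, min_length=1))
        assert fps == []

    def test_all_items_infrequent_yields_empty_tree(self):
        db = {"t1": {"a"}, "t2": {"b"}}
        tree = build_tree(db, MinerParams(min_support=2, min_length=1))
        assert tree.order == []

    def test_one_symbol_per_column_in_patterns(self):
        # multi-item assignment puts two symbols of one column in a
        # transaction; patterns must not use both
        db = ItemsetDatabase({
            "t1": frozenset({value_item("y1", 1), value_item("y1", 2),
                             value_item("y2", 1)}),
            "t2": frozenset({value_item("y1", 1), value_item("y1", 2),
                             value_item("y2", 1)}),
        })
        fps, _ = mine_closed(db, MinerParams(min_support=1, min_length=2))
        for fp in fps:
            cols = [i[1] for i in fp.items]
            assert len(cols) == len(set(cols))

    def test_saturation_cap_flags_truncation(self):
        rng = np.random.default_rng(0)
        db = {f"t{i}": frozenset("abcdefgh") for i in range(5)}
        fps, st = mine_closed(db, MinerParams(min_support=1, min_length=2,
                                              max_patterns=3))
        assert st.saturated
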