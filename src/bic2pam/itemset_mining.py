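"""Closed frequent itemset mining with transaction ids and constraint pushing.

The engine is an FP-growth variant (F2G) whose tree carries transaction
identifiers at path terminals, so every pattern comes out with its exact
coverage — the ingredient that turns frequent itemsets into biclusters.
Constraint pushing follows the established repertoire:

* succinct constraints remove conflicting transactions and items before the
  tree is built;
* anti-monotone constraints stop the growth of violating patterns;
* monotone constraints drive the mu-reduction (drop transactions whose full
  item set cannot satisfy the constraint) and alpha-reduction (drop single
  items that doom any pattern containing them), re-applied on every tau-th
  conditional projection (the FP-Bonsai discipline);
* convertible average constraints order the header table by cost, making a
  violating prefix safely prunable.

Closure is computed *within the constraint-satisfying pattern space*: a
satisfying pattern is reported iff no satisfying strict superset has the same
coverage.  This differs from unconstrained closure — e.g. under sum <= 1 the
pattern {a,b} is reported even when its unconstrained closure {a,b,c}
violates the constraint — and is what the pattern-to-bicluster mapping needs.

Pruning never changes the result set relative to an unpruned run followed by
post-filtering; only the number of visited candidates differs (exposed via
:class:`MinerStats` so pruning effectiveness is testable without timing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .constraints import (
    AggregateAtom,
    Constraint,
    CostTable,
    DEFAULT_COSTS,
    SetAtom,
)
from .patterns import FullPattern
from .preprocess import (
    ItemsetDatabase,
    is_annotation,
    item_column,
    item_symbol,
    raw_item,
)


@dataclass
class MinerParams:
    """Mining thresholds, constraints and pruning controls.

    ``min_support`` given as a fraction in (0, 1] is converted to
    ``ceil(fraction * |D|)``; ``tau`` is the periodicity of mu/alpha
    re-reduction on conditional projections; ``push=False`` disables all
    constraint pushing (constraints are then enforced purely by
    post-filtering — used to verify result invariance).
    """

    min_support: float = 2
    min_length: int = 2
    constraints: tuple[Constraint, ...] = ()
    costs: CostTable = field(default_factory=CostTable)
    tau: int = 1
    push: bool = True
    max_patterns: int | None = None

    def support_count(self, n_transactions: int) -> int:
        if self.min_support <= 0:
            raise ValueError("min_support must be positive")
        if isinstance(self.min_support, float) and self.min_support <= 1.0:
            return max(1, math.ceil(self.min_support * n_transactions))
        return int(self.min_support)


@dataclass
class MinerStats:
    """Search-effort counters; pruned runs must satisfy visited <= unpruned."""

    visited_nodes: int = 0
    projections: int = 0
    emitted: int = 0
    mu_removed: int = 0
    alpha_removed: int = 0
    saturated: bool = False


class _Saturated(Exception):
    pass


# ---------------------------------------------------------------------------
# FP-tree with transaction ids at path terminals
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("item", "parent", "children", "tids")

    def __init__(self, item, parent):
        self.item = item
        self.parent = parent
        self.children: dict = {}
        self.tids: set = set()


class FPTree:
    """Prefix-compressed transaction trie with a header of node links.

    ``order`` is the header order (items inserted in this order along every
    path); transaction-id sets sit at the node where each transaction's path
    ends and rise to ancestors as deeper items are retired during mining.
    """

    def __init__(self, order: Sequence):
        self.order = list(order)
        self.rank = {it: k for k, it in enumerate(self.order)}
        self.root = _Node(None, None)
        self.header: dict[object, list[_Node]] = {it: [] for it in self.order}

    def insert(self, items: Iterable, tids: Iterable) -> None:
        path = sorted((it for it in items if it in self.rank), key=self.rank.get)
        node = self.root
        for it in path:
            child = node.children.get(it)
            if child is None:
                child = _Node(it, node)
                node.children[it] = child
                self.header[it].append(child)
            node = child
        node.tids.update(tids)

    def n_transactions(self) -> int:
        def count(node: _Node) -> int:
            return len(node.tids) + sum(count(c) for c in node.children.values())

        return count(self.root)

    def retire(self, item) -> None:
        """Remove *item*'s nodes, rising their tids to the parents."""
        for node in self.header.get(item, ()):
            node.parent.tids.update(node.tids)
            node.parent.children.pop(item, None)
        self.header[item] = []

    def prefix_path(self, node: _Node) -> list:
        path = []
        cur = node.parent
        while cur is not None and cur.item is not None:
            path.append(cur.item)
            cur = cur.parent
        path.reverse()
        return path


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _as_fullpattern(items: frozenset, coverage: frozenset = frozenset()) -> FullPattern:
    cols = sorted({item_column(i) for i in items if item_column(i) is not None})
    col_sym = {}
    for it in items:
        c = item_column(it)
        if c is not None:
            col_sym.setdefault(c, item_symbol(it))
    if cols:
        symbols = tuple(col_sym[c] for c in cols)
    else:
        symbols = tuple(sorted((item_symbol(i) for i in items
                                if not is_annotation(i)), key=str))
    return FullPattern(items=items, coverage=coverage, columns=tuple(cols),
                       symbols=symbols, kind="itemset")


def _mu_eligible(atom, props: frozenset) -> bool:
    """Whole-transaction removal is sound for monotone atoms (the full item
    set is the best case) and for succinct min/max equality (membership
    test); succinct exclusions are handled by alpha-reduction instead."""
    if "monotone" in props:
        return True
    return (isinstance(atom, AggregateAtom) and atom.cmp == "="
            and atom.agg in ("min", "max"))


def _pushed_atoms(params: MinerParams, nonneg: bool):
    """Split pushed conjunct atoms by the property class used at each hook."""
    am, mono, rows_cov, convertible = [], [], [], []
    for c in params.constraints:
        for a in c.pushable_conjuncts():
            props = a.classify(nonneg)
            if isinstance(a, SetAtom) and a.target == "rows":
                if "anti_monotone" in props:
                    rows_cov.append(a)
                continue
            if "anti_monotone" in props:
                am.append(a)
            if _mu_eligible(a, props):
                mono.append(a)
            if "convertible_am" in props:
                convertible.append(a)
    return am, mono, rows_cov, convertible


def _transaction_can_satisfy(atom, items: frozenset, costs: CostTable) -> bool:
    """Monotone/succinct mu test: can any sub-pattern of *items* satisfy?

    For monotone atoms the transaction's full item set is the best case.
    Equality atoms get a dedicated membership test (a min = v pattern needs a
    cost-v item), everything else falls back to evaluating the full set.
    """
    fp = _as_fullpattern(items)
    if isinstance(atom, AggregateAtom) and atom.cmp == "=" and atom.agg in ("min", "max"):
        vals = [costs.cost(item_symbol(i)) for i in items if not is_annotation(i)]
        return any(v == atom.threshold for v in vals)
    try:
        return atom.evaluate(fp, costs)
    except Exception:
        return True  # unknown -> never reduce on it


def mu_reduce(
    db: ItemsetDatabase | Mapping,
    constraint: Constraint,
    costs: CostTable = DEFAULT_COSTS,
) -> ItemsetDatabase:
    """Delete transactions whose full item set cannot satisfy *constraint*.

    Sound for monotone (and succinct membership) constraints: a transaction
    failing a monotone constraint supports no satisfying sub-pattern.
    """
    trans = db.transactions if isinstance(db, ItemsetDatabase) else dict(db)
    atoms = [a for a in constraint.pushable_conjuncts()
             if _mu_eligible(a, a.classify())]
    atoms = [a for a in atoms if not (isinstance(a, SetAtom) and a.target == "rows")]
    kept = {
        tid: _coerce_items(items)
        for tid, items in trans.items()
        if all(_transaction_can_satisfy(a, _coerce_items(items), costs) for a in atoms)
    }
    if isinstance(db, ItemsetDatabase):
        return ItemsetDatabase(kept, db.coherency, dict(db.row_factors),
                               {m: s for m, s in db.mirror_of.items() if m in kept})
    return ItemsetDatabase(kept)


def alpha_reduce(
    db: ItemsetDatabase | Mapping,
    constraint: Constraint,
    costs: CostTable = DEFAULT_COSTS,
    min_length: int = 1,
) -> ItemsetDatabase:
    """Delete single items that doom every pattern containing them; drop
    transactions left shorter than the minimum pattern length."""
    trans = db.transactions if isinstance(db, ItemsetDatabase) else dict(db)
    nonneg = _costs_nonneg(trans, costs)
    atoms = list(constraint.pushable_conjuncts())
    kept: dict[str, frozenset] = {}
    for tid, items in trans.items():
        items = _coerce_items(items)
        filtered = frozenset(
            i for i in items
            if not any(_atom_dooms(a, i, costs, nonneg) for a in atoms)
        )
        if len(filtered) >= min_length:
            kept[tid] = filtered
    if isinstance(db, ItemsetDatabase):
        return ItemsetDatabase(kept, db.coherency, dict(db.row_factors),
                               {m: s for m, s in db.mirror_of.items() if m in kept})
    return ItemsetDatabase(kept)


def _atom_dooms(atom, item, costs: CostTable, nonneg: bool) -> bool:
    if isinstance(atom, AggregateAtom) and atom.agg == "sum" and not nonneg:
        return False
    try:
        return atom.item_dooms(item, costs)
    except Exception:
        return False


def _coerce_items(items: Iterable) -> frozenset:
    return frozenset(i if isinstance(i, tuple) else raw_item(i) for i in items)


def _costs_nonneg(trans: Mapping, costs: CostTable) -> bool:
    for items in trans.values():
        for i in _coerce_items(items):
            if is_annotation(i):
                continue
            try:
                if costs.cost(item_symbol(i)) < 0:
                    return False
            except Exception:
                return False
    return True


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _header_order(supports: Mapping, costs: CostTable, convertible) -> list:
    """Descending support by default; cost-sorted when a convertible average
    constraint is active, in the direction that makes its violation prunable
    (pattern growth adds items from the near end of the header)."""
    items = list(supports)
    if convertible:
        lead = convertible[0]
        ascending = lead.cmp == ">="

        def cost_key(it):
            try:
                c = costs.cost(item_symbol(it))
            except Exception:
                c = 0.0
            return (c if ascending else -c, str(it))

        return sorted(items, key=cost_key)
    return sorted(items, key=lambda it: (-supports[it], str(it)))


def build_tree(
    db: ItemsetDatabase | Mapping,
    params: MinerParams,
    stats: MinerStats | None = None,
) -> FPTree:
    """Build the initial FP-tree: succinct/mu/alpha reductions, frequency
    filtering, header ordering, tids attached at path terminals."""
    stats = stats or MinerStats()
    trans = db.transactions if isinstance(db, ItemsetDatabase) else db
    trans = {tid: _coerce_items(items) for tid, items in trans.items()}
    minsup = params.support_count(len(trans))
    nonneg = _costs_nonneg(trans, params.costs)
    am, mono, rows_cov, convertible = _pushed_atoms(params, nonneg)

    if params.push and params.constraints:
        before = len(trans)
        for c in params.constraints:
            reduced = mu_reduce(ItemsetDatabase(trans), c, params.costs)
            trans = reduced.transactions
            reduced = alpha_reduce(ItemsetDatabase(trans), c, params.costs,
                                   params.min_length)
            trans = reduced.transactions
        stats.mu_removed += before - len(trans)

    supports: dict = {}
    for items in trans.values():
        for it in items:
            supports[it] = supports.get(it, 0) + 1
    supports = {it: s for it, s in supports.items() if s >= minsup}
    order = _header_order(supports, params.costs,
                          convertible if params.push else [])
    tree = FPTree(order)
    for tid, items in trans.items():
        tree.insert(items, [tid])
    return tree


# ---------------------------------------------------------------------------
# mining
# ---------------------------------------------------------------------------

def mine_closed(
    db: ItemsetDatabase | Mapping,
    params: MinerParams,
) -> tuple[list[FullPattern], MinerStats]:
    """Mine closed full-patterns under thresholds and constraints.

    Returns the patterns satisfying min support, min length and every
    constraint, closed within the satisfying space, each with its exact
    coverage; plus the search-effort counters.
    """
    stats = MinerStats()
    trans = db.transactions if isinstance(db, ItemsetDatabase) else db
    trans = {tid: _coerce_items(items) for tid, items in trans.items()}
    n = len(trans)
    if n == 0:
        return [], stats
    minsup = params.support_count(n)
    nonneg = _costs_nonneg(trans, params.costs)
    am, mono, rows_cov, convertible = (
        _pushed_atoms(params, nonneg) if params.push else ([], [], [], [])
    )
    if convertible:
        # the header is cost-ordered for the first convertible atom; only
        # atoms sharing its direction are safely prefix-prunable
        convertible = [a for a in convertible if a.cmp == convertible[0].cmp]
    tree = build_tree(db, params, stats)

    collected: dict[frozenset, list[frozenset]] = {}

    def emit(pattern: frozenset, coverage: frozenset) -> None:
        if len(pattern) < params.min_length:
            return
        fp = _as_fullpattern(pattern, coverage)
        if not all(c.evaluate(fp, params.costs) for c in params.constraints):
            return
        stats.emitted += 1
        collected.setdefault(coverage, []).append(pattern)
        if params.max_patterns is not None and stats.emitted > params.max_patterns:
            raise _Saturated

    def reductions_ok(pattern: frozenset, path: list) -> bool:
        """mu test on a conditional transaction: patterns grown from it are
        subsets of pattern + path items; if that whole set fails a monotone
        atom, no satisfying pattern can come from this transaction."""
        full = pattern | frozenset(path)
        return all(_transaction_can_satisfy(a, full, params.costs) for a in mono)

    def mine_tree(tree: FPTree, pattern: frozenset, pattern_cols: frozenset,
                  pending_mono: tuple) -> None:
        for item in reversed(tree.order):
            nodes = tree.header.get(item, [])
            if not nodes:
                continue
            coverage = frozenset().union(*(n.tids for n in nodes))
            col = item_column(item)
            if len(coverage) < minsup or (col is not None and col in pattern_cols):
                tree.retire(item)
                continue
            stats.visited_nodes += 1
            new_pattern = pattern | {item}
            fp_new = _as_fullpattern(new_pattern, coverage)

            prune = False
            if params.push:
                if any(not a.coverage_ok(coverage) for a in rows_cov):
                    prune = True
                if not prune and any(not a.evaluate(fp_new, params.costs) for a in am):
                    prune = True
                if not prune and convertible and not all(
                    a.evaluate(fp_new, params.costs) for a in convertible
                ):
                    prune = True  # cost-ordered header: violation cannot recover
            if prune:
                tree.retire(item)
                continue

            # monotone atoms satisfied by this prefix need no further checks
            still_pending = tuple(
                a for a in pending_mono if not a.evaluate(fp_new, params.costs)
            )

            emit(new_pattern, coverage)

            base = []
            for node in nodes:
                if not node.tids:
                    continue
                path = tree.prefix_path(node)
                if path:
                    base.append((path, node.tids))
            if base:
                stats.projections += 1
                if params.push and params.tau >= 1 and (
                    stats.projections % params.tau == 0
                ):
                    before = len(base)
                    base = [
                        (p, t) for p, t in base
                        if reductions_ok(new_pattern, p)
                        and len(p) + len(new_pattern) >= params.min_length
                    ]
                    stats.mu_removed += before - len(base)
                supports: dict = {}
                for path, tids in base:
                    for it in path:
                        supports[it] = supports.get(it, 0) + len(tids)
                keep = {it for it, s in supports.items() if s >= minsup}
                if keep:
                    cond = FPTree([it for it in tree.order if it in keep])
                    for path, tids in base:
                        cond.insert([it for it in path if it in keep], tids)
                    new_cols = pattern_cols | ({col} if col is not None else set())
                    mine_tree(cond, new_pattern, new_cols, still_pending)
            tree.retire(item)

    pending = tuple(mono)
    try:
        mine_tree(tree, frozenset(), frozenset(), pending)
    except _Saturated:
        stats.saturated = True

    # closure within the satisfying space: per coverage, keep set-maximal
    result: list[FullPattern] = []
    for coverage, patterns in collected.items():
        patterns = sorted(set(patterns), key=len, reverse=True)
        maximal: list[frozenset] = []
        for p in patterns:
            if not any(p < q for q in maximal):
                maximal.append(p)
        for p in maximal:
            result.append(_as_fullpattern(p, coverage))
    result.sort(key=lambda fp: (-fp.support, -fp.length, repr(fp)))
    return result, stats
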