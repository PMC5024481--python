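"""Closed sequential pattern mining over item-indexable sequences.

Order-preserving biclusters correspond to frequent closed sequential
patterns over databases where every row lists its column ids sorted by
value, columns with tied values sharing one co-occurrence itemset.  Such
sequences are *item-indexable*: a token occurs at most once per sequence, so
every pattern has a unique embedding and prefix projections reduce to rank
comparisons on a per-sequence position index (the IndexSpan idea).

The search is a prefix-growth DFS (PrefixSpan style) with constraint
pushing via the prefix-monotone property:

* a prefix violating an anti-monotone bound (maximum precedences,
  co-occurrences or items) or conflicting with the regular expression is
  never expanded;
* a projected sequence that cannot satisfy a monotone constraint (required
  columns, required sub-orderings) is dropped from the projection — sound
  precisely because embeddings are unique;
* a super-pattern constraint already contained in the prefix is not
  re-checked on its extensions.

Closure is computed within the constraint-satisfying space over
(pattern, coverage) pairs: a satisfying pattern is reported iff no
satisfying strict supersequence has identical coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .constraints import Constraint, CostTable, DEFAULT_COSTS, RegexAtom
from .patterns import FullPattern
from .preprocess import SequenceDatabase

Element = tuple[str, ...]
Seq = tuple[Element, ...]


@dataclass
class IndexableSeqDB:
    """Per-sequence token -> itemset-rank index plus a global item index."""

    sequences: dict[str, Seq]
    positions: dict[str, dict[str, int]]
    item_index: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.sequences)


def index_db(db: SequenceDatabase | Mapping[str, Seq]) -> IndexableSeqDB:
    seqs = db.sequences if isinstance(db, SequenceDatabase) else dict(db)
    positions: dict[str, dict[str, int]] = {}
    item_index: dict[str, set[str]] = {}
    for rid, seq in seqs.items():
        pos: dict[str, int] = {}
        for rank, elem in enumerate(seq):
            for tok in elem:
                if tok in pos:
                    raise ValueError(
                        f"sequence {rid!r} repeats token {tok!r}: order-preserving "
                        "sequences must mention each column once"
                    )
                pos[tok] = rank
        positions[rid] = pos
        for tok in pos:
            item_index.setdefault(tok, set()).add(rid)
    return IndexableSeqDB(
        {r: tuple(tuple(e) for e in s) for r, s in seqs.items()},
        positions,
        {t: frozenset(s) for t, s in item_index.items()},
    )


@dataclass
class SeqConstraintSet:
    """Constraints pushable into the sequential search.

    ``required_items``/``forbidden_items`` are column tokens that must /
    must not appear; precedences count itemset transitions (a pattern of k
    itemsets has k - 1 precedences); ``super_patterns`` are sub-orderings the
    pattern must contain as a subsequence (e.g. ``((y2,), (y1,))`` for
    "y2 < y1"); ``regex`` constrains the overall shape; ``extra`` holds
    generic parsed constraints enforced at emission (aggregates over pattern
    columns use ``column_values``, the per-column medians of the supporting
    rows supplied by the caller).
    """

    required_items: frozenset[str] = frozenset()
    forbidden_items: frozenset[str] = frozenset()
    min_precedences: int = 0
    max_precedences: int | None = None
    min_cooccurrences: int = 1
    max_cooccurrences: int | None = None
    super_patterns: tuple[Seq, ...] = ()
    regex: RegexAtom | None = None
    extra: tuple[Constraint, ...] = ()

    def __post_init__(self) -> None:
        if self.min_precedences < 0 or self.min_cooccurrences < 1:
            raise ValueError("length bounds must be nonnegative")


@dataclass
class SeqMinerStats:
    visited_nodes: int = 0
    projections: int = 0
    sequences_pruned: int = 0
    emitted: int = 0
    saturated: bool = False


class _Saturated(Exception):
    pass


def seq_contains(big: Seq, small: Seq) -> bool:
    """Subsequence containment with itemset-subset matching (greedy)."""
    k = 0
    for elem in big:
        if k == len(small):
            return True
        if set(small[k]) <= set(elem):
            k += 1
    return k == len(small)


def _max_extension(prefix: Seq, seq: Seq, last_rank: int) -> Seq:
    """Largest pattern reachable from *prefix* within *seq*: the prefix with
    its last itemset completed by co-rank tokens, followed by the suffix."""
    if not prefix:
        return seq
    head = list(prefix[:-1])
    last = set(prefix[-1]) | set(seq[last_rank]) if last_rank < len(seq) else set(prefix[-1])
    head.append(tuple(sorted(last)))
    head.extend(seq[last_rank + 1:])
    return tuple(head)


def prefix_check(prefix: Seq, cs: SeqConstraintSet,
                 sequence: Seq | None = None, last_rank: int | None = None) -> str:
    """Classify a prefix (or a projected sequence) against the constraints.

    Returns ``"prune_prefix"`` when no extension of *prefix* can satisfy an
    anti-monotone bound or the regular expression; ``"prune_sequence"`` when
    the given projected sequence cannot satisfy a monotone constraint; else
    ``"continue"``.
    """
    if not prefix:
        raise ValueError("prefix must be nonempty")
    toks = {t for e in prefix for t in e}
    if toks & cs.forbidden_items:
        return "prune_prefix"
    if cs.max_precedences is not None and len(prefix) - 1 > cs.max_precedences:
        return "prune_prefix"
    if cs.max_cooccurrences is not None and any(
        len(e) > cs.max_cooccurrences for e in prefix
    ):
        return "prune_prefix"
    if cs.regex is not None and not cs.regex.prefix_viable(prefix):
        return "prune_prefix"
    if sequence is not None and last_rank is not None:
        reach = _max_extension(prefix, sequence, last_rank)
        reach_toks = {t for e in reach for t in e}
        if not cs.required_items <= reach_toks:
            return "prune_sequence"
        for sp in cs.super_patterns:
            if not seq_contains(reach, sp):
                return "prune_sequence"
    return "continue"


def project(db: SequenceDatabase | IndexableSeqDB | Mapping, prefix: Seq,
            min_support: int = 1) -> IndexableSeqDB:
    """Project the database on *prefix*: keep supporting sequences' suffixes.

    Raises when the prefix is supported by fewer than *min_support*
    sequences (projection of an infrequent prefix is a caller error).
    """
    idb = db if isinstance(db, IndexableSeqDB) else index_db(db)
    out: dict[str, Seq] = {}
    for rid, seq in idb.sequences.items():
        rank = _match_prefix(idb.positions[rid], prefix)
        if rank is None:
            continue
        out[rid] = tuple(seq[rank + 1:])
    if len(out) < min_support:
        raise ValueError(f"prefix {prefix!r} supported by {len(out)} < {min_support}")
    return index_db(out)


def _match_prefix(pos: Mapping[str, int], prefix: Seq) -> int | None:
    """Rank of the last matched itemset, or None; embeddings are unique."""
    last = -1
    for elem in prefix:
        ranks = set()
        for tok in elem:
            if tok not in pos:
                return None
            ranks.add(pos[tok])
        if len(ranks) != 1:
            return None
        (r,) = ranks
        if r <= last:
            return None
        last = r
    return last


# ---------------------------------------------------------------------------
# mining
# ---------------------------------------------------------------------------

def mine_sequential_closed(
    db: SequenceDatabase | IndexableSeqDB | Mapping,
    min_support: float,
    min_length: int = 2,
    cs: SeqConstraintSet | None = None,
    column_values: Mapping[str, float] | None = None,
    costs: CostTable = DEFAULT_COSTS,
    tau: int = 1,
    push: bool = True,
    max_patterns: int | None = None,
) -> tuple[list[FullPattern], SeqMinerStats]:
    """Mine closed frequent sequential patterns under the constraint set.

    ``min_support`` as a fraction in (0, 1] converts to a count over the
    database size; ``push=False`` disables all pruning (post-filter mode,
    used to verify result invariance).  Returns patterns with coverage,
    columns used and the ordering itself as the original pattern.
    """
    cs = cs or SeqConstraintSet()
    idb = db if isinstance(db, IndexableSeqDB) else index_db(db)
    stats = SeqMinerStats()
    n = len(idb)
    if n == 0:
        return [], stats
    if isinstance(min_support, float) and 0 < min_support <= 1.0:
        minsup = max(1, math.ceil(min_support * n))
    else:
        minsup = int(min_support)

    tokens = sorted(t for t, s in idb.item_index.items() if len(s) >= minsup)
    if push:
        tokens = [t for t in tokens if t not in cs.forbidden_items]

    collected: dict[frozenset, list[Seq]] = {}

    def emit(prefix: Seq, support: frozenset) -> None:
        total = sum(len(e) for e in prefix)
        if total < min_length:
            return
        if len(prefix) - 1 < cs.min_precedences:
            return
        if cs.min_cooccurrences > 1 and not any(
            len(e) >= cs.min_cooccurrences for e in prefix
        ):
            return
        toks = {t for e in prefix for t in e}
        if not cs.required_items <= toks or toks & cs.forbidden_items:
            return
        if cs.max_precedences is not None and len(prefix) - 1 > cs.max_precedences:
            return
        if cs.max_cooccurrences is not None and any(
            len(e) > cs.max_cooccurrences for e in prefix
        ):
            return
        if any(not seq_contains(prefix, sp) for sp in cs.super_patterns):
            return
        fp = _seq_fullpattern(prefix, support)
        if cs.regex is not None and not cs.regex.evaluate(fp):
            return
        if any(not c.evaluate(fp, costs, column_values) for c in cs.extra):
            return
        stats.emitted += 1
        collected.setdefault(support, []).append(prefix)
        if max_patterns is not None and stats.emitted > max_patterns:
            raise _Saturated

    def grow(prefix: Seq, supp: dict[str, int], pending_sp: tuple[Seq, ...]) -> None:
        """DFS node: *supp* maps supporting rid -> rank of last matched
        itemset; *pending_sp* holds super-patterns not yet satisfied."""
        stats.visited_nodes += 1
        if push:
            outcome = prefix_check(prefix, cs)
            if outcome == "prune_prefix":
                return
        emit(prefix, frozenset(supp))
        still_pending = tuple(
            sp for sp in pending_sp if not seq_contains(prefix, sp)
        ) if push else pending_sp

        stats.projections += 1
        cur = supp
        if push and tau >= 1 and stats.projections % tau == 0 and (
            cs.required_items or still_pending
        ):
            kept = {}
            for rid, rank in cur.items():
                seq = idb.sequences[rid]
                if prefix_check(prefix, cs, sequence=seq, last_rank=rank) != "prune_sequence":
                    kept[rid] = rank
            stats.sequences_pruned += len(cur) - len(kept)
            cur = kept

        last_elem = prefix[-1]
        last_tok = last_elem[-1]
        allow_s = not (push and cs.max_precedences is not None
                       and len(prefix) - 1 >= cs.max_precedences)
        allow_i = not (push and cs.max_cooccurrences is not None
                       and len(last_elem) >= cs.max_cooccurrences)
        for tok in tokens:
            # itemset extension: same rank, canonical ascending order
            if allow_i and tok > last_tok:
                isupp = {
                    rid: rank for rid, rank in cur.items()
                    if idb.positions[rid].get(tok) == rank
                }
                if len(isupp) >= minsup:
                    grow(prefix[:-1] + (last_elem + (tok,),), isupp, still_pending)
            # sequence extension: strictly later rank
            if allow_s:
                ssupp = {}
                for rid, rank in cur.items():
                    r = idb.positions[rid].get(tok)
                    if r is not None and r > rank:
                        ssupp[rid] = r
                if len(ssupp) >= minsup:
                    grow(prefix + ((tok,),), ssupp, still_pending)

    try:
        for tok in tokens:
            supp = {
                rid: idb.positions[rid][tok]
                for rid in idb.item_index.get(tok, ())
            }
            if len(supp) >= minsup:
                grow(((tok,),), supp, cs.super_patterns if push else ())
    except _Saturated:
        stats.saturated = True

    result: list[FullPattern] = []
    for coverage, patterns in collected.items():
        patterns = sorted(set(patterns),
                          key=lambda p: (-sum(len(e) for e in p), p))
        maximal: list[Seq] = []
        for p in patterns:
            if not any(p != q and seq_contains(q, p) for q in maximal):
                maximal.append(p)
        for p in maximal:
            result.append(_seq_fullpattern(p, coverage))
    result.sort(key=lambda fp: (-fp.support, -fp.length, repr(fp)))
    return result, stats


def _seq_fullpattern(prefix: Seq, coverage: frozenset) -> FullPattern:
    cols = tuple(sorted({t for e in prefix for t in e if not t.startswith("T:")}))
    return FullPattern(coverage=coverage, columns=cols, sequence=prefix,
                       kind="sequence")
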