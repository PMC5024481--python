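"""Brute-force oracles: exhaustive enumeration with constrained closure.

These deliberately share no code with the miners: itemset closure is
computed by powerset enumeration, sequential closure by enumerating every
sub-pattern of every input sequence.  Both keep, per coverage, the
set-maximal (or subsequence-maximal) patterns among those satisfying the
thresholds and constraints.
"""

from __future__ import annotations

from itertools import combinations

from bic2pam.constraints import Constraint, CostTable
from bic2pam.itemset_mining import _as_fullpattern, _coerce_items
from bic2pam.preprocess import item_column
from bic2pam.sequence_mining import _seq_fullpattern, seq_contains


def closed_itemsets_bruteforce(transactions, min_support, min_length,
                               constraints=(), costs=CostTable()):
    """All constrained closed (pattern, coverage) pairs by powerset search."""
    trans = {tid: _coerce_items(items) for tid, items in transactions.items()}
    universe = sorted({i for t in trans.values() for i in t}, key=str)
    satisfying = []
    for r in range(max(1, min_length), len(universe) + 1):
        for combo in combinations(universe, r):
            pattern = frozenset(combo)
            cols = [item_column(i) for i in pattern if item_column(i) is not None]
            if len(cols) != len(set(cols)):
                continue  # at most one symbol per column, as in the miner
            coverage = frozenset(t for t, its in trans.items() if pattern <= its)
            if len(coverage) < min_support:
                continue
            fp = _as_fullpattern(pattern, coverage)
            if all(c.evaluate(fp, costs) for c in constraints):
                satisfying.append((pattern, coverage))
    by_cov: dict = {}
    for pattern, coverage in satisfying:
        by_cov.setdefault(coverage, []).append(pattern)
    out = set()
    for coverage, patterns in by_cov.items():
        for p in patterns:
            if not any(p < q for q in patterns):
                out.add((p, coverage))
    return out


def _subpatterns(seq):
    """Every canonical sub-pattern of a sequence (nonempty sub-itemsets of a
    subsequence of its elements)."""
    results = {()}
    for elem in seq:
        subsets = []
        for r in range(1, len(elem) + 1):
            subsets.extend(tuple(sorted(c)) for c in combinations(elem, r))
        new = set()
        for prefix in results:
            for s in subsets:
                new.add(prefix + (s,))
        results |= new
    results.discard(())
    return results


def closed_sequences_bruteforce(sequences, min_support, min_length,
                                check=None):
    """All constrained closed sequential (pattern, coverage) pairs.

    *check* is a predicate on the pattern (tuple of tuples); coverage is
    subsequence containment with itemset-subset matching.
    """
    seqs = {rid: tuple(tuple(e) for e in s) for rid, s in sequences.items()}
    candidates = set()
    for s in seqs.values():
        candidates |= _subpatterns(s)
    satisfying = []
    for p in candidates:
        if sum(len(e) for e in p) < min_length:
            continue
        coverage = frozenset(r for r, s in seqs.items() if seq_contains(s, p))
        if len(coverage) < min_support:
            continue
        if check is not None and not check(p, coverage):
            continue
        satisfying.append((p, coverage))
    by_cov: dict = {}
    for p, cov in satisfying:
        by_cov.setdefault(cov, []).append(p)
    out = set()
    for cov, patterns in by_cov.items():
        for p in patterns:
            if not any(p != q and seq_contains(q, p) for q in patterns):
                out.add((p, cov))
    return out


def seq_check_from_constraintset(cs, costs=CostTable(), column_values=None):
    """Build an oracle-side predicate mirroring a SeqConstraintSet."""

    def check(p, cov):
        toks = {t for e in p for t in e}
        if not cs.required_items <= toks or toks & cs.forbidden_items:
            return False
        if len(p) - 1 < cs.min_precedences:
            return False
        if cs.max_precedences is not None and len(p) - 1 > cs.max_precedences:
            return False
        if cs.min_cooccurrences > 1 and not any(
            len(e) >= cs.min_cooccurrences for e in p
        ):
            return False
        if cs.max_cooccurrences is not None and any(
            len(e) > cs.max_cooccurrences for e in p
        ):
            return False
        if any(not seq_contains(p, sp) for sp in cs.super_patterns):
            return False
        fp = _seq_fullpattern(p, cov)
        if cs.regex is not None and not cs.regex.evaluate(fp):
            return False
        return all(c.evaluate(fp, costs, column_values) for c in cs.extra)

    return check
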