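"""Constraint expressions: parsing, property classification and evaluation.

Constraints are predicates over full-patterns: over the pattern's original
symbols (``pattern``), its database items (``items``), its supporting rows
(``rows``) or its columns (``cols``).  Two forms are supported, plus regular
expressions for sequential patterns:

* aggregate comparisons — ``min(pattern) <= -3``, ``countVal(pattern) >= 2``,
  ``avg(pattern) >= 2`` — computed against a cost table mapping each symbol
  to a real value (by default, an integer symbol costs its own value);
* set relations — ``rows superset {x2,x3}``, ``pattern contains {T:T1}``,
  ``items excludes {y2.0}``.

Each atom is classified by the pruning property it offers the miners:

==============  ==========================================================
succinct        decidable by membership tests; pushable as pre-filtering
monotone        once satisfied, stays satisfied under pattern supersets
anti_monotone   once violated, stays violated under pattern supersets
convertible_am  prefix-prunable under a cost-sorted item ordering (avg)
prefix_monotone sequential analogue (regular expressions)
==============  ==========================================================

Expressions combine atoms with ``and``/``or`` (``and`` binds tighter); one
constraint per line, ``#`` starts a comment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .patterns import FullPattern
from .preprocess import is_annotation, item_symbol

AGGS = ("min", "max", "range", "sum", "avg", "countVal", "length")
TARGETS = ("pattern", "items", "rows", "cols")
RELS = ("contains", "superset", "excludes")
CMPS = ("<=", ">=", "=")


class ConstraintError(ValueError):
    """Syntax or binding error in a constraint expression."""


# ---------------------------------------------------------------------------
# cost tables
# ---------------------------------------------------------------------------

@dataclass
class CostTable:
    """Symbol -> real cost; integer symbols default to their own value."""

    costs: dict = field(default_factory=dict)

    def cost(self, symbol) -> float:
        if symbol in self.costs:
            return float(self.costs[symbol])
        if isinstance(symbol, (int, float)):
            return float(symbol)
        raise ConstraintError(f"no cost defined for symbol {symbol!r}")

    def nonnegative(self, symbols: Iterable) -> bool:
        try:
            return all(self.cost(s) >= 0 for s in symbols)
        except ConstraintError:
            return False


DEFAULT_COSTS = CostTable()


# ---------------------------------------------------------------------------
# helpers shared by atoms
# ---------------------------------------------------------------------------

def _item_tokens(item) -> set[str]:
    """String tokens an item answers to in set-relation operands."""
    kind = item[0]
    if kind == "v":
        _, col, sym = item
        return {f"{col}.{sym}", str(sym)}
    if kind == "t":
        return {f"T:{item[1]}", item[1]}
    return {str(item[1])}


def _pattern_tokens(fp: FullPattern) -> set[str]:
    if fp.kind == "sequence":
        out: set[str] = set()
        for elem in fp.sequence:
            out.update(elem)
        return out
    tokens: set[str] = set()
    for item in fp.items:
        tokens |= _item_tokens(item)
    return tokens


def _value_costs(fp: FullPattern, costs: CostTable,
                 column_values: Mapping[str, float] | None = None) -> list[float]:
    """Costs entering aggregates: value items only, annotations excluded.

    Sequential patterns have no symbols of their own; aggregates then use the
    per-column values supplied by the caller (median of supporting rows).
    """
    if fp.kind == "sequence":
        if column_values is None:
            raise ConstraintError(
                "aggregate constraints on sequential patterns need column values"
            )
        return [float(column_values[c]) for c in fp.columns]
    vals = []
    for item in fp.items:
        if is_annotation(item):
            continue
        vals.append(costs.cost(item_symbol(item)))
    return vals


# ---------------------------------------------------------------------------
# atoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregateAtom:
    agg: str
    target: str
    cmp: str
    threshold: float

    def __str__(self) -> str:
        return f"{self.agg}({self.target}) {self.cmp} {self.threshold:g}"

    def _aggregate(self, fp: FullPattern, costs: CostTable,
                   column_values=None) -> float:
        if self.agg == "length":
            if self.target == "rows":
                return float(fp.support)
            if self.target == "cols":
                return float(len(fp.columns))
            return float(fp.length)
        vals = _value_costs(fp, costs, column_values)
        if not vals:
            raise ConstraintError("aggregate over empty value set")
        if self.agg == "min":
            return min(vals)
        if self.agg == "max":
            return max(vals)
        if self.agg == "range":
            return max(vals) - min(vals)
        if self.agg == "sum":
            return sum(vals)
        if self.agg == "avg":
            return sum(vals) / len(vals)
        if self.agg == "countVal":
            return float(len(set(vals)))
        raise ConstraintError(f"unknown aggregate {self.agg!r}")

    def evaluate(self, fp: FullPattern, costs: CostTable = DEFAULT_COSTS,
                 column_values=None) -> bool:
        x = self._aggregate(fp, costs, column_values)
        if self.cmp == "<=":
            return x <= self.threshold
        if self.cmp == ">=":
            return x >= self.threshold
        return x == self.threshold

    # -- pruning hooks ------------------------------------------------------

    def classify(self, nonneg_costs: bool = True) -> frozenset[str]:
        if self.target not in ("pattern", "items"):
            # aggregates over rows/cols act on coverage, which shrinks as
            # patterns grow: the pattern-space property table does not apply
            return frozenset()
        a, c = self.agg, self.cmp
        props: set[str] = set()
        if c == ">=":
            if a in ("range", "countVal", "length"):
                props.add("monotone")
            elif a == "max":
                props.update(("succinct", "monotone"))
            elif a == "min":
                props.add("anti_monotone")
            elif a == "sum" and nonneg_costs:
                props.add("monotone")
            elif a == "avg":
                props.add("convertible_am")
        elif c == "<=":
            if a in ("range", "countVal", "length"):
                props.add("anti_monotone")
            elif a == "max":
                props.add("anti_monotone")
            elif a == "min":
                props.update(("succinct", "monotone"))
            elif a == "sum" and nonneg_costs:
                props.add("anti_monotone")
            elif a == "avg":
                props.add("convertible_am")
        elif c == "=" and a in ("min", "max"):
            # membership-decidable: needs an item of cost v and no item
            # beyond it; pushable as pre-filtering
            props.add("succinct")
        return frozenset(props)

    def item_dooms(self, item, costs: CostTable) -> bool:
        """True when any pattern containing *item* must violate this atom
        (sound basis for alpha-reduction and header pruning)."""
        if self.target not in ("pattern", "items") or is_annotation(item):
            return False
        try:
            c = costs.cost(item_symbol(item))
        except ConstraintError:
            return False
        if self.agg == "max" and self.cmp in ("<=", "=") :
            return c > self.threshold
        if self.agg == "min" and self.cmp in (">=", "="):
            return c < self.threshold
        if self.agg == "sum" and self.cmp == "<=":
            # sound only under nonnegative costs; callers gate on that
            return c > self.threshold
        return False


@dataclass(frozen=True)
class SetAtom:
    target: str
    rel: str
    operand: frozenset  # string tokens

    def __str__(self) -> str:
        return f"{self.target} {self.rel} {{{','.join(sorted(self.operand))}}}"

    def _tokens(self, fp: FullPattern) -> set[str]:
        if self.target == "rows":
            return set(fp.coverage)
        if self.target == "cols":
            return set(fp.columns)
        return _pattern_tokens(fp)

    def evaluate(self, fp: FullPattern, costs: CostTable = DEFAULT_COSTS,
                 column_values=None) -> bool:
        toks = self._tokens(fp)
        if self.rel == "superset":
            return self.operand <= toks
        if self.rel == "contains":
            return bool(self.operand & toks)
        return not (self.operand & toks)  # excludes

    def classify(self, nonneg_costs: bool = True) -> frozenset[str]:
        if self.target == "rows":
            # coverage shrinks as patterns grow: containment requirements are
            # anti-monotone over pattern growth, exclusions monotone
            if self.rel in ("superset", "contains"):
                return frozenset({"anti_monotone"})
            return frozenset({"monotone"})
        if self.rel in ("superset", "contains"):
            return frozenset({"succinct", "monotone"})
        return frozenset({"succinct", "anti_monotone"})

    def item_dooms(self, item, costs: CostTable) -> bool:
        if self.rel != "excludes" or self.target == "rows":
            return False
        if self.target == "cols":
            return item[0] == "v" and item[1] in self.operand
        return bool(_item_tokens(item) & self.operand)

    def coverage_ok(self, tids: frozenset) -> bool:
        """Anti-monotone coverage check used inside the miners (rows target)."""
        if self.target != "rows":
            return True
        if self.rel == "superset":
            return self.operand <= tids
        if self.rel == "contains":
            return bool(self.operand & tids)
        return True  # excludes only improves as coverage shrinks


@dataclass(frozen=True)
class RegexAtom:
    """Shape constraint on sequential patterns.

    The pattern text chains elements with ``<`` (precedence); an element is a
    column id, ``*`` (any one column) or a parenthesised co-occurrence group.
    A sequential pattern satisfies the atom when its itemsets match the
    elements one-to-one, in order.
    """

    elements: tuple  # tuple of tuples of tokens; "*" is the wildcard

    def __str__(self) -> str:
        chain = " < ".join(
            e[0] if len(e) == 1 else "(" + " ".join(e) + ")" for e in self.elements
        )
        return f"regex({chain})"

    @staticmethod
    def _group_match(group: tuple, itemset: tuple, partial: bool) -> bool:
        """Can *itemset* be injectively matched into *group*'s slots?

        ``partial`` allows the itemset to fill only part of the group (the
        prefix may still grow by co-occurrence extension); a full match
        requires equal cardinality.
        """
        if partial:
            if len(itemset) > len(group):
                return False
        elif len(itemset) != len(group):
            return False
        slots = list(group)

        def assign(k: int, used: set[int]) -> bool:
            if k == len(itemset):
                return True
            tok = itemset[k]
            for s, slot in enumerate(slots):
                if s in used:
                    continue
                if slot == "*" or slot == tok:
                    if assign(k + 1, used | {s}):
                        return True
            return False

        return assign(0, set())

    def evaluate(self, fp: FullPattern, costs: CostTable = DEFAULT_COSTS,
                 column_values=None) -> bool:
        if fp.kind != "sequence":
            raise ConstraintError("regex constraints apply to sequential patterns")
        if len(fp.sequence) != len(self.elements):
            return False
        return all(
            self._group_match(g, s, partial=False)
            for g, s in zip(self.elements, fp.sequence)
        )

    def prefix_viable(self, prefix: Sequence[tuple]) -> bool:
        """False once the automaton is in a dead state: no extension of
        *prefix* can match the expression."""
        if len(prefix) > len(self.elements):
            return False
        for k, itemset in enumerate(prefix):
            last = k == len(prefix) - 1
            if not self._group_match(self.elements[k], tuple(itemset), partial=last):
                return False
        return True

    def classify(self, nonneg_costs: bool = True) -> frozenset[str]:
        return frozenset({"prefix_monotone"})

    def item_dooms(self, item, costs: CostTable) -> bool:
        return False


Atom = AggregateAtom | SetAtom | RegexAtom


# ---------------------------------------------------------------------------
# composite constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    """Disjunction of conjunctions of atoms (``and`` binds tighter)."""

    dnf: tuple[tuple[Atom, ...], ...]
    text: str = ""

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return tuple(a for conj in self.dnf for a in conj)

    @property
    def is_atomic(self) -> bool:
        return len(self.dnf) == 1 and len(self.dnf[0]) == 1

    def evaluate(self, fp: FullPattern, costs: CostTable = DEFAULT_COSTS,
                 column_values=None) -> bool:
        return any(
            all(a.evaluate(fp, costs, column_values) for a in conj)
            for conj in self.dnf
        )

    def classify(self, nonneg_costs: bool = True) -> frozenset[str]:
        """Properties of the composite.

        Conjunctions keep the union of their conjuncts' properties (each
        conjunct is pushed independently); a disjunction stays succinct only
        when every atom is succinct, otherwise it offers no pruning and is
        enforced by post-filtering.
        """
        if len(self.dnf) == 1:
            props: set[str] = set()
            for a in self.dnf[0]:
                props |= a.classify(nonneg_costs)
            return frozenset(props) if props else frozenset({"none"})
        all_props = [a.classify(nonneg_costs) for conj in self.dnf for a in conj]
        if all(("succinct" in p) for p in all_props):
            return frozenset({"succinct"})
        return frozenset({"none"})

    def pushable_conjuncts(self) -> tuple[Atom, ...]:
        """Atoms that may be pushed individually: only sound when the
        expression is a pure conjunction."""
        if len(self.dnf) == 1:
            return self.dnf[0]
        return ()


def evaluate(constraint: Constraint, fp: FullPattern,
             costs: CostTable = DEFAULT_COSTS, column_values=None) -> bool:
    return constraint.evaluate(fp, costs, column_values)


def classify(constraint: Constraint, nonneg_costs: bool = True) -> frozenset[str]:
    return constraint.classify(nonneg_costs)


# ---------------------------------------------------------------------------
# translation of pattern-space / column-space constraints to item space
# ---------------------------------------------------------------------------

def translate(constraint: Constraint, alphabet: Sequence, columns: Sequence[str]) -> Constraint:
    """Rewrite ``pattern``/``cols`` set atoms as item-space constraints.

    ``a in pattern`` becomes ``P ∩ {y1.a, ..., ym.a} != {}`` and ``y2 in cols``
    becomes ``P ∩ {y2.s : s in alphabet} != {}``; aggregate atoms over the
    pattern already act on the symbol part of items and pass through.
    """
    if not alphabet:
        raise ConstraintError("cannot translate against an empty alphabet")
    if not columns:
        raise ConstraintError("cannot translate against an empty column set")

    def translate_atom(a: Atom) -> Atom:
        if not isinstance(a, SetAtom):
            return a
        if a.target == "pattern":
            expanded = set()
            for tok in a.operand:
                if tok.startswith("T:"):
                    expanded.add(tok)
                else:
                    expanded.update(f"{y}.{tok}" for y in columns)
            return SetAtom("items", a.rel, frozenset(expanded))
        if a.target == "cols":
            expanded = set()
            for y in a.operand:
                expanded.update(f"{y}.{s}" for s in alphabet)
            return SetAtom("items", a.rel, frozenset(expanded))
        return a

    return Constraint(
        tuple(tuple(translate_atom(a) for a in conj) for conj in constraint.dnf),
        text=constraint.text,
    )


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<cmp><=|>=|=)|(?P<punct>[(){}<,])|(?P<word>[^\s(){}<,=]+))"
)


def _tokenize(text: str) -> list[str]:
    out = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            raise ConstraintError(f"syntax error at position {pos}: {text[pos:]!r}")
        out.append(m.group(m.lastgroup))
        pos = m.end()
    return out


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self) -> str | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def pop(self, expect: str | None = None) -> str:
        tok = self.peek()
        if tok is None:
            raise ConstraintError(f"unexpected end of constraint: {self.text!r}")
        if expect is not None and tok != expect:
            raise ConstraintError(
                f"expected {expect!r} but found {tok!r} in {self.text!r}"
            )
        self.i += 1
        return tok

    def parse(self) -> Constraint:
        dnf = [self._conj()]
        while self.peek() == "or":
            self.pop()
            dnf.append(self._conj())
        if self.peek() is not None:
            raise ConstraintError(f"trailing tokens from {self.peek()!r} in {self.text!r}")
        return Constraint(tuple(dnf), text=self.text)

    def _conj(self) -> tuple[Atom, ...]:
        atoms = [self._atom()]
        while self.peek() == "and":
            self.pop()
            atoms.append(self._atom())
        return tuple(atoms)

    def _atom(self) -> Atom:
        tok = self.pop()
        if tok == "regex":
            return self._regex()
        if tok in AGGS:
            self.pop("(")
            target = self.pop()
            if target not in TARGETS:
                raise ConstraintError(f"unknown target {target!r} in {self.text!r}")
            self.pop(")")
            cmp = self.pop()
            if cmp not in CMPS:
                raise ConstraintError(f"expected comparator, found {cmp!r}")
            num = self.pop()
            try:
                threshold = float(num)
            except ValueError as exc:
                raise ConstraintError(f"expected number, found {num!r}") from exc
            return AggregateAtom(tok, target, cmp, threshold)
        if tok in TARGETS:
            rel = self.pop()
            if rel not in RELS:
                raise ConstraintError(f"unknown relation {rel!r} in {self.text!r}")
            self.pop("{")
            ids = [self.pop()]
            while self.peek() == ",":
                self.pop()
                ids.append(self.pop())
            self.pop("}")
            return SetAtom(tok, rel, frozenset(ids))
        raise ConstraintError(f"unknown aggregate/target {tok!r} in {self.text!r}")

    def _regex(self) -> RegexAtom:
        self.pop("(")
        elements: list[tuple[str, ...]] = []
        while True:
            tok = self.pop()
            if tok == "(":
                group: list[str] = []
                while self.peek() != ")":
                    t = self.pop()
                    if t != ",":
                        group.append(t)
                self.pop(")")
                if not group:
                    raise ConstraintError("empty co-occurrence group in regex")
                elements.append(tuple(group))
            else:
                elements.append((tok,))
            nxt = self.peek()
            if nxt == "<":
                self.pop()
                continue
            self.pop(")")
            break
        return RegexAtom(tuple(elements))


def parse_constraint(text: str) -> Constraint:
    """Parse one constraint expression."""
    stripped = text.split("#", 1)[0].strip()
    if not stripped:
        raise ConstraintError("empty constraint expression")
    return _Parser(stripped).parse()


def parse_constraints(text: str) -> list[Constraint]:
    """Parse a constraints file: one expression per line, ``#`` comments."""
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        try:
            out.append(_Parser(stripped).parse())
        except ConstraintError as exc:
            raise ConstraintError(f"line {lineno}: {exc}") from exc
    return out
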