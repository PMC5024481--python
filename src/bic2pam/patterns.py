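"""Full-patterns: patterns carrying their supporting rows and columns.

A full-pattern is the unit both miners return: the pattern ``P`` in the
transactional database, its coverage ``Phi`` (supporting transaction ids),
the column indexes ``Psi`` it spans, and the original pattern ``Upsilon``
(symbols aligned to columns for itemsets; the ordering relation for
sequences).  Biclusters are read off directly: I = Phi, J = Psi.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FullPattern:
    """Pattern + coverage + columns + original pattern.

    For itemset patterns ``items`` holds the (col, symbol) items and
    ``symbols`` the symbol sequence aligned to sorted ``columns``.  For
    sequential patterns ``sequence`` holds the ordered tuple of co-occurrence
    itemsets (tuples of column tokens) and ``items`` is empty.
    """

    items: frozenset = frozenset()
    coverage: frozenset = frozenset()
    columns: tuple = ()
    symbols: tuple = ()
    sequence: tuple = ()
    kind: str = "itemset"  # "itemset" | "sequence"

    @property
    def support(self) -> int:
        return len(self.coverage)

    @property
    def length(self) -> int:
        if self.kind == "sequence":
            return sum(len(e) for e in self.sequence)
        return len(self.items)

    def __repr__(self) -> str:  # compact: for logs and debug dumps
        if self.kind == "sequence":
            pat = "<" + " ".join(
                e[0] if len(e) == 1 else "(" + " ".join(e) + ")" for e in self.sequence
            ) + ">"
        else:
            pat = "{" + ",".join(sorted(map(str, self.items))) + "}"
        return f"FullPattern({pat}, sup={self.support})"
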