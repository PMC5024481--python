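"""Core data model: matrices, networks, annotations, biclusters and solutions.

A :class:`NumericMatrix` holds a real-valued matrix ``A`` with named rows
(typically genes) and columns (conditions, or network nodes).  Missing cells
are first-class citizens, encoded as NaN: network adjacency matrices are
sparse and absent interactions must never be confused with zero-weight ones.

A :class:`Bicluster` is a pair ``(I, J)`` of row and column subsets together
with the pattern of expected values ``k_j`` (one per column), optional
per-row additive factors ``gamma_i``, optional signs ``c_i`` for symmetric
coherency, and the coherency assumption under which it was found.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("bic2pam")

#: tokens interpreted as missing cells when reading delimited matrices
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "null")

COHERENCIES = ("constant", "additive", "symmetric", "order-preserving")


class ParseError(ValueError):
    """Raised for malformed input files (position information in message)."""


@dataclass
class NumericMatrix:
    """Real-valued matrix with named rows/columns; NaN marks missing cells."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # shape (n_rows, n_cols), float, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        self._col_index = {c: j for j, c in enumerate(self.col_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def amplitude(self) -> float:
        """Amplitude ``A-bar = max - min`` over observed (non-missing) values."""
        obs = self.values[~np.isnan(self.values)]
        if obs.size == 0:
            return 0.0
        return float(obs.max() - obs.min())

    def row_index(self, row_id: str) -> int:
        return self._row_index[row_id]

    def col_index(self, col_id: str) -> int:
        return self._col_index[col_id]

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.values)))

    def copy(self) -> "NumericMatrix":
        return NumericMatrix(list(self.row_ids), list(self.col_ids), self.values.copy())


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ParseError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class Network:
    """Weighted network as an edge list; endpoints must be declared nodes."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    directed: bool = False

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for u, v, _ in self.edges:
            if u not in declared or v not in declared:
                raise ValueError(f"edge ({u}, {v}) references undeclared node")
            key = (u, v) if self.directed else (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"duplicate edge ({u}, {v})")
            seen.add(key)


@dataclass
class AnnotationMap:
    """Mapping row identifier -> set of annotation terms (opaque strings)."""

    entries: dict[str, set[str]]

    @property
    def term_universe(self) -> set[str]:
        out: set[str] = set()
        for terms in self.entries.values():
            out |= terms
        return out

    def bind(self, matrix: NumericMatrix) -> "AnnotationMap":
        """Restrict to rows present in *matrix*, warning on unknown ids."""
        known = set(matrix.row_ids)
        unknown = [r for r in self.entries if r not in known]
        if unknown:
            log.warning("annotations: skipped %d unknown row ids", len(unknown))
        return AnnotationMap({r: set(t) for r, t in self.entries.items() if r in known})


@dataclass
class Bicluster:
    """Submatrix (I, J) with its expected-value pattern and coherency tag.

    ``cols`` is an ordered tuple and ``pattern`` is aligned to it.  For
    order-preserving coherency the pattern is the column ordering itself,
    a tuple of tied groups (each a tuple of column ids), not values.
    """

    rows: frozenset[str]
    cols: tuple[str, ...]
    pattern: tuple
    coherency: str = "constant"
    row_factors: dict[str, float] = field(default_factory=dict)
    signs: dict[str, int] = field(default_factory=dict)
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.coherency not in COHERENCIES:
            raise ValueError(f"unknown coherency {self.coherency!r}")
        if len(self.rows) < 1 or len(self.cols) < 2:
            raise ValueError("bicluster needs >=1 row and >=2 columns")
        if self.coherency != "order-preserving" and len(self.pattern) != len(self.cols):
            raise ValueError("pattern length must equal number of columns")

    @property
    def col_set(self) -> frozenset[str]:
        return frozenset(self.cols)

    @property
    def n_cells(self) -> int:
        return len(self.rows) * len(self.cols)

    def key(self) -> tuple:
        return (self.rows, self.col_set)

    def to_dict(self) -> dict:
        return {
            "rows": sorted(self.rows),
            "cols": list(self.cols),
            "pattern": [list(p) if isinstance(p, tuple) else p for p in self.pattern],
            "coherency": self.coherency,
            "row_factors": {k: self.row_factors[k] for k in sorted(self.row_factors)},
            "signs": {k: self.signs[k] for k in sorted(self.signs)},
            "p_value": self.p_value,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Bicluster":
        pattern = tuple(tuple(p) if isinstance(p, list) else p for p in d["pattern"])
        return cls(
            rows=frozenset(d["rows"]),
            cols=tuple(d["cols"]),
            pattern=pattern,
            coherency=d.get("coherency", "constant"),
            row_factors=dict(d.get("row_factors") or {}),
            signs={k: int(v) for k, v in (d.get("signs") or {}).items()},
            p_value=d.get("p_value"),
        )


def cell_jaccard(a: Bicluster, b: Bicluster) -> float:
    """Jaccard similarity between the cell sets I x J of two biclusters."""
    ri = len(a.rows & b.rows)
    ci = len(a.col_set & b.col_set)
    inter = ri * ci
    union = a.n_cells + b.n_cells - inter
    return inter / union if union else 0.0


@dataclass
class BiclusteringSolution:
    """Ordered collection of biclusters plus run provenance and coverage."""

    biclusters: list[Bicluster]
    provenance: dict = field(default_factory=dict)
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.biclusters)

    def to_dict(self) -> dict:
        return {
            "biclusters": [b.to_dict() for b in self.biclusters],
            "params": self.provenance,
            "coverage": self.coverage,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BiclusteringSolution":
        return cls(
            biclusters=[Bicluster.from_dict(b) for b in d["biclusters"]],
            provenance=dict(d.get("params") or {}),
            coverage=float(d.get("coverage", 0.0)),
        )


def solution_coverage(solution_bics: Iterable[Bicluster], matrix: NumericMatrix) -> float:
    """Fraction of non-missing cells of *matrix* covered by >=1 bicluster."""
    covered: set[tuple[int, int]] = set()
    for b in solution_bics:
        ri = [matrix.row_index(r) for r in b.rows if r in matrix._row_index]
        ci = [matrix.col_index(c) for c in b.cols if c in matrix._col_index]
        for i in ri:
            for j in ci:
                if not np.isnan(matrix.values[i, j]):
                    covered.add((i, j))
    total = matrix.n_observed
    return len(covered) / total if total else 0.0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(
    path,
    sep: str = "\t",
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> NumericMatrix:
    """Read a delimited matrix: header row of column ids, first field row id."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    miss = set(missing_tokens)
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i, rid in enumerate(row_ids):
        for j, cid in enumerate(col_ids):
            tok = raw[i, j].strip()
            if tok in miss:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(tok)
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric cell at row {rid!r}, column {cid!r}: {tok!r}"
                ) from exc
    return NumericMatrix(row_ids, col_ids, values)


def write_matrix(m: NumericMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(m.values, index=m.row_ids, columns=m.col_ids)
    df.to_csv(path, sep=sep, na_rep="NA")


def read_network(path, sep: str = "\t", directed: bool = False) -> Network:
    """Read a 3-column edge list (node, node, weight)."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ParseError("network file needs 3 columns: node, node, weight")
    edges = []
    nodes: list[str] = []
    seen: set[str] = set()
    for k, (u, v, w) in enumerate(zip(df[0], df[1], df[2])):
        try:
            weight = float(w)
        except ValueError as exc:
            raise ParseError(f"non-numeric weight on line {k + 1}: {w!r}") from exc
        for node in (u, v):
            if node not in seen:
                seen.add(node)
                nodes.append(node)
        edges.append((u, v, weight))
    return Network(nodes, edges, directed=directed)


def network_to_matrix(net: Network) -> NumericMatrix:
    """Map a network onto a (sparse) adjacency matrix.

    Absent edges become missing cells, not zeros: a zero would fabricate an
    interaction of zero strength.  Undirected networks give a symmetric
    matrix over the full node set with a missing diagonal.
    """
    if not net.edges:
        raise ValueError("cannot map an empty edge set")
    nodes = list(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    values = np.full((len(nodes), len(nodes)), np.nan)
    for u, v, w in net.edges:
        values[idx[u], idx[v]] = w
        if not net.directed:
            values[idx[v], idx[u]] = w
    return NumericMatrix(nodes, [str(n) for n in nodes], values)


def read_annotations(path, sep: str = "\t") -> AnnotationMap:
    """Read ``row_id<TAB>term[,term...]`` lines; empty term lists allowed."""
    entries: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(sep)
            rid = parts[0].strip()
            if not rid:
                raise ParseError(f"annotations line {lineno}: empty row id")
            terms = set()
            if len(parts) > 1 and parts[1].strip():
                terms = {t.strip() for t in parts[1].split(",") if t.strip()}
            entries.setdefault(rid, set()).update(terms)
    return AnnotationMap(entries)


def write_annotations(ann: AnnotationMap, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for rid in sorted(ann.entries):
            fh.write(f"{rid}{sep}{','.join(sorted(ann.entries[rid]))}\n")


def write_solution(solution: BiclusteringSolution, path) -> None:
    with open(path, "w") as fh:
        json.dump(solution.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_solution(path) -> BiclusteringSolution:
    with open(path) as fh:
        return BiclusteringSolution.from_dict(json.load(fh))
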