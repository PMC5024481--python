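"""Normalization, discretization and mapping into transactional databases.

Pattern-based biclustering turns a real-valued matrix into a symbolic one
and then into a transactional database: one transaction per row, whose items
concatenate the column id with the cell's symbol (``y1.-2`` style).  Biclusters
with constant coherency are the frequent closed itemsets of that database;
additive and symmetric coherencies are reduced to the constant case by row
alignment and row mirroring; order-preserving biclusters come from sequences
of column indexes ordered by value.

Two robustness devices from this family of methods live here:

* *multi-item assignment* — a cell close to a discretization cutpoint also
  receives the adjacent bin's symbol, so borderline values do not break
  otherwise coherent patterns;
* *uninformative-symbol removal* — a succinct constraint stating symbols of
  no interest (e.g. non-differential expression) deletes their items before
  mining.

Items are tuples: ``("v", col_id, symbol)`` for value items, ``("t", term)``
for annotation items, ``("r", name)`` for raw items (used by the debug
pattern-mining surface where transactions are given directly).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data import AnnotationMap, NumericMatrix

log = logging.getLogger("bic2pam")

Item = tuple  # ("v", col, sym) | ("t", term) | ("r", name)


def value_item(col: str, sym: int) -> Item:
    return ("v", col, int(sym))


def ann_item(term: str) -> Item:
    return ("t", term)


def raw_item(name: str) -> Item:
    return ("r", name)


def item_symbol(item: Item):
    """Symbol part used by cost tables: the integer symbol for value items,
    the name for raw items, ``None`` for annotation items (no cost)."""
    kind = item[0]
    if kind == "v":
        return item[2]
    if kind == "r":
        return item[1]
    return None


def item_column(item: Item) -> str | None:
    return item[1] if item[0] == "v" else None


def is_annotation(item: Item) -> bool:
    return item[0] == "t"


def format_item(item: Item) -> str:
    if item[0] == "v":
        return f"{item[1]}.{item[2]}"
    if item[0] == "t":
        return f"T:{item[1]}"
    return str(item[1])


def make_alphabet(n_items: int) -> list[int]:
    """Integer alphabet; centered at 0 when odd (e.g. {-2,-1,0,1,2})."""
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if n_items % 2:
        h = n_items // 2
        return list(range(-h, h + 1))
    h = n_items // 2
    return [*range(-h, 0), *range(1, h + 1)]


# ---------------------------------------------------------------------------
# normalization and discretization
# ---------------------------------------------------------------------------

def normalize_rows(m: NumericMatrix) -> NumericMatrix:
    """Zero-mean row-oriented normalization; missing cells untouched."""
    values = m.values.copy()
    for i, rid in enumerate(m.row_ids):
        row = values[i]
        obs = ~np.isnan(row)
        if not obs.any():
            raise ValueError(f"row {rid!r} has no observed values")
        values[i, obs] = row[obs] - row[obs].mean()
    return NumericMatrix(list(m.row_ids), list(m.col_ids), values)


@dataclass
class DiscretizationModel:
    """Cutpoints mapping reals to an ordered integer alphabet.

    ``coherency_strength`` is delta = amplitude / |alphabet|: the wider the
    alphabet, the finer the allowed deviation within a symbol.
    """

    alphabet: list[int]
    cutpoints: np.ndarray  # strictly increasing, len == n_items - 1
    amplitude: float
    method: str = "gaussian_quantile"
    multi_item_fraction: float = 0.1  # alpha in [0, 0.5)

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if len(self.cutpoints) != len(self.alphabet) - 1:
            raise ValueError("need |alphabet| - 1 cutpoints")
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        if not 0.0 <= self.multi_item_fraction < 0.5:
            raise ValueError("multi_item_fraction must lie in [0, 0.5)")

    @property
    def n_items(self) -> int:
        return len(self.alphabet)

    @property
    def coherency_strength(self) -> float:
        return self.amplitude / self.n_items

    def _cutpoint_tolerances(self) -> np.ndarray:
        """Per-cutpoint half-width of the multi-item boundary band."""
        alpha = self.multi_item_fraction
        cuts = self.cutpoints
        widths = np.diff(cuts)  # widths of interior bins
        tol = np.empty(len(cuts))
        fallback = (self.amplitude / self.n_items) if self.amplitude > 0 else 1.0
        for k in range(len(cuts)):
            cands = []
            if k >= 1:
                cands.append(widths[k - 1])  # bin below is interior
            if k < len(widths):
                cands.append(widths[k])
            tol[k] = alpha * (min(cands) if cands else fallback)
        return tol

    def assign(self, value: float) -> list[int]:
        """Symbols for one value; first entry is the primary bin's symbol."""
        cuts = self.cutpoints
        k = int(np.searchsorted(cuts, value, side="right"))
        out = [self.alphabet[k]]
        if self.multi_item_fraction > 0:
            tol = self._cutpoint_tolerances()
            if k >= 1 and value - cuts[k - 1] <= tol[k - 1]:
                out.append(self.alphabet[k - 1])
            if k < len(cuts) and cuts[k] - value <= tol[k]:
                out.append(self.alphabet[k + 1])
        return out


def fit_discretization(
    m: NumericMatrix,
    n_items: int,
    method: str = "gaussian_quantile",
    multi_item_fraction: float = 0.1,
) -> DiscretizationModel:
    """Fit cutpoints on all observed values of *m*.

    ``gaussian_quantile`` places the cutpoints at the Normal(mu, sigma)
    quantiles k/n_items for the fitted overall distribution; ``equal_width``
    splits [min, max] evenly.  Zero variance falls back to equal width.
    """
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    obs = m.values[~np.isnan(m.values)]
    if obs.size == 0:
        raise ValueError("matrix has no observed values")
    alphabet = make_alphabet(n_items)
    if method == "gaussian_quantile":
        mu, sigma = float(obs.mean()), float(obs.std())
        if sigma <= 0:
            log.warning("zero variance: falling back to equal_width discretization")
            method = "equal_width"
        else:
            qs = np.arange(1, n_items) / n_items
            cuts = stats.norm.ppf(qs, loc=mu, scale=sigma)
            return DiscretizationModel(alphabet, cuts, m.amplitude,
                                       "gaussian_quantile", multi_item_fraction)
    if method != "equal_width":
        raise ValueError(f"unknown discretization method {method!r}")
    lo, hi = float(obs.min()), float(obs.max())
    if hi <= lo:
        lo, hi = lo - 0.5, lo + 0.5
    cuts = np.linspace(lo, hi, n_items + 1)[1:-1]
    return DiscretizationModel(alphabet, cuts, m.amplitude,
                               "equal_width", multi_item_fraction)


@dataclass
class SymbolicMatrix:
    """Discretized matrix: primary symbol per cell plus multi-item extras."""

    row_ids: list[str]
    col_ids: list[str]
    primary: np.ndarray  # float array, NaN = missing, else integer symbol
    multi: dict[tuple[int, int], int]  # (i, j) -> secondary symbol
    model: DiscretizationModel

    def symbols_at(self, i: int, j: int) -> list[int]:
        if np.isnan(self.primary[i, j]):
            return []
        out = [int(self.primary[i, j])]
        if (i, j) in self.multi:
            out.append(self.multi[(i, j)])
        return out

    def column_symbol_frequency(self, j: int, sym: int) -> float:
        """Empirical frequency of *sym* among observed cells of column *j*,
        counting multi-item assignments."""
        col = self.primary[:, j]
        obs = ~np.isnan(col)
        n = int(obs.sum())
        if n == 0:
            return 0.0
        hits = int((col[obs] == sym).sum())
        hits += sum(
            1 for (i, jj), s in self.multi.items() if jj == j and s == sym and obs[i]
        )
        return min(1.0, hits / n)


def discretize(m: NumericMatrix, model: DiscretizationModel) -> SymbolicMatrix:
    """Assign each observed cell its bin symbol, plus the adjacent bin's
    symbol when within ``alpha * bin_width`` of a cutpoint."""
    primary = np.full(m.shape, np.nan)
    multi: dict[tuple[int, int], int] = {}
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            v = m.values[i, j]
            if np.isnan(v):
                continue
            syms = model.assign(v)
            primary[i, j] = syms[0]
            if len(syms) > 1:
                multi[(i, j)] = syms[1]
    return SymbolicMatrix(list(m.row_ids), list(m.col_ids), primary, multi, model)


# ---------------------------------------------------------------------------
# transactional databases
# ---------------------------------------------------------------------------

MIRROR_PREFIX = "~"


@dataclass
class ItemsetDatabase:
    """Transactions (row id -> item set) plus mapping metadata.

    ``row_factors`` holds the additive adjustment gamma_i subtracted from each
    row (additive coherency); ``mirror_of`` maps mirrored transaction ids
    (symmetric coherency) back to their source row.
    """

    transactions: dict[str, frozenset]
    coherency: str = "constant"
    row_factors: dict[str, int] = field(default_factory=dict)
    mirror_of: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.transactions)

    @property
    def item_universe(self) -> set:
        out: set = set()
        for t in self.transactions.values():
            out |= t
        return out

    def copy(self) -> "ItemsetDatabase":
        return ItemsetDatabase(
            dict(self.transactions), self.coherency,
            dict(self.row_factors), dict(self.mirror_of),
        )


def align_additive_row(symbols: Sequence[int]) -> tuple[list[int], int]:
    """Anchor a row's symbols at zero minimum; return (pattern, gamma).

    A row (1, 3, 2) becomes pattern (0, 2, 1) with gamma = 1: under coherency
    across rows a_ij = k_j + gamma_i, the subtracted minimum is the row's
    additive adjustment.
    """
    gamma = min(symbols)
    return [s - gamma for s in symbols], gamma


def to_itemset_db(sym: SymbolicMatrix, coherency: str = "constant") -> ItemsetDatabase:
    """Map a symbolic matrix to an itemset database under a coherency.

    constant  -- item ``(col, symbol)`` per (cell, symbol);
    additive  -- each row anchored at zero-minimum symbol, gamma_i recorded;
    symmetric -- every row emitted twice, the mirror with negated symbols.
    """
    if coherency not in ("constant", "additive", "symmetric"):
        raise ValueError(f"unsupported coherency for itemset mapping: {coherency!r}")
    transactions: dict[str, frozenset] = {}
    row_factors: dict[str, int] = {}
    mirror_of: dict[str, str] = {}
    for i, rid in enumerate(sym.row_ids):
        cells: list[tuple[str, int, bool]] = []  # (col, symbol, is_primary)
        prim: list[int] = []
        for j, cid in enumerate(sym.col_ids):
            syms = sym.symbols_at(i, j)
            if not syms:
                continue
            prim.append(syms[0])
            cells.append((cid, syms[0], True))
            for s in syms[1:]:
                cells.append((cid, s, False))
        if not cells:
            continue
        if coherency == "additive":
            _, gamma = align_additive_row(prim)
            row_factors[rid] = gamma
            cells = [(c, s - gamma, p) for c, s, p in cells]
        transactions[rid] = frozenset(value_item(c, s) for c, s, _ in cells)
        if coherency == "symmetric":
            mid = MIRROR_PREFIX + rid
            transactions[mid] = frozenset(value_item(c, -s) for c, s, _ in cells)
            mirror_of[mid] = rid
    return ItemsetDatabase(transactions, coherency, row_factors, mirror_of)


@dataclass
class SequenceDatabase:
    """Row id -> ordered tuple of index-itemsets (columns tied in value).

    Elements are tuples of tokens sorted lexicographically; tokens are column
    ids, or ``T:term`` strings for appended annotations.
    """

    sequences: dict[str, tuple[tuple[str, ...], ...]]

    def __len__(self) -> int:
        return len(self.sequences)


def to_sequence_db(m: NumericMatrix, n_items: int | None = None) -> SequenceDatabase:
    """Order each row's columns ascending by value; ties share one itemset.

    With ``n_items`` set, values are first discretized (overall Gaussian
    model) and ties are decided on symbols — the coarser the alphabet, the
    more co-occurrences; ``None`` ties on exact value equality.
    """
    sym_lookup = None
    if n_items is not None:
        model = fit_discretization(m, n_items)
        symm = discretize(m, model)
        sym_lookup = symm.primary
    sequences: dict[str, tuple] = {}
    for i, rid in enumerate(m.row_ids):
        keyed = []
        for j, cid in enumerate(m.col_ids):
            v = m.values[i, j]
            if np.isnan(v):
                continue
            key = sym_lookup[i, j] if sym_lookup is not None else v
            keyed.append((key, cid))
        if len(keyed) < 2:
            continue
        keyed.sort(key=lambda kv: (kv[0], kv[1]))
        groups: list[list[str]] = []
        last_key = None
        for key, cid in keyed:
            if last_key is None or key != last_key:
                groups.append([])
                last_key = key
            groups[-1].append(cid)
        sequences[rid] = tuple(tuple(sorted(g)) for g in groups)
    return SequenceDatabase(sequences)


# ---------------------------------------------------------------------------
# annotations and uninformative symbols
# ---------------------------------------------------------------------------

def append_annotations(db, ann: AnnotationMap):
    """Append one annotation item per term to each row's transaction.

    Itemset databases gain ``("t", term)`` items; sequence databases gain one
    trailing itemset of ``T:term`` tokens.  Rows absent from *ann* are left
    unchanged; transactions gain variable length.
    """
    if isinstance(db, ItemsetDatabase):
        out = db.copy()
        for tid, items in out.transactions.items():
            rid = out.mirror_of.get(tid, tid)
            terms = ann.entries.get(rid)
            if terms:
                out.transactions[tid] = items | {ann_item(t) for t in terms}
        return out
    if isinstance(db, SequenceDatabase):
        seqs = dict(db.sequences)
        for rid, seq in seqs.items():
            terms = ann.entries.get(rid)
            if terms:
                seqs[rid] = seq + (tuple(sorted(f"T:{t}" for t in terms)),)
        return SequenceDatabase(seqs)
    raise TypeError(f"unsupported database type {type(db).__name__}")


def remove_uninformative(db: ItemsetDatabase, symbols: Iterable[int]) -> ItemsetDatabase:
    """Delete all items whose symbol part is in *symbols*; drop emptied rows."""
    removed = set(symbols)
    out_trans: dict[str, frozenset] = {}
    n_items_removed = 0
    n_trans_dropped = 0
    for tid, items in db.transactions.items():
        kept = frozenset(i for i in items if item_symbol(i) not in removed)
        n_items_removed += len(items) - len(kept)
        if kept:
            out_trans[tid] = kept
        else:
            n_trans_dropped += 1
    if n_items_removed or n_trans_dropped:
        log.info("uninformative removal: %d items, %d transactions dropped",
                 n_items_removed, n_trans_dropped)
    return ItemsetDatabase(out_trans, db.coherency, dict(db.row_factors),
                           {m: s for m, s in db.mirror_of.items() if m in out_trans})
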