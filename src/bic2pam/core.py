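"""Pipeline orchestration: preprocess, constrain, mine, postprocess.

The run proceeds in four stages: (1) the input matrix (or network mapped to
a sparse adjacency matrix) is normalized and discretized into transactional
databases; (2) constraints are parsed, checked for soundness against the
preprocessed databases and translated to item space; (3) the constrained
miners are applied with a support threshold that starts high and decreases
by a relative step per round, until the solution reaches a target number of
dissimilar biclusters or a target coverage of matrix cells; (4) the pooled
patterns are mapped to biclusters and postprocessed — significance
filtering, extension, reduction, merging and overlap filtering.

Statistical significance uses a column-independence null: the probability
that a random row matches the pattern is the product of the pattern's
per-column symbol frequencies (for order-preserving patterns, the ordering
probability 1/|J|! under no ties), and the p-value is the upper binomial
tail P(Bin(n, p_phi) >= |I|), Bonferroni-corrected across the tested
patterns.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from . import constraints as C
from .data import (
    AnnotationMap,
    Bicluster,
    BiclusteringSolution,
    NumericMatrix,
    Network,
    cell_jaccard,
    network_to_matrix,
    solution_coverage,
)
from .itemset_mining import MinerParams, MinerStats, mine_closed
from .patterns import FullPattern
from .preprocess import (
    MIRROR_PREFIX,
    ItemsetDatabase,
    SequenceDatabase,
    SymbolicMatrix,
    ann_item,
    append_annotations,
    discretize,
    fit_discretization,
    is_annotation,
    item_column,
    item_symbol,
    normalize_rows,
    remove_uninformative,
    to_itemset_db,
    to_sequence_db,
    value_item,
)
from .sequence_mining import (
    SeqConstraintSet,
    SeqMinerStats,
    mine_sequential_closed,
    seq_contains,
)

log = logging.getLogger("bic2pam")

ITEMSET_COHERENCIES = ("constant", "additive", "symmetric")


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the method's standard setting.

    The support threshold starts at ``theta_start`` and is multiplied by
    ``1 - theta_step`` each round (a relative decrease, so the loop never
    crosses zero), flooring at ``min_rows`` supporting rows.  The loop stops
    at ``stop_biclusters`` dissimilar significant biclusters or coverage
    ``stop_coverage`` of observed cells.  ``max_round_patterns`` is a
    saturation guard: a mining round emitting more candidates than this is
    truncated and ends the loop for that alphabet.
    """

    coherency: str = "constant"  # one of COHERENCIES or "all"
    n_items: tuple[int, ...] | None = None  # default sweep {3,5,7}
    discretization: str = "gaussian_quantile"
    multi_item_fraction: float = 0.1
    normalize: bool = True
    theta_start: float = 0.80
    theta_step: float = 0.10
    min_cols: int = 3  # patterns on fewer columns are trivial in wide matrices
    min_rows: int = 2
    stop_biclusters: int = 50
    stop_coverage: float = 0.10
    merge_overlap: float = 0.70
    filter_overlap: float = 0.60
    significance_alpha: float = 0.01
    noise_tolerance: float = 0.2
    tau: int = 1
    max_round_patterns: int = 5000
    removed_symbols: tuple = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta_step < self.theta_start <= 1:
            raise ValueError("need 0 < theta_step < theta_start <= 1")
        for name in ("stop_coverage", "merge_overlap", "filter_overlap"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 < self.significance_alpha < 1:
            raise ValueError("significance_alpha must lie in (0, 1)")
        if not 0 <= self.noise_tolerance <= 1:
            raise ValueError("noise_tolerance must lie in [0, 1]")

    def alphabets(self) -> tuple[int, ...]:
        return self.n_items if self.n_items else (3, 5, 7)

    def coherencies(self) -> tuple[str, ...]:
        if self.coherency == "all":
            return ("constant", "additive", "symmetric", "order-preserving")
        return (self.coherency,)


@dataclass
class RunReport:
    """Run audit: timings, pruning counters and constraint satisfaction."""

    stage_seconds: dict[str, float] = field(default_factory=dict)
    visited_nodes: int = 0
    projections: int = 0
    mu_removed: int = 0
    alpha_removed: int = 0
    rounds: int = 0
    patterns_mined: int = 0
    saturated: bool = False
    constraint_audit: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
            "visited_nodes": self.visited_nodes,
            "projections": self.projections,
            "mu_removed": self.mu_removed,
            "alpha_removed": self.alpha_removed,
            "rounds": self.rounds,
            "patterns_mined": self.patterns_mined,
            "saturated": self.saturated,
            "constraint_audit": self.constraint_audit,
        }


# ---------------------------------------------------------------------------
# pattern -> bicluster mapping
# ---------------------------------------------------------------------------

def pattern_to_bicluster(
    fp: FullPattern,
    coherency: str = "constant",
    row_factors: Mapping[str, int] | None = None,
) -> Bicluster | None:
    """Map a full-pattern to a bicluster: I = coverage, J = columns,
    pattern = original symbols (or the ordering, for sequences).

    Mirrored transaction ids (symmetric coherency) fold back to their source
    rows, keeping the first-seen orientation; annotation items are dropped
    from the pattern.  Returns None for patterns spanning fewer than two
    columns (annotation-only patterns cannot form a bicluster).
    """
    if len(fp.columns) < 2:
        return None
    rows: dict[str, int] = {}
    for tid in sorted(fp.coverage, key=lambda t: (t.startswith(MIRROR_PREFIX), t)):
        if tid.startswith(MIRROR_PREFIX):
            rows.setdefault(tid[len(MIRROR_PREFIX):], -1)
        else:
            rows.setdefault(tid, 1)
    signs = {r: s for r, s in rows.items() if coherency == "symmetric"}
    factors = {}
    if coherency == "additive" and row_factors:
        factors = {r: row_factors[r] for r in rows if r in row_factors}
    pattern = fp.sequence if fp.kind == "sequence" else fp.symbols
    return Bicluster(
        rows=frozenset(rows),
        cols=tuple(fp.columns),
        pattern=tuple(pattern),
        coherency=coherency if fp.kind != "sequence" else "order-preserving",
        row_factors=factors,
        signs=signs,
    )


def bicluster_to_fullpattern(
    bic: Bicluster, annotations: AnnotationMap | None = None
) -> FullPattern:
    """Rebuild a full-pattern view for post-hoc constraint auditing.

    Annotation items shared by *all* member rows are re-attached, so a
    succinct annotation-containment constraint holds for the bicluster
    exactly when every row carries the term.
    """
    if bic.coherency == "order-preserving":
        return FullPattern(coverage=bic.rows, columns=tuple(sorted(bic.cols)),
                           sequence=tuple(bic.pattern), kind="sequence")
    items = {value_item(c, s) for c, s in zip(bic.cols, bic.pattern)}
    if annotations is not None and bic.rows:
        shared: set[str] | None = None
        for r in bic.rows:
            terms = annotations.entries.get(r, set())
            shared = set(terms) if shared is None else shared & terms
        items |= {ann_item(t) for t in (shared or ())}
    cols = tuple(sorted(bic.cols))
    sym = dict(zip(bic.cols, bic.pattern))
    return FullPattern(items=frozenset(items), coverage=bic.rows, columns=cols,
                       symbols=tuple(sym[c] for c in cols), kind="itemset")


# ---------------------------------------------------------------------------
# postprocessing: significance, extension, reduction, merging, filtering
# ---------------------------------------------------------------------------

def significance(bic: Bicluster, sym: SymbolicMatrix) -> float:
    """Upper binomial-tail p-value of observing >= |I| pattern-matching rows.

    p_phi is the product of per-column empirical symbol frequencies (the
    ordering probability 1/|J|! for order-preserving patterns); the null is
    column independence.  Uncorrected; callers apply Bonferroni.
    """
    n = len(sym.row_ids)
    if bic.coherency == "order-preserving":
        p_phi = 1.0 / math.factorial(len(bic.cols))
    else:
        p_phi = 1.0
        for cid, s in zip(bic.cols, bic.pattern):
            j = sym.col_ids.index(cid)
            p_phi *= sym.column_symbol_frequency(j, int(s))
    return float(sps.binom.sf(len(bic.rows) - 1, n, p_phi))


def _db_item_frequencies(db: ItemsetDatabase) -> dict:
    freq: dict = {}
    n = max(1, len(db.transactions))
    for items in db.transactions.values():
        for it in items:
            freq[it] = freq.get(it, 0) + 1
    return {it: c / n for it, c in freq.items()}


def _significance_from_db(fp: FullPattern, db_freq: Mapping, n: int) -> float:
    if fp.kind == "sequence":
        p_phi = 1.0 / math.factorial(max(1, len(fp.columns)))
    else:
        p_phi = 1.0
        for it in fp.items:
            if is_annotation(it):
                continue
            p_phi *= db_freq.get(it, 0.0)
    return float(sps.binom.sf(fp.support - 1, n, min(1.0, p_phi)))


def _row_match_fraction(values: np.ndarray, centers: np.ndarray, delta: float) -> np.ndarray:
    """Per-row fraction of pattern columns within delta/2 of the expected
    value; missing cells count as mismatches."""
    diff = np.abs(values - centers[None, :])
    ok = np.where(np.isnan(diff), False, diff <= delta / 2 + 1e-12)
    return ok.sum(axis=1) / centers.size


def _expected_values(matrix: NumericMatrix, bic: Bicluster) -> np.ndarray:
    ridx = [matrix.row_index(r) for r in bic.rows]
    cidx = [matrix.col_index(c) for c in bic.cols]
    sub = matrix.values[np.ix_(ridx, cidx)]
    return np.nanmedian(sub, axis=0)


def _aligned_values(matrix: NumericMatrix, bic: Bicluster,
                    centers: np.ndarray) -> np.ndarray:
    """Row values aligned for the bicluster's coherency: additive rows are
    shifted by their median offset from the pattern, symmetric rows by the
    better-fitting sign."""
    cidx = [matrix.col_index(c) for c in bic.cols]
    vals = matrix.values[:, cidx].copy()
    if bic.coherency == "additive":
        off = np.nanmedian(vals - centers[None, :], axis=1)
        vals = vals - off[:, None]
    elif bic.coherency == "symmetric":
        pos = np.nansum(np.abs(vals - centers[None, :]), axis=1)
        neg = np.nansum(np.abs(-vals - centers[None, :]), axis=1)
        flip = neg < pos
        vals[flip] = -vals[flip]
    return vals


def extend(
    bic: Bicluster,
    matrix: NumericMatrix,
    noise_tolerance: float,
    delta: float,
    sym: SymbolicMatrix | None = None,
    max_passes: int = 5,
) -> Bicluster:
    """Add rows (then columns) matching the pattern in >= (1 - tolerance)
    of positions; a position matches when the cell lies within delta/2 of
    the pattern's expected value (the coherency-strength band).  Row and
    column passes alternate until a fixpoint (bounded by *max_passes*).
    """
    if bic.coherency == "order-preserving":
        return bic  # ordering extension handled by pattern support directly
    need = 1.0 - noise_tolerance - 1e-12
    out = bic
    for _ in range(max_passes):
        centers = _expected_values(matrix, out)
        vals = _aligned_values(matrix, out, centers)
        frac = _row_match_fraction(vals, centers, delta)
        rows = set(out.rows)
        for i, rid in enumerate(matrix.row_ids):
            if frac[i] >= need:
                rows.add(rid)
        grown = Bicluster(frozenset(rows), out.cols, out.pattern, out.coherency,
                          dict(out.row_factors), dict(out.signs), out.p_value)
        # column pass against the enlarged row set
        ridx = [matrix.row_index(r) for r in grown.rows]
        off = np.zeros(len(ridx))
        if grown.coherency == "additive":
            cidx = [matrix.col_index(c) for c in grown.cols]
            off = np.nanmedian(
                matrix.values[np.ix_(ridx, cidx)] - centers[None, :], axis=1
            )
        new_cols = list(grown.cols)
        new_pattern = list(grown.pattern)
        for j, cid in enumerate(matrix.col_ids):
            if cid in grown.cols:
                continue
            col = matrix.values[ridx, j] - off
            center = np.nanmedian(col)
            if np.isnan(center):
                continue
            okf = np.mean(np.where(np.isnan(col), False,
                                   np.abs(col - center) <= delta / 2))
            if okf >= need:
                new_cols.append(cid)
                new_pattern.append(_modal_symbol(sym, grown.rows, cid) if sym
                                   else int(round(center / max(delta, 1e-12))))
        if len(new_cols) > len(grown.cols):
            grown = Bicluster(grown.rows, tuple(new_cols), tuple(new_pattern),
                              grown.coherency, grown.row_factors, grown.signs,
                              grown.p_value)
        if grown.rows == out.rows and grown.cols == out.cols:
            return grown
        out = grown
    return out


def reduce_bicluster(
    bic: Bicluster,
    matrix: NumericMatrix,
    noise_tolerance: float,
    delta: float,
) -> Bicluster | None:
    """Drop rows, then columns, matching in < (1 - tolerance) of positions;
    None when fewer than one row or two columns survive."""
    if bic.coherency == "order-preserving":
        return bic
    centers = _expected_values(matrix, bic)
    vals = _aligned_values(matrix, bic, centers)
    frac = _row_match_fraction(vals, centers, delta)
    need = 1.0 - noise_tolerance - 1e-12
    rows = {r for r in bic.rows if frac[matrix.row_index(r)] >= need}
    if not rows:
        return None
    ridx = [matrix.row_index(r) for r in rows]
    keep_cols, keep_pattern = [], []
    for k, cid in enumerate(bic.cols):
        colvals = vals[ridx, k]
        okf = np.mean(np.where(np.isnan(colvals), False,
                               np.abs(colvals - centers[k]) <= delta / 2 + 1e-12))
        if okf >= need:
            keep_cols.append(cid)
            keep_pattern.append(bic.pattern[k])
    if len(keep_cols) < 2:
        return None
    return Bicluster(frozenset(rows), tuple(keep_cols), tuple(keep_pattern),
                     bic.coherency, {r: g for r, g in bic.row_factors.items() if r in rows},
                     {r: s for r, s in bic.signs.items() if r in rows}, bic.p_value)


def _modal_symbol(sym: SymbolicMatrix, rows: Iterable[str], cid: str) -> int:
    j = sym.col_ids.index(cid)
    counts: dict[int, int] = {}
    for rid in rows:
        i = sym.row_ids.index(rid)
        for s in sym.symbols_at(i, j):
            counts[s] = counts.get(s, 0) + 1
    if not counts:
        return 0
    best = max(counts.values())
    # ties break toward the symbol nearest zero, for determinism
    return min((s for s, c in counts.items() if c == best), key=lambda s: (abs(s), s))


def merge(
    biclusters: Sequence[Bicluster],
    overlap: float,
    sym: SymbolicMatrix | None = None,
) -> list[Bicluster]:
    """Merge pairs with cell-set Jaccard above *overlap*, to a fixpoint.

    The merged pattern is recomputed as the per-column modal symbol over the
    merged rows (requires the symbolic matrix; otherwise the larger input's
    pattern wins for shared columns).
    """
    bics = list(biclusters)
    changed = True
    while changed:
        changed = False
        out: list[Bicluster] = []
        used = [False] * len(bics)
        for a in range(len(bics)):
            if used[a]:
                continue
            cur = bics[a]
            for b in range(a + 1, len(bics)):
                if used[b]:
                    continue
                if cur.coherency != bics[b].coherency:
                    continue
                if cell_jaccard(cur, bics[b]) > overlap:
                    cur = _merge_pair(cur, bics[b], sym)
                    used[b] = True
                    changed = True
            used[a] = True
            out.append(cur)
        bics = out
    return bics


def _merge_pair(a: Bicluster, b: Bicluster, sym: SymbolicMatrix | None) -> Bicluster:
    rows = a.rows | b.rows
    cols = list(a.cols) + [c for c in b.cols if c not in a.col_set]
    if a.coherency == "order-preserving":
        base = a if a.n_cells >= b.n_cells else b
        return Bicluster(rows, base.cols, base.pattern, a.coherency,
                         p_value=_min_p(a, b))
    if sym is not None:
        pattern = tuple(_modal_symbol(sym, rows, c) for c in cols)
    else:
        pat_map = dict(zip(b.cols, b.pattern))
        pat_map.update(dict(zip(a.cols, a.pattern)))
        pattern = tuple(pat_map[c] for c in cols)
    factors = {**b.row_factors, **a.row_factors}
    signs = {**b.signs, **a.signs}
    return Bicluster(rows, tuple(cols), pattern, a.coherency, factors, signs,
                     _min_p(a, b))


def _min_p(a: Bicluster, b: Bicluster) -> float | None:
    ps = [p for p in (a.p_value, b.p_value) if p is not None]
    return min(ps) if ps else None


def filter_biclusters(
    biclusters: Sequence[Bicluster],
    filter_overlap: float,
    alpha: float,
    n_tests: int | None = None,
) -> list[Bicluster]:
    """Drop insignificant biclusters (Bonferroni-corrected p >= alpha) and
    any bicluster overlapping a strictly larger retained one above the
    threshold; output sorted by (corrected p, size desc)."""
    n_tests = n_tests or max(1, len(biclusters))
    scored = []
    for b in biclusters:
        p = b.p_value if b.p_value is not None else 0.0
        p_corr = min(1.0, p * n_tests)
        if p_corr < alpha:
            scored.append((p_corr, b))
    if not scored and biclusters:
        log.info("all %d biclusters filtered as insignificant", len(biclusters))
    scored.sort(key=lambda pb: (pb[0], -pb[1].n_cells, sorted(pb[1].rows),
                                pb[1].cols))
    kept: list[tuple[float, Bicluster]] = []
    for p_corr, b in scored:
        dominated = any(
            kb.n_cells > b.n_cells and cell_jaccard(b, kb) > filter_overlap
            for _, kb in kept
        )
        if not dominated:
            kept.append((p_corr, b))
    out = []
    for p_corr, b in kept:
        out.append(Bicluster(b.rows, b.cols, b.pattern, b.coherency,
                             b.row_factors, b.signs, p_corr))
    return out


# ---------------------------------------------------------------------------
# constraint binding
# ---------------------------------------------------------------------------

def check_constraint_soundness(
    parsed: Sequence[C.Constraint],
    matrix: NumericMatrix,
    alphabet: Sequence[int],
    annotations: AnnotationMap | None = None,
) -> None:
    """Verify every referenced row/column/symbol/term exists before mining."""
    rows = set(matrix.row_ids)
    cols = set(matrix.col_ids)
    syms = {str(s) for s in alphabet}
    terms = {f"T:{t}" for t in annotations.term_universe} if annotations else set()
    item_toks = {f"{c}.{s}" for c in cols for s in alphabet}
    for con in parsed:
        for atom in con.atoms:
            if not isinstance(atom, C.SetAtom):
                continue
            for tok in atom.operand:
                if atom.target == "rows":
                    ok = tok in rows
                elif atom.target == "cols":
                    ok = tok in cols
                else:
                    ok = (tok in syms or tok in item_toks or tok in terms
                          or tok.startswith("T:"))
                if not ok:
                    raise C.ConstraintError(
                        f"constraint {con.text!r}: unbound identifier {tok!r} "
                        f"for target {atom.target!r}"
                    )


def _seq_constraints(parsed: Sequence[C.Constraint]) -> SeqConstraintSet:
    required: set[str] = set()
    forbidden: set[str] = set()
    regex = None
    extra: list[C.Constraint] = []
    for con in parsed:
        plain = True
        if con.is_atomic:
            atom = con.dnf[0][0]
            if isinstance(atom, C.RegexAtom):
                regex = atom
                continue
            if isinstance(atom, C.SetAtom) and atom.target in ("cols", "pattern"):
                if atom.rel == "superset":
                    required |= set(atom.operand)
                    continue
                if atom.rel == "excludes":
                    forbidden |= set(atom.operand)
                    continue
        if plain:
            extra.append(con)
    return SeqConstraintSet(required_items=frozenset(required),
                            forbidden_items=frozenset(forbidden),
                            regex=regex, extra=tuple(extra))


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

def run(
    data: NumericMatrix | Network,
    config: RunConfig | None = None,
    constraints: Sequence[C.Constraint | str] = (),
    annotations: AnnotationMap | None = None,
    report: RunReport | None = None,
) -> BiclusteringSolution:
    """Full biclustering run; returns the postprocessed solution.

    *constraints* may be parsed objects or expression strings.  The same
    inputs always give the same solution: the pipeline is deterministic.
    """
    config = config or RunConfig()
    report = report if report is not None else RunReport()
    t0 = time.perf_counter()

    matrix = network_to_matrix(data) if isinstance(data, Network) else data
    parsed = [
        c if isinstance(c, C.Constraint) else C.parse_constraint(c)
        for c in constraints
    ]
    norm = normalize_rows(matrix) if config.normalize else matrix
    if annotations is not None:
        annotations = annotations.bind(matrix)
    report.stage_seconds["preprocess"] = time.perf_counter() - t0

    all_bics: list[Bicluster] = []
    for coherency in config.coherencies():
        if coherency == "order-preserving":
            bics = _run_order_preserving(norm, config, parsed, annotations, report)
        else:
            bics = _run_itemset(norm, config, coherency, parsed, annotations, report)
        all_bics.extend(bics)

    t1 = time.perf_counter()
    solution_bics = _audit_constraints(all_bics, parsed, annotations, report)
    solution_bics = filter_biclusters(
        solution_bics, config.filter_overlap, config.significance_alpha,
        n_tests=max(1, report.patterns_mined),
    )
    coverage = solution_coverage(solution_bics, matrix)
    report.stage_seconds["postprocess_final"] = time.perf_counter() - t1
    provenance = {
        "coherency": config.coherency,
        "n_items": list(config.alphabets()),
        "theta_start": config.theta_start,
        "theta_step": config.theta_step,
        "stop_biclusters": config.stop_biclusters,
        "stop_coverage": config.stop_coverage,
        "merge_overlap": config.merge_overlap,
        "filter_overlap": config.filter_overlap,
        "significance_alpha": config.significance_alpha,
        "noise_tolerance": config.noise_tolerance,
        "constraints": [c.text for c in parsed],
        "seed": config.seed,
    }
    return BiclusteringSolution(solution_bics, provenance, coverage)


def _audit_constraints(bics, parsed, annotations, report) -> list[Bicluster]:
    if not parsed:
        return list(bics)
    kept = []
    audit = {c.text: 0 for c in parsed}
    for b in bics:
        fp = bicluster_to_fullpattern(b, annotations)
        bad = [c for c in parsed if not c.evaluate(fp, C.DEFAULT_COSTS)]
        if bad:
            for c in bad:
                audit[c.text] += 1
            continue
        kept.append(b)
    report.constraint_audit = [
        {"constraint": text, "violations_dropped": n} for text, n in audit.items()
    ]
    return kept


def _theta_schedule(config: RunConfig, n: int):
    theta = config.theta_start
    while True:
        count = max(config.min_rows, math.ceil(theta * n))
        yield count
        if count <= config.min_rows:
            return
        theta *= 1.0 - config.theta_step


def _satisfies_all(bic, parsed, annotations) -> bool:
    fp = bicluster_to_fullpattern(bic, annotations)
    return all(c.evaluate(fp, C.DEFAULT_COSTS) for c in parsed)


def _run_itemset(norm, config, coherency, parsed, annotations, report):
    alphabets = config.alphabets()
    dbs: dict[int, ItemsetDatabase] = {}
    syms: dict[int, SymbolicMatrix] = {}
    freqs: dict[int, dict] = {}
    t0 = time.perf_counter()
    for n_items in alphabets:
        model = fit_discretization(norm, n_items, config.discretization,
                                   config.multi_item_fraction)
        sym = discretize(norm, model)
        db = to_itemset_db(sym, coherency)
        if config.removed_symbols:
            db = remove_uninformative(db, config.removed_symbols)
        if annotations is not None:
            db = append_annotations(db, annotations)
        dbs[n_items] = db
        syms[n_items] = sym
        freqs[n_items] = _db_item_frequencies(db)
    report.stage_seconds["map_databases"] = (
        report.stage_seconds.get("map_databases", 0.0) + time.perf_counter() - t0
    )

    if parsed:
        alpha0 = alphabets[0]
        check_constraint_soundness(
            parsed, norm,
            syms[alpha0].model.alphabet, annotations,
        )
    translated: dict[int, list[C.Constraint]] = {}
    for n_items in alphabets:
        model_alpha = syms[n_items].model.alphabet
        translated[n_items] = [
            C.translate(c, model_alpha, norm.col_ids) if any(
                isinstance(a, C.SetAtom) and a.target in ("pattern", "cols")
                for a in c.atoms
            ) else c
            for c in parsed
        ]

    n_all = norm.shape[0]
    seen: set = set()
    patterns: list[tuple[int, FullPattern]] = []  # (n_items, fp)
    active = {n_items: True for n_items in alphabets}
    solution: list[Bicluster] = []
    cache: dict = {}

    for support in _theta_schedule(config, n_all):
        report.rounds += 1
        t0 = time.perf_counter()
        new = 0
        for n_items in alphabets:
            if not active[n_items]:
                continue
            db = dbs[n_items]
            params = MinerParams(
                min_support=support, min_length=config.min_cols,
                constraints=tuple(translated[n_items]),
                costs=C.DEFAULT_COSTS, tau=config.tau,
                max_patterns=config.max_round_patterns,
            )
            fps, st = mine_closed(db, params)
            report.visited_nodes += st.visited_nodes
            report.projections += st.projections
            report.mu_removed += st.mu_removed
            if st.saturated:
                active[n_items] = False
                report.saturated = True
            for fp in fps:
                key = (n_items, fp.coverage, fp.items)
                if key not in seen:
                    seen.add(key)
                    patterns.append((n_items, fp))
                    new += 1
        report.stage_seconds["mine"] = (
            report.stage_seconds.get("mine", 0.0) + time.perf_counter() - t0
        )
        report.patterns_mined = len(patterns)

        t0 = time.perf_counter()
        if new:
            solution = _postprocess_itemset(
                patterns, dbs, syms, freqs, norm, config, coherency,
                parsed, annotations, cache,
            )
        report.stage_seconds["postprocess"] = (
            report.stage_seconds.get("postprocess", 0.0) + time.perf_counter() - t0
        )
        if len(solution) >= config.stop_biclusters:
            break
        if solution and solution_coverage(solution, norm) >= config.stop_coverage:
            break
        if not any(active.values()):
            break
    return solution


def _postprocess_itemset(patterns, dbs, syms, freqs, norm, config, coherency,
                         parsed, annotations, cache):
    n_tests = max(1, len(patterns))
    candidates: list[tuple[int, Bicluster]] = []
    for n_items, fp in patterns:
        key = (n_items, fp.coverage, fp.items)
        if key in cache:
            bic = cache[key]
        else:
            p = _significance_from_db(fp, freqs[n_items], len(dbs[n_items]))
            bic = pattern_to_bicluster(fp, coherency, dbs[n_items].row_factors)
            if bic is not None:
                bic = Bicluster(bic.rows, bic.cols, bic.pattern, bic.coherency,
                                bic.row_factors, bic.signs, p)
            cache[key] = bic
        if bic is None:
            continue
        if min(1.0, (bic.p_value or 0.0) * n_tests) < config.significance_alpha:
            candidates.append((n_items, bic))

    # extension/reduction on the significant survivors only
    processed: list[Bicluster] = []
    seen_keys: set = set()
    for n_items, bic in candidates:
        delta = syms[n_items].model.coherency_strength
        ekey = ("ext", n_items, bic.rows, bic.cols, bic.pattern)
        if ekey in cache:
            ext = cache[ekey]
        else:
            ext = extend(bic, norm, config.noise_tolerance, delta, syms[n_items])
            if parsed and not _satisfies_all(ext, parsed, annotations):
                ext = bic  # extension must not break an inputted constraint
            red = reduce_bicluster(ext, norm, config.noise_tolerance, delta)
            ext = red if red is not None else ext
            ext = Bicluster(ext.rows, ext.cols, ext.pattern, ext.coherency,
                            ext.row_factors, ext.signs, bic.p_value)
            cache[ekey] = ext
        k = ext.key() + (ext.pattern,)
        if k not in seen_keys:
            seen_keys.add(k)
            processed.append(ext)

    sym0 = syms[max(syms)]
    merged = merge(processed, config.merge_overlap, sym0)
    # final reduction at the finest coherency strength: merging unions rows,
    # so shed members that do not fit the merged pattern tightly
    delta_fine = sym0.model.coherency_strength
    final = []
    for b in merged:
        red = reduce_bicluster(b, norm, config.noise_tolerance, delta_fine)
        b = red if red is not None else b
        if config.removed_symbols:
            # extension/merging must not reintroduce uninformative symbols
            b = _strip_symbols(b, set(config.removed_symbols))
            if b is None:
                continue
        final.append(b)
    return filter_biclusters(final, config.filter_overlap,
                             config.significance_alpha, n_tests=n_tests)


def _strip_symbols(bic: Bicluster, removed: set) -> Bicluster | None:
    keep = [(c, s) for c, s in zip(bic.cols, bic.pattern) if s not in removed]
    if len(keep) == len(bic.cols):
        return bic
    if len(keep) < 2:
        return None
    cols, pattern = zip(*keep)
    return Bicluster(bic.rows, tuple(cols), tuple(pattern), bic.coherency,
                     bic.row_factors, bic.signs, bic.p_value)


def _run_order_preserving(norm, config, parsed, annotations, report):
    m = norm.shape[1]
    n_sym = max(2, math.ceil(m / 4))
    t0 = time.perf_counter()
    db = to_sequence_db(norm, n_items=n_sym)
    if annotations is not None:
        db = append_annotations(db, annotations)
    report.stage_seconds["map_databases"] = (
        report.stage_seconds.get("map_databases", 0.0) + time.perf_counter() - t0
    )
    if parsed:
        check_constraint_soundness(parsed, norm, list(range(-n_sym, n_sym + 1)),
                                   annotations)
    cs = _seq_constraints(parsed)
    col_medians = {
        c: float(np.nanmedian(norm.values[:, j])) for j, c in enumerate(norm.col_ids)
    }

    n_all = max(1, len(db))
    seen: set = set()
    patterns: list[FullPattern] = []
    solution: list[Bicluster] = []
    for support in _theta_schedule(config, n_all):
        report.rounds += 1
        fps, st = mine_sequential_closed(
            db, support, config.min_cols, cs, column_values=col_medians,
            tau=config.tau, max_patterns=config.max_round_patterns,
        )
        report.visited_nodes += st.visited_nodes
        report.projections += st.projections
        new = 0
        for fp in fps:
            key = (fp.coverage, fp.sequence)
            if key not in seen:
                seen.add(key)
                patterns.append(fp)
                new += 1
        report.patterns_mined = len(patterns)
        if st.saturated:
            report.saturated = True
        if new:
            n_tests = max(1, len(patterns))
            cands = []
            for fp in patterns:
                p = _significance_from_db(fp, {}, n_all)
                if min(1.0, p * n_tests) < config.significance_alpha:
                    b = pattern_to_bicluster(fp, "order-preserving")
                    if b is not None:
                        cands.append(Bicluster(b.rows, b.cols, b.pattern,
                                               b.coherency, p_value=p))
            merged = merge(cands, config.merge_overlap)
            solution = filter_biclusters(merged, config.filter_overlap,
                                         config.significance_alpha, n_tests)
        if len(solution) >= config.stop_biclusters:
            break
        if solution and solution_coverage(solution, norm) >= config.stop_coverage:
            break
        if st.saturated:
            break
    return solution
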