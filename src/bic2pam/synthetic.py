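"""Synthetic benchmarks with planted biclusters and known ground truth.

The generator emulates the regularities of gene expression matrices used to
benchmark pattern-based biclustering: a background of i.i.d. values over the
data range with K planted biclusters whose sizes are drawn uniformly from
setting-specific ranges.  Constant biclusters share a per-column expected
value; order-preserving biclusters share a column ordering.  Corruptions are
parameterizable: additive noise deviations on a fraction of cells, missing
cells, and overlapping biclusters combined through plaid effects.

Settings (rows x cols -> planted count K and size ranges):

=========  ==========  ============  ============
setting    K (base/mu) rows/bic      cols/bic
500x50     6/mu        mu*[50,70]    mu*[5,7]
1000x100   10/mu       mu*[70,100]   mu*[7,10]
2000x200   15/mu       mu*[100,200]  mu*[8,12]
4000x400   20/mu       mu*[200,300]  mu*[10,15]
=========  ==========  ============  ============

where mu reflects the flexibility of the coherency assumption (mu = 1 for
constant, mu = 2 for order-preserving).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import (
    AnnotationMap,
    Bicluster,
    BiclusteringSolution,
    NumericMatrix,
    cell_jaccard,
)

log = logging.getLogger("bic2pam")

#: per-setting (K base, row-size range, col-size range)
SETTINGS: dict[str, tuple[int, tuple[int, int], tuple[int, int]]] = {
    "500x50": (6, (50, 70), (5, 7)),
    "1000x100": (10, (70, 100), (7, 10)),
    "2000x200": (15, (100, 200), (8, 12)),
    "4000x400": (20, (200, 300), (10, 15)),
}

_MU = {"constant": 1, "order-preserving": 2}


@dataclass
class SyntheticConfig:
    """Benchmark parameters; defaults are the standard setting (coherency
    strength 20% i.e. 5 symbols, 2% noisy and missing cells, overlap 0.2
    with additive plaid effects)."""

    n_rows: int = 500
    n_cols: int = 50
    coherency: str = "constant"  # "constant" | "order-preserving"
    k_base: int = 6
    row_size: tuple[int, int] = (50, 70)
    col_size: tuple[int, int] = (5, 7)
    n_items: int = 5  # delta = range / n_items
    noise_deviation: float | None = None  # default delta/2
    noisy_fraction: float = 0.02
    missing_fraction: float = 0.02
    overlap: float = 0.2  # overlapping degree theta
    plaid_f: str = "sum"  # sum | product | weighted
    plaid_nu: float = 1.0  # cumulative effect weight
    plaid_eps: float = 0.1  # plaid noise
    plaid_kappa: float = 0.3  # interacting biclusters, fraction of K
    plaid_phi: float = 0.8  # spread of overlapping areas
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coherency not in _MU:
            raise ValueError(f"unsupported coherency {self.coherency!r}")
        for lo, hi, n in ((self.row_size + (self.n_rows,)),
                          (self.col_size + (self.n_cols,))):
            if not 1 <= lo <= hi:
                raise ValueError("size range must satisfy 1 <= lo <= hi")
            if self.mu * hi > n:
                raise ValueError(
                    f"bicluster size range {lo}-{hi} (x mu={self.mu}) exceeds "
                    f"matrix dimension {n}"
                )

    @property
    def mu(self) -> int:
        return _MU[self.coherency]

    @property
    def n_biclusters(self) -> int:
        """Planted count K = base * (1 / mu)."""
        return max(1, round(self.k_base / self.mu))

    @property
    def delta(self) -> float:
        """Coherency strength over the unit value range."""
        return 1.0 / self.n_items

    @classmethod
    def from_setting(cls, setting: str, coherency: str = "constant",
                     **kwargs) -> "SyntheticConfig":
        if setting not in SETTINGS:
            raise ValueError(f"unknown setting {setting!r}; pick from {sorted(SETTINGS)}")
        base, rows, cols = SETTINGS[setting]
        n_rows, n_cols = (int(x) for x in setting.split("x"))
        mu = _MU[coherency]
        return cls(
            n_rows=n_rows, n_cols=n_cols, coherency=coherency, k_base=base,
            row_size=(rows[0] * mu, rows[1] * mu),
            col_size=(cols[0] * mu, cols[1] * mu),
            **kwargs,
        )


@dataclass
class GroundTruth:
    """Planted biclusters plus (optional) per-bicluster annotation terms."""

    biclusters: list[Bicluster]
    bicluster_terms: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.biclusters)

    def to_dict(self) -> dict:
        return {
            "biclusters": [b.to_dict() for b in self.biclusters],
            "bicluster_terms": {str(k): v for k, v in self.bicluster_terms.items()},
        }

    @classmethod
    def from_dict(cls, d) -> "GroundTruth":
        return cls(
            [Bicluster.from_dict(b) for b in d["biclusters"]],
            {int(k): v for k, v in d.get("bicluster_terms", {}).items()},
        )


def generate(cfg: SyntheticConfig) -> tuple[NumericMatrix, GroundTruth]:
    """Generate one benchmark instance; fully determined by cfg.seed.

    Background cells are i.i.d. uniform on [0, 1].  With overlap 0, planted
    biclusters occupy disjoint rows and columns; otherwise roughly
    ``kappa * K`` biclusters share about ``overlap`` of their rows with a
    partner, overlapping cells combined by the plaid function.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, K = cfg.n_rows, cfg.n_cols, cfg.n_biclusters
    values = rng.uniform(0.0, 1.0, size=(n, m))
    row_ids = [f"x{i + 1}" for i in range(n)]
    col_ids = [f"y{j + 1}" for j in range(m)]

    sizes = [
        (int(rng.integers(cfg.row_size[0], cfg.row_size[1] + 1)),
         int(rng.integers(cfg.col_size[0], cfg.col_size[1] + 1)))
        for _ in range(K)
    ]
    if cfg.overlap <= 0:
        if sum(r for r, _ in sizes) > n or sum(c for _, c in sizes) > m:
            raise ValueError("disjoint placement infeasible for these sizes")
        rperm = rng.permutation(n)
        cperm = rng.permutation(m)
        placements = []
        ri = ci = 0
        for nr, nc in sizes:
            placements.append((rperm[ri:ri + nr], cperm[ci:ci + nc]))
            ri += nr
            ci += nc
    else:
        placements = []
        n_inter = round(cfg.plaid_kappa * K)
        for k, (nr, nc) in enumerate(sizes):
            if k > 0 and k <= n_inter:
                # share ~overlap of rows (scaled by phi) with the previous one
                prev_rows, prev_cols = placements[k - 1]
                n_share = min(len(prev_rows), max(1, round(cfg.overlap * cfg.plaid_phi * nr)))
                shared = rng.choice(prev_rows, size=n_share, replace=False)
                rest = rng.choice(
                    np.setdiff1d(np.arange(n), shared), size=nr - n_share,
                    replace=False,
                )
                rows = np.concatenate([shared, rest])
                cols = rng.choice(m, size=nc, replace=False)
            else:
                rows = rng.choice(n, size=nr, replace=False)
                cols = rng.choice(m, size=nc, replace=False)
            placements.append((rows, cols))

    sums = np.zeros((n, m))
    prods = np.ones((n, m))
    counts = np.zeros((n, m), dtype=int)
    planted: list[Bicluster] = []
    for (rows, cols) in placements:
        nc = len(cols)
        if cfg.coherency == "constant":
            kj = rng.uniform(0.0, 1.0, size=nc)  # aligned to cols order
            block = np.tile(kj, (len(rows), 1))
            order_sorted = sorted(range(nc), key=lambda t: cols[t])
            bic_cols = tuple(col_ids[cols[t]] for t in order_sorted)
            bic_pattern = tuple(float(kj[t]) for t in order_sorted)
        else:
            perm = rng.permutation(nc)  # perm[t] = local col at value-rank t
            sorted_vals = np.sort(rng.uniform(0.0, 1.0, size=(len(rows), nc)), axis=1)
            block = np.empty((len(rows), nc))
            block[:, perm] = sorted_vals
            bic_cols = tuple(sorted(col_ids[cols[t]] for t in range(nc)))
            bic_pattern = tuple((col_ids[cols[perm[t]]],) for t in range(nc))
        sums[np.ix_(rows, cols)] += block
        prods[np.ix_(rows, cols)] *= block
        counts[np.ix_(rows, cols)] += 1
        planted.append(Bicluster(
            rows=frozenset(row_ids[i] for i in rows),
            cols=bic_cols,
            pattern=bic_pattern,
            coherency=cfg.coherency,
        ))

    single = counts == 1
    values[single] = sums[single]
    multi = counts > 1
    if multi.any():
        if cfg.plaid_f == "sum":
            combined = cfg.plaid_nu * sums[multi]
        elif cfg.plaid_f == "product":
            combined = cfg.plaid_nu * prods[multi]
        elif cfg.plaid_f == "weighted":
            combined = cfg.plaid_nu * sums[multi] / counts[multi]
        else:
            raise ValueError(f"unknown plaid function {cfg.plaid_f!r}")
        combined = combined + cfg.plaid_eps * rng.standard_normal(int(multi.sum()))
        values[multi] = combined

    if cfg.noisy_fraction > 0:
        dev = cfg.noise_deviation if cfg.noise_deviation is not None else cfg.delta / 2
        k = int(round(cfg.noisy_fraction * n * m))
        idx = rng.choice(n * m, size=k, replace=False)
        values.flat[idx] += rng.uniform(-dev, dev, size=k)
    if cfg.missing_fraction > 0:
        k = int(round(cfg.missing_fraction * n * m))
        idx = rng.choice(n * m, size=k, replace=False)
        values.flat[idx] = np.nan

    return NumericMatrix(row_ids, col_ids, values), GroundTruth(planted)


def annotate(
    gt: GroundTruth,
    row_ids: Sequence[str],
    per_row: tuple[float, float] = (4.0, 2.0),
    per_term_rows: tuple[float, float] = (100.0, 10.0),
    consistency: tuple[float, float] = (0.85, 0.10),
    seed: int = 0,
) -> AnnotationMap:
    """Annotate rows with background terms plus one dedicated term per
    planted bicluster shared by ~``consistency`` of its rows.

    ``per_row`` is the mean +/- sd of annotations per row (clipped at 0);
    background terms each cover ~``per_term_rows`` rows.
    """
    if per_row[0] <= 0 or per_term_rows[0] <= 0:
        raise ValueError("annotation means must be positive")
    rng = np.random.default_rng(seed)
    n = len(row_ids)
    entries: dict[str, set[str]] = {r: set() for r in row_ids}

    # dedicated consistent term per planted bicluster
    for k, bic in enumerate(gt.biclusters):
        term = f"TB{k + 1}"
        gt.bicluster_terms[k] = term
        frac = float(np.clip(rng.normal(*consistency), 0.0, 1.0))
        members = sorted(bic.rows)
        n_share = int(round(frac * len(members)))
        for r in rng.choice(members, size=n_share, replace=False):
            entries[str(r)].add(term)

    # background terms: enough to meet the per-row budget
    target = {r: max(0, int(round(rng.normal(*per_row)))) for r in row_ids}
    total = sum(target.values())
    n_terms = max(1, int(round(total / per_term_rows[0])))
    deficit = {r: t - len(entries[r]) for r, t in target.items()}
    for t in range(n_terms):
        term = f"T{t + 1}"
        size = max(1, int(round(rng.normal(*per_term_rows))))
        pool = [r for r in row_ids if deficit[r] > 0]
        if not pool:
            break
        chosen = rng.choice(pool, size=min(size, len(pool)), replace=False)
        for r in chosen:
            entries[str(r)].add(term)
            deficit[str(r)] -= 1
    return AnnotationMap(entries)


def match_score(
    found: BiclusteringSolution | Sequence[Bicluster],
    hidden: GroundTruth | Sequence[Bicluster],
) -> dict[str, float]:
    """Jaccard-based match scores between found and planted biclusters.

    ``recoverability`` averages, over hidden biclusters, the best cell-set
    Jaccard against the found solution (1 = every planted bicluster exactly
    recovered); ``precision`` is the symmetric direction — the complement of
    spuriousness — averaging over found biclusters their best match against
    the hidden ones.
    """
    fb = list(found.biclusters if isinstance(found, BiclusteringSolution) else found)
    hb = list(hidden.biclusters if isinstance(hidden, GroundTruth) else hidden)
    if not fb or not hb:
        log.warning("match_score: empty %s collection",
                    "found" if not fb else "hidden")
        return {"recoverability": 0.0, "precision": 0.0}
    rec = float(np.mean([max(cell_jaccard(h, f) for f in fb) for h in hb]))
    prec = float(np.mean([max(cell_jaccard(f, h) for h in hb) for f in fb]))
    return {"recoverability": rec, "precision": prec}
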