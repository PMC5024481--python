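# Methods

## Model

A bicluster `B = (I, J)` of a real-valued matrix `A` satisfies coherency
across rows, `a_ij = k_j + γ_i + η_ij`, where `k_j` is the expected value
of column `j`, `γ_i` a per-row adjustment (zero for constant coherency)
and `η_ij ∈ [−δ/2, δ/2]` noise bounded by the coherency strength `δ`.
Symmetric coherency additionally allows a per-row sign `c_i ∈ {1, −1}`;
order-preserving coherency replaces value expectations by a shared linear
ordering of the columns.  After discretization into an alphabet `𝓛`, the
strength is tied to the alphabet size, `δ = Ā/|𝓛|` with `Ā` the amplitude
of observed values: more symbols mean a finer coherency.

Mining proceeds on transactional views of `A`.  For itemset coherencies
each row becomes a transaction of `column.symbol` items (additive rows are
first anchored at zero-minimum symbol, recording `γ_i`; symmetric rows are
emitted twice, the mirror with negated symbols).  For order-preserving
coherency each row becomes the sequence of its column ids sorted by value,
ties sharing a co-occurrence itemset.  Closed full-patterns — patterns with
coverage `Φ_P`, columns `Ψ_P` and original symbols `Υ_P`, such that no
satisfying strict super-pattern has identical coverage — map directly to
maximal biclusters via `I = Φ_P`, `J = Ψ_P`, `φ_B = Υ_P`.

### Constrained closure

Constraints restrict the admissible pattern space, so closure is computed
*within the satisfying space*: a satisfying pattern is reported iff no
satisfying strict superset (supersequence) has identical coverage.  This
is required for the mapping to biclusters to remain exhaustive — under
`sum(P) ≤ 1` on the worked database the answer is `{a,b}`, although the
unconstrained closure of `{a,b}` is `{a,b,c}`, which violates the bound.
Both miners therefore enumerate all satisfying frequent patterns (with the
prunings below, all of which are result-invariant) and keep, per coverage
group, the set-maximal members.  For sequences, maximality is decided on
(pattern, coverage) pairs; co-occurrence `(y1 y3)` and precedence `y1 y3`
are incomparable patterns — neither contains the other.

### Constraint classification and pushing

Atoms are classified by the pruning property they offer (the standard
taxonomy): `range ≥ v`, `countVal ≥ v`, required item sets → monotone;
`max ≤ v`, `min ≥ v`, `sum ≤ v` under nonnegative costs, `length ≤ v`,
excluded item sets → anti-monotone; `min ≤ v`, `max ≥ v`, membership
relations, `min/max = v` → succinct; `avg` bounds → convertible; sequence
regular expressions → prefix-monotone.  Aggregates over the `rows`/`cols`
targets are left unclassified (coverage shrinks as patterns grow, so the
pattern-space table does not apply) and enforced by post-filtering, except
row-containment constraints, which are pushed as anti-monotone coverage
checks.  Conjunctions are pushed per conjunct; disjunctions are pushed only
when all atoms are succinct, otherwise post-filtered.  A documented
departure from one motivating description: `|P ∩ {T1,T2}| ≥ 1` is treated
as monotone/succinct (standard definitions), and annotation consistency is
realized as a succinct containment constraint.

In the itemset miner: succinct value bounds delete conflicting items
(α-reduction) and monotone constraints delete transactions whose full item
set cannot satisfy them (μ-reduction) — sound because a transaction failing
a monotone constraint supports no satisfying subset; both are re-applied on
every τ-th conditional projection (τ = 1 by default).  Anti-monotone
violations stop pattern growth.  A convertible average bound orders the
header table by cost in the direction that makes extensions one-sided
(ascending for `avg ≥ v`, descending for `avg ≤ v`), after which a
violating prefix can never recover and is pruned; when several convertible
atoms disagree in direction, the first is pushed and the rest post-filtered.
Monotone atoms, once satisfied by a prefix, are dropped from further
checks.  In the sequential miner, prefixes conflicting with anti-monotone
length bounds or the regular-expression automaton are not expanded, and
projected sequences that cannot satisfy a monotone constraint are removed
from the projection — sound because order-preserving sequences are
item-indexable (every column occurs once per row), making embeddings
unique.

Transaction ids ride on the FP-tree at path terminals and rise to parents
as deeper items are retired, so every pattern emerges with its exact
coverage; conditional trees preserve the global header order (required for
the μ/α reductions to commute with projection).  Patterns never take two
symbols of one column (multi-item assignment would otherwise create
degenerate biclusters); the brute-force oracles in the test suite apply
the same rule.

### Significance

The filtering statistic is a column-independence binomial tail, replacing
the external criterion the surrounding literature delegates to: the
probability that a random row matches the pattern is
`p_φ = Π_{j∈J} f_j(k_j)` with `f_j` the empirical frequency of symbol
`k_j` in column `j` (inside the pipeline, the item's relative support in
the mined database — identical by construction, and correctly aligned for
additive/symmetric coherencies); for order-preserving patterns
`p_φ = 1/|J|!`, a no-ties approximation.  The p-value is
`P(Bin(n, p_φ) ≥ |I|)`, Bonferroni-corrected by the number of patterns
tested; biclusters at corrected `p ≥ α` (default 0.01) are dropped.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `n_items` | {3, 5, 7} | alphabet sweep for itemset coherencies; `⌈m/4⌉` symbols decide ties for order-preserving |
| `multi_item_fraction` α | 0.1 | cells within `α · bin width` of a cutpoint get both adjacent symbols |
| `theta_start`, `theta_step` | 0.80, 0.10 | support starts at 80 % of rows and decreases relatively (`θ ← 0.9 θ`), flooring at 2 rows |
| `min_cols` | 3 | minimum pattern columns; on wide matrices 2-column patterns are statistically trivial and crowd out real modules |
| `stop_biclusters`, `stop_coverage` | 50, 0.10 | stop once this many dissimilar significant biclusters, or this coverage, is reached |
| `merge_overlap` | 0.70 | merge pairs above this cell-set Jaccard (pattern recomputed as per-column mode, ties toward zero) |
| `filter_overlap` | 0.60 | drop biclusters overlapping a strictly larger retained one above this |
| `significance_alpha` | 0.01 | Bonferroni-corrected significance level |
| `noise_tolerance` | 0.2 | extension/reduction keep rows and columns matching ≥ 80 % of positions |
| `max_round_patterns` | 5000 | saturation guard per mining round (below) |

Choices made where the underlying description was open, all configurable:

* **Relative support decrease.** "Decrease by 10 %" is read as
  `θ ← 0.9 θ` so the loop can never cross zero; results from the `{3,5,7}`
  sweep are unioned (dedup by coverage and items) before postprocessing.
* **Extension/reduction match numerically.** A row (column) matches the
  pattern at a position when the cell lies within `δ/2` of the pattern's
  expected value — `δ` taken from the pattern's own alphabet, the expected
  value as the member-row median, with additive offsets and symmetric signs
  re-estimated per row.  Row and column passes alternate to a fixpoint.
  After merging, a final reduction at the finest swept `δ` sheds members
  that fit only loosely.
* **Postprocessing order.** Significance screening runs before extension
  (extension of insignificant candidates is wasted work), then extension,
  reduction, merging and the overlap/significance filter.  Inputted
  constraints are re-audited on the final biclusters (with annotation items
  re-attached when shared by all member rows); an extension that would
  break a constraint is rolled back.
* **Saturation guard.** At low support on unstructured background the
  closed-pattern space grows combinatorially.  A round emitting more than
  `max_round_patterns` candidates is truncated (kept patterns are the
  highest-support ones) and ends the support loop for that alphabet.  This
  bounds the search; the stop criteria themselves are unchanged.
* **Default coherency** for `run`/CLI is `constant`; `all` iterates the
  four coherencies.
* **Sequence ties.** `to_sequence_db` ties on exact value equality by
  default; given `n_items`, values are first discretized and ties decided
  on symbols (the pipeline uses `max(2, ⌈m/4⌉)`, trading precedences
  against co-occurrences).
* **Mirror folding.** Symmetric biclusters keep at most one orientation
  per row, the unmirrored one first.

## Synthetic benchmarks

The generator emulates expression-like matrices: background cells i.i.d.
uniform on the unit range (configurable), K planted biclusters per the
setting table (K = base/μ, sizes uniform in μ-scaled ranges; μ = 1
constant, μ = 2 order-preserving).  Constant biclusters share per-column
expected values drawn uniformly; order-preserving ones share a random
column ordering with per-row sorted uniforms.  Defaults follow the
standard benchmark condition: 5 symbols (δ = 20 %), 2 % noisy cells
(additive uniform deviation of δ/2 by default; "±20 % of range" noise is
the `noise_deviation = δ` choice), 2 % missing cells, overlap degree 0.2
with plaid combination (`sum` by default; `product` and ν-weighted mean
also implemented, with ε-scaled Gaussian noise on overlapping cells, and
κ = 0.3 K interacting biclusters sharing ~θ·φ of their rows).  The
annotation generator gives each row ~N(4, 2) background terms in groups of
~N(100, 10) rows and each planted bicluster a dedicated term shared by
~N(85 %, 10 pp) of its rows.

What the generator does *not* emulate: heavy-tailed expression
distributions, correlated background structure, batch effects, or
column-wise annotation. Passing recovery tests therefore demonstrates
correctness of the method's machinery under its stated model, not
performance on real expression data.

Match scores are cell-set Jaccard based: recoverability = mean over hidden
biclusters of the best Jaccard against the found solution; precision the
converse.  Problem sizes in the tests: the recovery checks run one
instance of the 500×50 setting per condition (about a minute each); the
miner-vs-oracle equivalence checks run 200 random databases per constraint
class (≤ 10 transactions × 8 items, ≤ 8 sequences × 6 columns) per miner,
comparing against powerset / subsequence enumeration oracles with
constrained closure, in both pushed and post-filter modes with
visited-candidate counters asserting pruned ≤ unpruned.

## Numerical and degenerate-input conventions

Missing cells are first-class (NaN): excluded from normalization means,
discretization fits and transactions — in network adjacency matrices an
absent edge is missing, never zero.  Gaussian-quantile discretization with
zero variance falls back to equal width with a warning; a degenerate
constant matrix yields a single symbol.  Multi-item tolerance near a
cutpoint uses the narrower adjacent finite bin (amplitude/|𝓛| when both
neighbours are unbounded); with α = 0 every cell gets exactly one symbol,
including cells exactly on a cutpoint.  Header-table ties break
lexicographically; merged-pattern modal ties break toward the symbol
nearest zero; solutions sort by (corrected p, size, row ids).  The whole
pipeline is deterministic: the seed only enters the synthetic generator.

## Known limitations

Association-rule-based noise handling and plaid-model composition are out
of scope, as are gap/temporal sequence constraints (irrelevant for
order-preserving models) and data partitioning for matrices beyond ~10⁸
cells.  The order-preserving significance model ignores ties, which makes
it conservative on heavily tied data.  Order-preserving recovery of
planted benchmarks is weaker than the constant case: tie discretization
fragments long orderings, and no numeric extension is attempted for
sequences.  The binomial significance filter assumes column independence;
correlated conditions inflate significance.
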