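"""Constrained closed full-pattern mining on a tiny transactional database.

Builds the classic three-transaction database, attaches a cost table, and
mines it under one constraint of each pruning class.  The printed patterns
carry their coverage — the transaction ids that turn a frequent itemset
into a bicluster.
"""

from bic2pam import CostTable, MinerParams, mine_closed, parse_constraint
from bic2pam.preprocess import format_item

db = {"x1": {"a", "b", "c"}, "x2": {"a", "b", "c", "d"}, "x3": {"a", "d"}}
costs = CostTable({"a": 0, "b": 1, "c": 2, "d": 3})

for text in [
    "range(pattern) >= 2",   # monotone: at least two cost units apart
    "sum(pattern) <= 1",     # anti-monotone: cheap patterns only
    "pattern superset {c,d}",  # succinct: require both c and d
    "avg(pattern) >= 2",     # convertible: expensive on average
]:
    constraint = parse_constraint(text)
    params = MinerParams(min_support=1, min_length=2,
                         constraints=(constraint,), costs=costs)
    patterns, stats = mine_closed(db, params)
    print(f"{text:26s} -> {len(patterns)} closed pattern(s), "
          f"{stats.visited_nodes} candidates visited")
    for fp in patterns:
        items = ",".join(sorted(format_item(i) for i in fp.items))
        print(f"    {{{items}}} supported by {sorted(fp.coverage)}")

# Closure is computed within the constraint-satisfying space: under
# sum <= 1 the miner reports {a,b} even though its unconstrained closure
# {a,b,c} violates the constraint.
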