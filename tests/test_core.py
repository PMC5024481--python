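import json

import numpy as np
import pytest
from scipy import stats as sps

from bic2pam import (
    Bicluster,
    NumericMatrix,
    RunConfig,
    cell_jaccard,
    extend,
    filter_biclusters,
    merge,
    pattern_to_bicluster,
    reduce_bicluster,
    run,
    significance,
)
from bic2pam.core import bicluster_to_fullpattern
from bic2pam.data import AnnotationMap
from bic2pam.patterns import FullPattern
from bic2pam.preprocess import (
    DiscretizationModel,
    SymbolicMatrix,
    value_item,
)
from bic2pam.synthetic import SyntheticConfig, annotate, generate, match_score


def fp(items, coverage, columns, symbols):
    return FullPattern(items=frozenset(items), coverage=frozenset(coverage),
                       columns=tuple(columns), symbols=tuple(symbols))


class TestPatternToBicluster:
    def test_mapping_keeps_rows_columns_pattern(self):
        f = fp({value_item("y1", 6), value_item("y2", 5), value_item("y4", 3)},
               {"t1", "t3"}, ("y1", "y2", "y4"), (6, 5, 3))
        b = pattern_to_bicluster(f)
        assert b.rows == frozenset({"t1", "t3"})
        assert b.cols == ("y1", "y2", "y4")
        assert b.pattern == (6, 5, 3)

    def test_additive_factors_attached(self):
        f = fp({value_item("y1", 0), value_item("y2", 2)}, {"x1"},
               ("y1", "y2"), (0, 2))
        b = pattern_to_bicluster(f, "additive", {"x1": 1, "x9": 5})
        assert b.row_factors == {"x1": 1}

    def test_symmetric_mirror_folds_with_original_orientation_first(self):
        f = fp({value_item("y1", 2), value_item("y2", -1)},
               {"x2", "~x2", "~x3"}, ("y1", "y2"), (2, -1))
        b = pattern_to_bicluster(f, "symmetric")
        assert b.rows == frozenset({"x2", "x3"})
        assert b.signs == {"x2": 1, "x3": -1}

    def test_annotation_only_columns_cannot_form_bicluster(self):
        f = FullPattern(items=frozenset({value_item("y1", 1), ("t", "T1")}),
                        coverage=frozenset({"x1"}), columns=("y1",), symbols=(1,))
        assert pattern_to_bicluster(f) is None


class TestMerge:
    def b(self, rows, cols):
        return Bicluster(frozenset(rows), tuple(cols), tuple(0 for _ in cols))

    def test_identical_duplicates_collapse(self):
        out = merge([self.b({"r1"}, ("c1", "c2")), self.b({"r1"}, ("c1", "c2"))], 0.7)
        assert len(out) == 1

    def test_jaccard_point_six_not_merged_at_point_seven(self):
        rows = {f"r{i}" for i in range(4)}
        a = self.b(rows, ("c1", "c2", "c3", "c4"))
        b = self.b(rows, ("c2", "c3", "c4", "c5"))
        assert cell_jaccard(a, b) == pytest.approx(12 / 20)
        assert len(merge([a, b], 0.7)) == 2
        assert len(merge([a, b], 0.5)) == 1

    def test_disjoint_unchanged(self):
        out = merge([self.b({"r1"}, ("c1", "c2")), self.b({"r2"}, ("c3", "c4"))], 0.7)
        assert len(out) == 2

    def test_merged_pattern_is_per_column_mode(self):
        model = DiscretizationModel([-1, 0, 1], np.array([-0.5, 0.5]), 2.0,
                                    "equal_width", 0.0)
        prim = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        sym = SymbolicMatrix(["r1", "r2", "r3"], ["c1", "c2"], prim, {}, model)
        a = Bicluster(frozenset({"r1", "r2"}), ("c1", "c2"), (1, 1))
        b = Bicluster(frozenset({"r2", "r3"}), ("c1", "c2"), (1, 0))
        (m,) = merge([a, b], 0.3, sym)  # cell Jaccard = 2/6
        assert m.rows == frozenset({"r1", "r2", "r3"})
        assert m.pattern == (1, 0)


class TestExtendReduce:
    def planted(self):
        rng = np.random.default_rng(23)
        values = rng.uniform(0, 1, (20, 6))
        values[:8, :3] = np.tile([0.1, 0.5, 0.9], (8, 1))
        rows = [f"r{i}" for i in range(20)]
        cols = [f"c{j}" for j in range(6)]
        m = NumericMatrix(rows, cols, values)
        core = Bicluster(frozenset(rows[:5]), ("c0", "c1", "c2"), (0, 0, 0))
        return m, core, rows

    def test_zero_tolerance_adds_only_perfect_rows(self):
        m, core, rows = self.planted()
        out = extend(core, m, 0.0, delta=0.05)
        assert frozenset(rows[:8]) <= out.rows
        assert all(r in rows[:8] for r in out.rows)

    def test_partial_match_added_within_tolerance(self):
        rows = ["a", "b"]
        vals = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.9]])
        m = NumericMatrix(rows, ["c1", "c2", "c3"], vals)
        core = Bicluster(frozenset({"a"}), ("c1", "c2", "c3"), (0, 0, 0))
        loose = extend(core, m, 0.4, delta=0.1)  # 2/3 matched >= 0.6
        assert "b" in loose.rows
        strict = extend(core, m, 0.2, delta=0.1)
        assert "b" not in strict.rows

    def test_reduce_is_identity_on_clean_bicluster(self):
        m, core, rows = self.planted()
        full = Bicluster(frozenset(rows[:8]), ("c0", "c1", "c2"), (0, 0, 0))
        out = reduce_bicluster(full, m, 0.0, delta=0.05)
        assert out.rows == full.rows and out.cols == full.cols

    def test_reduce_drops_nonmatching_row(self):
        m, core, rows = self.planted()
        noisy = Bicluster(frozenset(rows[:9]), ("c0", "c1", "c2"), (0, 0, 0))
        out = reduce_bicluster(noisy, m, 0.0, delta=0.05)
        assert out.rows == frozenset(rows[:8])


class TestSignificance:
    def sym(self, prim):
        prim = np.asarray(prim, dtype=float)
        model = DiscretizationModel([0, 1], np.array([0.5]), 1.0,
                                    "equal_width", 0.0)
        rows = [f"r{i}" for i in range(prim.shape[0])]
        cols = [f"c{j}" for j in range(prim.shape[1])]
        return SymbolicMatrix(rows, cols, prim, {}, model), rows, cols

    def test_constant_columns_give_p_one(self):
        sym, rows, cols = self.sym(np.zeros((10, 2)))
        b = Bicluster(frozenset(rows), tuple(cols), (0, 0))
        assert significance(b, sym) == pytest.approx(1.0)

    def test_matches_binomial_tail_oracle(self):
        prim = np.zeros((100, 2))
        prim[:10, 0] = 1.0
        prim[:10, 1] = 1.0
        sym, rows, cols = self.sym(prim)
        b = Bicluster(frozenset(rows[:5]), tuple(cols), (1, 1))
        # p_phi = 0.1 * 0.1; P(Bin(100, 0.01) >= 5)
        expected = sps.binom.sf(4, 100, 0.01)
        assert significance(b, sym) == pytest.approx(expected)

    def test_more_rows_never_less_significant(self):
        prim = np.zeros((50, 2))
        prim[:20, :] = 1.0
        sym, rows, cols = self.sym(prim)
        last = 1.1
        for k in (5, 10, 15, 20):
            b = Bicluster(frozenset(rows[:k]), tuple(cols), (1, 1))
            p = significance(b, sym)
            assert p <= last + 1e-12
            last = p

    def test_order_preserving_uses_ordering_probability(self):
        sym, rows, cols = self.sym(np.zeros((24, 2)))
        b = Bicluster(frozenset(rows[:12]), tuple(cols),
                      (("c0",), ("c1",)), coherency="order-preserving")
        expected = sps.binom.sf(11, 24, 1 / 2)
        assert significance(b, sym) == pytest.approx(expected)


class TestFilter:
    def test_contained_bicluster_dropped_against_larger(self):
        big = Bicluster(frozenset(f"r{i}" for i in range(10)),
                        tuple(f"c{j}" for j in range(5)), (0,) * 5,
                        p_value=1e-9)
        small = Bicluster(frozenset(f"r{i}" for i in range(8)),
                          tuple(f"c{j}" for j in range(4)), (0,) * 4,
                          p_value=1e-8)
        out = filter_biclusters([big, small], 0.6, 0.01, n_tests=1)
        assert len(out) == 1 and out[0].rows == big.rows

    def test_dissimilar_significant_both_kept(self):
        a = Bicluster(frozenset({"r1", "r2"}), ("c1", "c2"), (0, 0), p_value=1e-9)
        b = Bicluster(frozenset({"r3", "r4"}), ("c3", "c4"), (0, 0), p_value=1e-9)
        assert len(filter_biclusters([a, b], 0.6, 0.01, n_tests=1)) == 2

    def test_all_insignificant_gives_empty_output(self):
        a = Bicluster(frozenset({"r1"}), ("c1", "c2"), (0, 0), p_value=0.5)
        assert filter_biclusters([a], 0.6, 0.01, n_tests=1) == []

    def test_bonferroni_correction_applied(self):
        a = Bicluster(frozenset({"r1"}), ("c1", "c2"), (0, 0), p_value=0.004)
        assert len(filter_biclusters([a], 0.6, 0.01, n_tests=1)) == 1
        assert filter_biclusters([a], 0.6, 0.01, n_tests=10) == []


class TestRunPipeline:
    def small_instance(self, seed=5):
        cfg = SyntheticConfig(n_rows=120, n_cols=20, coherency="constant",
                              k_base=2, row_size=(30, 40), col_size=(4, 5),
                              noisy_fraction=0, missing_fraction=0,
                              overlap=0, seed=seed)
        return generate(cfg)

    def test_recovers_planted_biclusters(self):
        m, gt = self.small_instance()
        sol = run(m, RunConfig(n_items=(3, 5), stop_biclusters=10,
                               max_round_patterns=2000))
        scores = match_score(sol, gt)
        assert scores["recoverability"] >= 0.8

    def test_deterministic_end_to_end(self):
        m, gt = self.small_instance()
        config = RunConfig(n_items=(3, 5), stop_biclusters=10,
                           max_round_patterns=2000)
        s1 = run(m, config)
        s2 = run(m, config)
        assert json.dumps(s1.to_dict(), sort_keys=True) == \
            json.dumps(s2.to_dict(), sort_keys=True)

    def test_stop_after_first_round_with_target_one(self):
        m, gt = self.small_instance()
        sol = run(m, RunConfig(n_items=(5,), stop_biclusters=1,
                               max_round_patterns=2000))
        assert len(sol) >= 1

    def test_uninformative_symbols_absent_from_solutions(self):
        m, gt = self.small_instance(seed=9)
        sol = run(m, RunConfig(n_items=(5,), stop_biclusters=5,
                               removed_symbols=(0,), max_round_patterns=2000))
        for b in sol.biclusters:
            assert 0 not in b.pattern

    def test_unbound_constraint_rejected_before_mining(self):
        m, gt = self.small_instance()
        with pytest.raises(Exception, match="unbound"):
            run(m, RunConfig(n_items=(5,)), constraints=["rows superset {nope}"])

    def test_returned_biclusters_satisfy_constraints(self):
        m, gt = self.small_instance()
        text = "countVal(pattern) >= 2"
        sol = run(m, RunConfig(n_items=(5,), stop_biclusters=10,
                               max_round_patterns=2000), constraints=[text])
        from bic2pam.constraints import parse_constraint

        c = parse_constraint(text)
        for b in sol.biclusters:
            assert c.evaluate(bicluster_to_fullpattern(b))

    def test_annotation_containment_constraint_enforced(self):
        m, gt = self.small_instance(seed=13)
        ann = annotate(gt, m.row_ids, per_row=(3, 1), per_term_rows=(30, 5),
                       consistency=(1.0, 0.0), seed=13)
        term = gt.bicluster_terms[0]
        sol = run(m, RunConfig(n_items=(5,), stop_biclusters=5,
                               max_round_patterns=2000),
                  constraints=[f"pattern contains {{T:{term}}}"],
                  annotations=ann)
        assert len(sol) >= 1
        for b in sol.biclusters:
            assert all(term in ann.entries.get(r, set()) for r in b.rows)
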