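import math

import numpy as np
import pytest
from scipy import stats

from bic2pam import (
    AnnotationMap,
    NumericMatrix,
    append_annotations,
    discretize,
    fit_discretization,
    normalize_rows,
    remove_uninformative,
    to_itemset_db,
    to_sequence_db,
)
from bic2pam.preprocess import (
    align_additive_row,
    ann_item,
    make_alphabet,
    value_item,
)


def mat(rows, values):
    values = np.asarray(values, dtype=float)
    cols = [f"y{j + 1}" for j in range(values.shape[1])]
    return NumericMatrix(rows, cols, values)


class TestNormalize:
    def test_mean_subtraction(self):
        m = normalize_rows(mat(["r"], [[1, 2, 3]]))
        np.testing.assert_allclose(m.values, [[-1, 0, 1]])

    def test_constant_row(self):
        m = normalize_rows(mat(["r"], [[5, 5]]))
        np.testing.assert_allclose(m.values, [[0, 0]])

    def test_missing_cells_ignored_and_untouched(self):
        m = normalize_rows(mat(["r"], [[1, np.nan, 3]]))
        np.testing.assert_allclose(m.values, [[-1, np.nan, 1]])

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        m = mat([f"r{i}" for i in range(5)], rng.normal(2, 3, (5, 8)))
        once = normalize_rows(m)
        twice = normalize_rows(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_all_missing_row_rejected(self):
        with pytest.raises(ValueError, match="r1"):
            normalize_rows(mat(["r1"], [[np.nan, np.nan]]))


class TestDiscretization:
    def test_gaussian_quantile_cutpoints_match_normal_ppf(self):
        rng = np.random.default_rng(0)
        m = mat([f"r{i}" for i in range(100)], rng.normal(0, 1, (100, 10)))
        model = fit_discretization(m, 3)
        obs = m.values.ravel()
        expected = stats.norm.ppf([1 / 3, 2 / 3], loc=obs.mean(), scale=obs.std())
        np.testing.assert_allclose(model.cutpoints, expected)
        # standard normal oracle: cuts near +-0.4307 for mu=0, sigma=1
        assert model.cutpoints[1] == pytest.approx(0.4307, abs=0.1)

    def test_median_split_with_two_items(self):
        rng = np.random.default_rng(1)
        m = mat([f"r{i}" for i in range(50)], rng.normal(0, 1, (50, 10)))
        model = fit_discretization(m, 2)
        assert model.cutpoints[0] == pytest.approx(m.values.mean())

    def test_zero_variance_falls_back_to_equal_width(self):
        m = mat(["r1", "r2"], [[1.0, 1.0], [1.0, 1.0]])
        model = fit_discretization(m, 3, "gaussian_quantile")
        assert model.method == "equal_width"
        sym = discretize(m, model)
        assert set(np.unique(sym.primary)) == {0.0}  # single middle symbol

    def test_alphabet_centered_when_odd(self):
        assert make_alphabet(5) == [-2, -1, 0, 1, 2]
        assert make_alphabet(4) == [-2, -1, 1, 2]

    def test_multi_item_boundary_band(self):
        # uniform values on [0,1], 3 equal-width bins, alpha=0.1: cells within
        # 1/30 of a cutpoint get both adjacent symbols
        vals = np.linspace(0.001, 0.999, 200).reshape(8, 25)
        m = mat([f"r{i}" for i in range(8)], vals)
        model = fit_discretization(m, 3, "equal_width", multi_item_fraction=0.1)
        sym = discretize(m, model)
        lo, hi = 1 / 3 - 1 / 30, 1 / 3 + 1 / 30
        for i in range(8):
            for j in range(25):
                v = vals[i, j]
                near_cut = (lo <= v <= hi) or (1 - hi <= v <= 1 - lo)
                assert ((i, j) in sym.multi) == near_cut, v

    def test_alpha_zero_partitions_cells(self):
        rng = np.random.default_rng(3)
        m = mat([f"r{i}" for i in range(10)], rng.uniform(0, 1, (10, 10)))
        model = fit_discretization(m, 5, multi_item_fraction=0.0)
        sym = discretize(m, model)
        assert sym.multi == {}
        assert not np.isnan(sym.primary).any()

    def test_value_on_cutpoint_gets_both_symbols(self):
        m = mat(["r1", "r2"], [[0.0, 1.0], [2.0, 3.0]])
        model = fit_discretization(m, 3, "equal_width", multi_item_fraction=0.1)
        cut = model.cutpoints[0]
        assert sorted(model.assign(cut)) == sorted(model.assign(cut))  # stable
        assert len(model.assign(cut)) == 2


class TestItemsetMapping:
    def test_constant_concatenates_column_and_symbol(self):
        # row x1 with symbols (6, 5, missing, 3) -> {y1.6, y2.5, y4.3}
        from bic2pam.preprocess import SymbolicMatrix, DiscretizationModel

        model = DiscretizationModel(list(range(10)), np.arange(0.5, 9.0), 9.0,
                                    "equal_width", 0.0)
        prim = np.array([[6.0, 5.0, np.nan, 3.0]])
        sym = SymbolicMatrix(["x1"], ["y1", "y2", "y3", "y4"], prim, {}, model)
        db = to_itemset_db(sym, "constant")
        assert db.transactions["x1"] == frozenset(
            {value_item("y1", 6), value_item("y2", 5), value_item("y4", 3)}
        )

    def test_additive_anchors_at_zero_minimum(self):
        assert align_additive_row([1, 3, 2]) == ([0, 2, 1], 1)
        assert align_additive_row([3, 5, 4]) == ([0, 2, 1], 3)

    def test_additive_db_records_gamma_and_reconstructs(self):
        from bic2pam.preprocess import SymbolicMatrix, DiscretizationModel

        model = DiscretizationModel([0, 1, 2, 3], np.array([0.5, 1.5, 2.5]),
                                    4.0, "equal_width", 0.0)
        prim = np.array([[1.0, 3.0, 2.0], [0.0, 2.0, 1.0]])
        sym = SymbolicMatrix(["x1", "x2"], ["y1", "y2", "y3"], prim, {}, model)
        db = to_itemset_db(sym, "additive")
        assert db.row_factors == {"x1": 1, "x2": 0}
        # re-adding gamma reconstructs the original symbols exactly
        for rid, row in zip(["x1", "x2"], prim):
            items = db.transactions[rid]
            rebuilt = {c: s + db.row_factors[rid] for (_, c, s) in items}
            assert rebuilt == {f"y{j + 1}": row[j] for j in range(3)}

    def test_symmetric_emits_mirrored_transaction(self):
        from bic2pam.preprocess import SymbolicMatrix, DiscretizationModel

        model = DiscretizationModel([-2, -1, 0, 1, 2], np.arange(-1.5, 2.0),
                                    4.0, "equal_width", 0.0)
        prim = np.array([[-2.0, 1.0]])
        sym = SymbolicMatrix(["x1"], ["y1", "y2"], prim, {}, model)
        db = to_itemset_db(sym, "symmetric")
        assert db.transactions["x1"] == frozenset(
            {value_item("y1", -2), value_item("y2", 1)})
        assert db.transactions["~x1"] == frozenset(
            {value_item("y1", 2), value_item("y2", -1)})
        assert db.mirror_of == {"~x1": "x1"}


class TestSequenceMapping:
    def test_ties_share_one_itemset(self):
        db = to_sequence_db(mat(["r"], [[2, 1, 2]]))
        assert db.sequences["r"] == (("y2",), ("y1", "y3"))

    def test_strictly_increasing_row(self):
        db = to_sequence_db(mat(["r"], [[1, 2, 3]]))
        assert db.sequences["r"] == (("y1",), ("y2",), ("y3",))

    def test_all_equal_row_single_itemset(self):
        db = to_sequence_db(mat(["r"], [[4, 4, 4]]))
        assert db.sequences["r"] == (("y1", "y2", "y3"),)

    def test_total_length_equals_observed_columns(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, (6, 7))
        vals[2, 3] = np.nan
        m = mat([f"r{i}" for i in range(6)], vals)
        db = to_sequence_db(m)
        for i, rid in enumerate(m.row_ids):
            n_obs = int(np.count_nonzero(~np.isnan(vals[i])))
            assert sum(len(e) for e in db.sequences[rid]) == n_obs


class TestAnnotationsAndRemoval:
    def _db(self):
        from bic2pam.preprocess import ItemsetDatabase

        return ItemsetDatabase({
            "x1": frozenset({value_item("y1", 0), value_item("y2", 2)}),
            "x2": frozenset({value_item("y1", 1), value_item("y2", 0)}),
            "x3": frozenset({value_item("y1", 0), value_item("y2", 0)}),
        })

    def test_append_annotation_items(self):
        db = append_annotations(self._db(), AnnotationMap({"x3": {"T1", "T2"}}))
        assert ann_item("T1") in db.transactions["x3"]
        assert ann_item("T2") in db.transactions["x3"]
        assert db.transactions["x1"] == self._db().transactions["x1"]

    def test_annotation_universe_growth_bounded_by_terms(self):
        ann = AnnotationMap({f"x{i}": {"T1", "T2", "T3"} for i in (1, 2, 3)})
        base = self._db()
        db = append_annotations(base, ann)
        assert len(db.item_universe) == len(base.item_universe) + 3

    def test_remove_uninformative_drops_items_and_empty_rows(self):
        db = remove_uninformative(self._db(), {0})
        assert "x3" not in db.transactions  # all-zero row dropped
        assert len(db) == 2
        assert db.transactions["x1"] == frozenset({value_item("y2", 2)})

    def test_remove_empty_set_is_identity(self):
        db = self._db()
        assert remove_uninformative(db, set()).transactions == db.transactions
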