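"""Assay matrix, Eq-style scoring, Fisher/t associations, pathway scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import escreen as es
from escreen.assoc import (
    LEL_INACTIVE,
    AssayMatrix,
    DomainError,
    SchemaError,
    association_screen,
    fisher_association,
    load_pathway_map,
    pathway_score,
    ttest_association,
    with_pathway_scores,
)

from conftest import fisher_oracle


def calls_from_fixture(table1):
    calls = table1.copy()
    calls["ac50_M"] = calls["ac50_uM"] * 1e-6
    calls["active"] = True
    return calls


class TestAssayMatrix:
    def test_all_inactive_default_fill(self):
        calls = pd.DataFrame({
            "chemical": ["a", "b", "c"], "endpoint": "cell_loss",
            "ac50_M": 1.0, "active": False,
        })
        m = AssayMatrix.from_calls(calls)
        assert m.values.shape == (3, 4)
        assert (m.values.to_numpy() == 1.0).all()

    def test_fixture_has_56_rows_with_activity(self, table1):
        m = AssayMatrix.from_calls(calls_from_fixture(table1))
        assert m.values.shape[0] == 56
        assert ((m.values < 1.0).any(axis=1)).all()

    def test_csv_roundtrip(self, tmp_path, table1):
        m = AssayMatrix.from_calls(calls_from_fixture(table1))
        path = tmp_path / "matrix.csv"
        m.to_csv(path)
        back = AssayMatrix.read_csv(path)
        pd.testing.assert_frame_equal(m.values, back.values)
        assert m.kinds == back.kinds

    def test_duplicate_columns_rejected(self):
        calls = pd.DataFrame({"chemical": ["a"], "endpoint": ["cell_loss"],
                              "ac50_M": [1e-6], "active": [True]})
        extra = pd.DataFrame({"cell_loss": [1.0]}, index=pd.Index(["a"], name="chemical"))
        with pytest.raises(SchemaError):
            AssayMatrix.from_calls(calls, extra=extra)

    def test_dichotomize(self):
        df = pd.DataFrame({"a": [1.0, 1e-6], "lel_b": [LEL_INACTIVE, 250.0]},
                          index=pd.Index(["x", "y"], name="chemical"))
        binary = AssayMatrix(df).dichotomize()
        assert binary["a"].tolist() == [0, 1]
        assert binary["lel_b"].tolist() == [0, 1]

    def test_scale_scores_values(self):
        df = pd.DataFrame({"a": [1.0, 1e-6, 1.25e-5]},
                          index=pd.Index(list("xyz"), name="chemical"))
        scores = AssayMatrix(df).scale_scores()
        assert scores["a"].tolist() == pytest.approx([0.0, 6.0, 4.903089986991944])

    def test_scale_scores_rejects_nonpositive(self):
        df = pd.DataFrame({"a": [0.0]}, index=pd.Index(["x"], name="chemical"))
        with pytest.raises(DomainError):
            AssayMatrix(df).scale_scores()

    def test_score_positive_iff_dichotomized_active(self, table1):
        m = AssayMatrix.from_calls(calls_from_fixture(table1))
        assert ((m.scale_scores() > 0).astype(int) == m.dichotomize()).all().all()


class TestFisher:
    def test_perfect_split_matches_enumeration(self):
        r = fisher_association([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert r.p_value == pytest.approx(2 / 252, abs=1e-12)
        assert r.p_value == pytest.approx(fisher_oracle(5, 0, 0, 5), abs=1e-12)

    def test_degenerate_output_flagged(self):
        r = fisher_association([1, 0, 1, 0], [0, 0, 0, 0])
        assert r.p_value == 1.0 and r.degenerate

    @pytest.mark.parametrize("table", [(2, 1, 1, 2), (3, 0, 1, 3), (1, 2, 3, 1),
                                       (4, 4, 0, 0), (2, 2, 2, 2)])
    def test_small_tables_match_oracle(self, table):
        TP, FP, FN, TN = table
        x = [1] * (TP + FP) + [0] * (FN + TN)
        y = [1] * TP + [0] * FP + [1] * FN + [0] * TN
        r = fisher_association(x, y)
        if not r.degenerate:
            assert r.p_value == pytest.approx(fisher_oracle(*table), abs=1e-12)


class TestTtest:
    def test_identical_groups(self):
        r = ttest_association([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_variance_guarded(self):
        r = ttest_association([0, 0, 0, 0, 6, 6, 6, 6], [0, 0, 0, 0, 1, 1, 1, 1])
        assert r.degenerate
        assert np.isinf(r.statistic)
        assert r.p_value == 0.0

    def test_small_group_not_testable(self):
        r = ttest_association([1.0, 2.0, 3.0], [1, 0, 0])
        assert not r.testable

    def test_type_one_error_rate(self):
        """Null rejection rate at p<=0.05 stays near nominal (Welch t)."""
        rng = np.random.default_rng(321)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            scores = rng.normal(size=100)
            labels = rng.integers(0, 2, size=100)
            if labels.sum() < 2 or labels.sum() > 98:
                continue
            r = ttest_association(scores, labels)
            rejections += r.p_value <= 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestPathwayScore:
    MATRIX = AssayMatrix(pd.DataFrame(
        {"a1": [1e-6, 1.0], "a2": [1e-7, 1.0], "a3": [1.0, 1.0]},
        index=pd.Index(["x", "y"], name="chemical")))

    def test_minimum_rule(self):
        ps = pathway_score(self.MATRIX, {"pw": ["a1", "a2", "a3"]})
        assert ps.loc["x", "ps_pw"] == pytest.approx(1e-7)
        assert ps.loc["y", "ps_pw"] == 1.0

    def test_singleton_identity(self):
        ps = pathway_score(self.MATRIX, {"pw": ["a1"]})
        assert (ps["ps_pw"] == self.MATRIX.values["a1"]).all()

    def test_empty_pathway_rejected(self):
        with pytest.raises(SchemaError):
            load_pathway_map({"pw": []})

    def test_unknown_column_rejected(self):
        with pytest.raises(SchemaError):
            pathway_score(self.MATRIX, {"pw": ["nope"]})

    def test_conservation_never_below_members(self):
        augmented = with_pathway_scores(self.MATRIX, {"pw": ["a1", "a2"]})
        ps = augmented.values["ps_pw"]
        assert (ps == self.MATRIX.values[["a1", "a2"]].min(axis=1)).all()


class TestAssociationScreen:
    def _planted_matrix(self, seed=9, n=40):
        rng = np.random.default_rng(seed)
        vals = np.where(rng.uniform(size=(n, 5)) < 0.5,
                        10.0 ** rng.uniform(-7, -5, size=(n, 5)), 1.0)
        df = pd.DataFrame(vals, columns=[f"in{i}" for i in range(5)],
                          index=pd.Index([f"c{i}" for i in range(n)], name="chemical"))
        df["lel_out"] = np.where(df["in2"] < 1.0, 100.0, LEL_INACTIVE)
        return AssayMatrix(df)

    def test_planted_association_ranks_first(self):
        m = self._planted_matrix()
        res = association_screen(m, inputs=[f"in{i}" for i in range(5)],
                                 outputs=["lel_out"])
        assert res.iloc[0]["input"] == "in2"
        assert res.iloc[0]["significant"]
        assert res["p"].is_monotonic_increasing

    def test_empty_outputs_gives_empty_table(self):
        m = self._planted_matrix()
        res = association_screen(m, inputs=["in0"], outputs=[])
        assert res.empty

    def test_identical_column_pairs_skipped(self):
        m = self._planted_matrix()
        res = association_screen(m, inputs=["in0"], outputs=["in0"])
        assert res.empty

    def test_unknown_column_raises(self):
        m = self._planted_matrix()
        with pytest.raises(SchemaError):
            association_screen(m, inputs=["nope"], outputs=["lel_out"])

    def test_bh_adjustment_monotone(self):
        m = self._planted_matrix()
        res = association_screen(m, bh_adjust=True)
        assert (res["p_adj"] >= res["p"] - 1e-15).all()


@given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6), st.integers(0, 6))
@settings(max_examples=60, deadline=None)
def test_fisher_matches_oracle_property(TP, FP, FN, TN):
    if TP + FP + FN + TN == 0:
        return
    x = [1] * (TP + FP) + [0] * (FN + TN)
    y = [1] * TP + [0] * FP + [1] * FN + [0] * TN
    r = fisher_association(x, y)
    if not r.degenerate:
        assert r.p_value == pytest.approx(fisher_oracle(TP, FP, FN, TN), abs=1e-12)
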