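import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sentisess.agreement import (
    ContingencyTable,
    build_table,
    icc_a1,
    interpret_icc,
    interpret_kappa,
    per_patient_icc,
    weighted_kappa,
)
from sentisess.calibration import RatingSet
from sentisess.preprocess import SessionRecord
from sentisess.scorer import score_record

from .oracles import oracle_icc_a1, oracle_weighted_kappa

# Printed human-vs-human 3x3 contingency counts used as a worked example
TABLE2 = np.array([[106, 14, 5], [14, 43, 4], [7, 13, 57]])


class TestContingencyTable:
    def test_perfect_agreement_diagonal(self):
        cats = {f"r{i}": c for i, c in enumerate(["negative"] * 4 + ["neutral"] * 3 + ["positive"] * 3)}
        t = build_table(cats, cats)
        assert np.array_equal(np.diag(t.counts), [4, 3, 3])
        assert t.counts.sum() == 10

    def test_published_table_margins(self):
        t = ContingencyTable(TABLE2)
        assert t.n == 263
        assert t.row_totals().tolist() == [125, 61, 77]
        assert t.column_totals().tolist() == [127, 70, 66]

    def test_column_and_margin_percentages(self):
        t = ContingencyTable(TABLE2)
        assert t.column_percentages()[0, 0] == pytest.approx(100 * 106 / 127)
        rows_pct, cols_pct = t.margin_percentages()
        assert rows_pct[0] == pytest.approx(100 * 125 / 263)

    def test_disjoint_ids_error(self):
        with pytest.raises(ValueError):
            build_table({"a": "neutral"}, {"b": "neutral"})


class TestWeightedKappa:
    @pytest.mark.parametrize("scheme", ["unweighted", "linear", "quadratic"])
    def test_perfect_agreement_is_one(self, scheme):
        t = ContingencyTable(np.diag([10, 10, 10]))
        assert weighted_kappa(t, scheme).estimate == pytest.approx(1.0)

    def test_independence_is_zero(self):
        counts = np.zeros((3, 3), int)
        counts[:2, :2] = 25
        t = ContingencyTable(counts)
        assert weighted_kappa(t, "linear").estimate == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "scheme,expected",
        [("unweighted", 0.6588), ("linear", 0.7072), ("quadratic", 0.7505)],
    )
    def test_published_table_against_oracle(self, scheme, expected):
        t = ContingencyTable(TABLE2)
        est = weighted_kappa(t, scheme)
        assert est.estimate == pytest.approx(oracle_weighted_kappa(TABLE2, scheme), abs=1e-12)
        assert est.estimate == pytest.approx(expected, abs=5e-4)

    def test_se_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.inter_rater")
        for scheme, wt in [("unweighted", None), ("linear", "linear"), ("quadratic", "quadratic")]:
            est = weighted_kappa(ContingencyTable(TABLE2), scheme)
            ref = statsmodels.cohens_kappa(TABLE2, wt=wt)
            assert est.estimate == pytest.approx(ref.kappa, abs=1e-12)
            assert est.se == pytest.approx(np.sqrt(ref.var_kappa), abs=1e-12)

    def test_transpose_symmetry(self):
        for scheme in ("unweighted", "linear", "quadratic"):
            a = weighted_kappa(ContingencyTable(TABLE2), scheme).estimate
            b = weighted_kappa(ContingencyTable(TABLE2.T), scheme).estimate
            assert a == pytest.approx(b)

    def test_scale_invariance_and_se_shrinks(self):
        t1 = ContingencyTable(TABLE2)
        t4 = ContingencyTable(TABLE2 * 4)
        e1, e4 = weighted_kappa(t1, "linear"), weighted_kappa(t4, "linear")
        assert e1.estimate == pytest.approx(e4.estimate)
        assert e4.se == pytest.approx(e1.se / 2.0)

    def test_degenerate_single_category_error(self):
        counts = np.zeros((3, 3), int)
        counts[0, 0] = 50
        with pytest.raises(ValueError):
            weighted_kappa(ContingencyTable(counts), "linear")

    def test_ci_contains_estimate(self):
        est = weighted_kappa(ContingencyTable(TABLE2), "linear")
        assert est.ci_lo <= est.estimate <= est.ci_hi
        assert est.interpretation == "substantial"


class TestIccA1:
    def test_identical_columns_exact_agreement(self):
        x = np.array([[1, 1], [2, 2], [3, 3], [4, 4]], float)
        est = icc_a1(x)
        assert est.estimate == 1.0
        assert (est.ci_lo, est.ci_hi) == (1.0, 1.0)

    def test_constant_offset_penalized(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        est = icc_a1(x)
        assert est.estimate == pytest.approx(10 / 13)
        assert est.estimate < 1.0

    def test_hand_matrix_equals_sums_of_squares_oracle(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        assert icc_a1(x).estimate == pytest.approx(oracle_icc_a1(x), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_random_small_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        x = rng.normal(size=(n, 2))
        assert icc_a1(x).estimate == pytest.approx(oracle_icc_a1(x), abs=1e-10)

    def test_matches_published_closed_form_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 2))
        x[:, 1] = 0.8 * x[:, 0] + 0.4 * x[:, 1]
        est = icc_a1(x)
        df = pd.DataFrame(
            {
                "t": np.repeat(np.arange(15), 2),
                "r": np.tile([0, 1], 15),
                "y": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "t", "r", "y").set_index("Type").loc["ICC(A,1)"]
        assert est.estimate == pytest.approx(ref["ICC"], abs=1e-10)
        assert est.f_value == pytest.approx(ref["F"], abs=1e-10)
        assert (est.df1, est.df2) == (ref["df1"], ref["df2"])

    def test_pairwise_deletion(self):
        x = np.array([[1.0, 1.1], [2.0, np.nan], [3.0, 2.9], [4.0, 4.2], [5.0, 4.8]])
        est = icc_a1(x)
        assert est.n_pairs == 4
        assert est.df1 == 3

    def test_minimum_pairs_and_degenerate_errors(self):
        with pytest.raises(ValueError):
            icc_a1(np.array([[1.0, 2.0], [2.0, 3.0]]))
        with pytest.raises(ValueError):
            icc_a1(np.full((5, 2), 3.0))

    def test_f_dfs_follow_pair_count(self):
        rng = np.random.default_rng(0)
        est = icc_a1(rng.normal(size=(50, 2)))
        assert (est.df1, est.df2) == (49, 49)


class TestInterpretations:
    @pytest.mark.parametrize(
        "value,label",
        [(-0.1, "none"), (0.1, "slight"), (0.29, "fair"), (0.5, "moderate"), (0.68, "substantial"), (0.9, "almost perfect")],
    )
    def test_kappa_bands(self, value, label):
        assert interpret_kappa(value) == label

    @pytest.mark.parametrize(
        "value,label",
        [(0.4, "poor"), (0.6, "moderate"), (0.8, "good"), (0.95, "excellent")],
    )
    def test_icc_bands(self, value, label):
        assert interpret_icc(value) == label


class TestPerPatientIcc:
    def _results(self, tiny_lex, per_patient):
        results = []
        rng = np.random.default_rng(7)
        idx = 0
        for pid, n in per_patient.items():
            for seq in range(1, n + 1):
                idx += 1
                sentiment = ["goed"] if rng.random() < 0.5 else ["slecht"]
                if rng.random() < 0.3:
                    sentiment = ["niet"] + sentiment
                tokens = ["aa", "bb", "cc", "dd"] + sentiment
                rec = SessionRecord(f"r{idx}", pid, seq, " ".join(tokens), tokens=tuple(tokens))
                results.append(score_record(rec, tiny_lex))
        return results

    def test_affine_aligned_rater_gives_icc_one_and_small_patients_skipped(self, tiny_lex):
        results = self._results(tiny_lex, {"p1": 20, "p2": 2})
        # automated overalls here are exactly +1 or -1, so the rater scores
        # 4 + 2*overall are an exact affine image: both series standardize to
        # the identical pooled z-series and each per-patient ICC is 1
        scores = {
            r.record_id: int(4 + 2 * r.overall) for r in results if r.relevant_auto
        }
        out = per_patient_icc(results, RatingSet("r1", scores))
        assert "p2" not in out  # below the 3-pair minimum
        est = out["p1"]
        assert est.estimate == pytest.approx(1.0)
        assert est.df1 == est.df2 == est.n_pairs - 1
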