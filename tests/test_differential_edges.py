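"""Signed DCE calling, cross-cohort overlap and sign-proportion summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcenet import (
    AdjacencyMatrix,
    DceParams,
    ExpressionMatrix,
    concordance_summary,
    correlation_matrix,
    identify_dces,
    overlap_dce_sets,
    sign_proportion,
    signed_adjacency_difference,
    soft_threshold_adjacency,
)
from dcenet.differential_edges import dces_from_adjacencies
from dcenet.errors import ParameterError, ValidationError
from conftest import PUBLISHED_OVERLAP_EDGES, brute_force_dces, dce_set_from_signs


def adj_from(matrix, beta=6, label=""):
    n = matrix.shape[0]
    return AdjacencyMatrix(tuple(f"G{i}" for i in range(n)), matrix, beta, label)


def delta_frame(deltas, ids=None):
    deltas = np.asarray(deltas, dtype=float)
    ids = ids or [f"G{i}" for i in range(deltas.shape[0])]
    return pd.DataFrame(deltas, index=ids, columns=ids)


class TestSignedAdjacencyDifference:
    def test_elementwise_difference(self):
        a_d = np.array([[0.0, 0.531441], [0.531441, 0.0]])
        a_c = np.array([[0.0, 0.000064], [0.000064, 0.0]])
        delta = signed_adjacency_difference(adj_from(a_d), adj_from(a_c))
        assert delta.iloc[0, 1] == pytest.approx(0.531377)

    def test_identical_groups_give_zero(self):
        a = np.array([[0.0, 0.4], [0.4, 0.0]])
        delta = signed_adjacency_difference(adj_from(a), adj_from(a.copy()))
        assert (delta.to_numpy() == 0).all()

    def test_negative_delta_when_control_stronger(self):
        a_d = np.array([[0.0, 0.1], [0.1, 0.0]])
        a_c = np.array([[0.0, 0.4], [0.4, 0.0]])
        delta = signed_adjacency_difference(adj_from(a_d), adj_from(a_c))
        assert delta.iloc[0, 1] == pytest.approx(-0.3)

    def test_feature_mismatch_lists_symmetric_difference(self):
        a = np.zeros((2, 2))
        adj_x = AdjacencyMatrix(("A", "B"), a, 6)
        adj_y = AdjacencyMatrix(("A", "C"), a, 6)
        with pytest.raises(ValidationError, match="B, C"):
            signed_adjacency_difference(adj_x, adj_y)

    def test_beta_mismatch_rejected(self):
        a = np.zeros((2, 2))
        with pytest.raises(ValidationError, match="beta"):
            signed_adjacency_difference(adj_from(a, beta=6), adj_from(a, beta=4))


class TestIdentifyDces:
    def test_edge_above_cutoff_called_with_positive_sign(self):
        d = delta_frame([[0, 0.531377], [0.531377, 0]])
        result = identify_dces(d, DceParams(cutoff=0.3))
        assert len(result) == 1
        rec = result.records[("G0", "G1")]
        assert rec.sign == 1

    def test_boundary_delta_excluded_by_strict_inequality(self):
        d = delta_frame([[0, 0.30], [0.30, 0]])
        assert len(identify_dces(d, DceParams(cutoff=0.3))) == 0

    def test_high_vs_moderate_correlation_pair_is_a_dce(self):
        # |r| = 0.85 in disease, 0.30 in control at beta = 6
        delta = 0.85**6 - 0.30**6
        d = delta_frame([[0, delta], [delta, 0]])
        result = identify_dces(d, DceParams(cutoff=0.3))
        assert delta == pytest.approx(0.3764205156, abs=1e-9)
        assert len(result) == 1

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ParameterError):
            DceParams(cutoff=1.5)
        with pytest.raises(ParameterError):
            DceParams(cutoff=0.0)

    def test_raising_cutoff_never_adds_edges(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(-0.9, 0.9, size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        d = delta_frame(m)
        low = identify_dces(d, DceParams(cutoff=0.2)).edges()
        high = identify_dces(d, DceParams(cutoff=0.5)).edges()
        assert high <= low

    def test_permutation_invariance_of_edge_set(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(-0.9, 0.9, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        ids = [f"G{i}" for i in range(6)]
        perm = [4, 2, 0, 5, 1, 3]
        d = delta_frame(m, ids)
        d_perm = delta_frame(m[np.ix_(perm, perm)], [ids[i] for i in perm])
        set_a = identify_dces(d, DceParams(cutoff=0.3))
        set_b = identify_dces(d_perm, DceParams(cutoff=0.3))
        assert set_a.edges() == set_b.edges()
        for e in set_a.edges():
            assert set_a.records[e].sign == set_b.records[e].sign

    def test_sign_times_delta_is_absolute_delta(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(-0.9, 0.9, size=(10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        result = identify_dces(delta_frame(m), DceParams(cutoff=0.3))
        assert len(result) > 0
        for rec in result.records.values():
            assert rec.sign * rec.delta == abs(rec.delta)
            assert abs(rec.delta) > 0.3

    def test_matches_brute_force_oracle_on_random_two_group_data(self):
        rng = np.random.default_rng(99)
        params = DceParams(cutoff=0.3, beta=6)
        ids = tuple(f"G{i:02d}" for i in range(12))
        for _ in range(10):
            xd = rng.normal(size=(12, 10))
            xc = rng.normal(size=(12, 10))
            samples_d = tuple(f"d{k}" for k in range(10))
            samples_c = tuple(f"c{k}" for k in range(10))
            expr_d = ExpressionMatrix(ids, samples_d, xd)
            expr_c = ExpressionMatrix(ids, samples_c, xc)
            adj_d = soft_threshold_adjacency(correlation_matrix(expr_d), 6, "disease")
            adj_c = soft_threshold_adjacency(correlation_matrix(expr_c), 6, "control")
            called = dces_from_adjacencies(adj_d, adj_c, params)
            oracle = brute_force_dces(expr_d, expr_c, beta=6, cutoff=0.3)
            assert {e: r.sign for e, r in called.records.items()} == oracle


class TestOverlapAndConcordance:
    def test_shared_edge_same_sign_classified_same(self):
        set_pd = dce_set_from_signs([("FLJ40288", "LOC101928144", 1)], "PD")
        set_cc = dce_set_from_signs([("FLJ40288", "LOC101928144", 1)], "CC")
        report = overlap_dce_sets(set_pd, set_cc)
        assert report.n_shared == 1 and report.n_same == 1

    def test_shared_edge_opposite_sign_classified_opposite(self):
        set_pd = dce_set_from_signs([("LINC01365", "LINC00868", -1)], "PD")
        set_cc = dce_set_from_signs([("LINC01365", "LINC00868", 1)], "CC")
        report = overlap_dce_sets(set_pd, set_cc)
        assert report.n_opposite == 1 and report.n_same == 0

    def test_disjoint_sets_give_empty_report(self):
        set_a = dce_set_from_signs([("A", "B", 1)], "A")
        set_b = dce_set_from_signs([("C", "D", -1)], "B")
        report = overlap_dce_sets(set_a, set_b)
        summary = concordance_summary(report)
        assert summary == {
            "n_shared": 0,
            "n_opposite": 0,
            "n_same": 0,
            "proportion_opposite": 0.0,
        }

    def test_overlap_symmetric_with_swapped_sign_columns(self):
        edges_a = [("A", "B", 1), ("C", "D", -1), ("E", "F", 1)]
        edges_b = [("A", "B", -1), ("C", "D", -1), ("X", "Y", 1)]
        set_a = dce_set_from_signs(edges_a, "A")
        set_b = dce_set_from_signs(edges_b, "B")
        fwd = overlap_dce_sets(set_a, set_b)
        rev = overlap_dce_sets(set_b, set_a)
        assert [e for e, _, _ in fwd.shared_edges] == [
            e for e, _, _ in rev.shared_edges
        ]
        assert [(sa, sb) for _, sa, sb in fwd.shared_edges] == [
            (sb, sa) for _, sa, sb in rev.shared_edges
        ]

    def test_report_rows_sorted_by_edge(self):
        edges = [("Z", "Y", 1), ("A", "B", 1), ("M", "N", -1)]
        set_a = dce_set_from_signs(edges, "A")
        set_b = dce_set_from_signs(edges, "B")
        report = overlap_dce_sets(set_a, set_b)
        keys = [e for e, _, _ in report.shared_edges]
        assert keys == sorted(keys)

    def test_all_opposite_proportion_is_one(self):
        edges_a = [(f"G{i}", f"H{i}", 1) for i in range(4)]
        edges_b = [(f"G{i}", f"H{i}", -1) for i in range(4)]
        report = overlap_dce_sets(
            dce_set_from_signs(edges_a, "A"), dce_set_from_signs(edges_b, "B")
        )
        assert concordance_summary(report)["proportion_opposite"] == 1.0

    def test_published_sixteen_edge_table_concordance(self):
        set_pd = dce_set_from_signs(
            [(a, b, s_pd) for a, b, s_pd, _ in PUBLISHED_OVERLAP_EDGES], "PD"
        )
        set_cc = dce_set_from_signs(
            [(a, b, s_cc) for a, b, _, s_cc in PUBLISHED_OVERLAP_EDGES], "CC"
        )
        summary = concordance_summary(overlap_dce_sets(set_pd, set_cc))
        assert summary["n_shared"] == 16
        assert summary["n_opposite"] == 15
        assert summary["n_same"] == 1


class TestSignProportion:
    def test_half_and_half(self):
        s = dce_set_from_signs([("A", "B", 1), ("C", "D", -1)], "x")
        props = sign_proportion(s)
        assert props["pct_negative"] == 50.00
        assert props["pct_positive"] == 50.00

    def test_empty_set_flagged(self):
        s = dce_set_from_signs([], "x")
        props = sign_proportion(s)
        assert props["empty"] is True
        assert props["n_total"] == 0 and props["pct_negative"] == 0.0

    def test_two_decimal_rounding_half_away_from_zero(self):
        # 1/3 positive -> 33.33; 2/3 negative -> 66.67
        s = dce_set_from_signs(
            [("A", "B", 1), ("C", "D", -1), ("E", "F", -1)], "x"
        )
        props = sign_proportion(s)
        assert props["pct_positive"] == 33.33
        assert props["pct_negative"] == 66.67

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n_pos=st.integers(0, 40),
        n_neg=st.integers(0, 40),
    )
    def test_counts_always_sum_to_total(self, n_pos, n_neg):
        edges = [(f"P{i}", f"Q{i}", 1) for i in range(n_pos)] + [
            (f"R{i}", f"S{i}", -1) for i in range(n_neg)
        ]
        props = sign_proportion(dce_set_from_signs(edges, "x"))
        assert props["n_positive"] + props["n_negative"] == props["n_total"]
        if props["n_total"]:
            assert props["pct_positive"] + props["pct_negative"] == pytest.approx(
                100.0, abs=0.011
            )
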