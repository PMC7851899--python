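"""Shared fixtures: small expression matrices and a brute-force DCE oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcenet import (
    DceParams,
    DceRecord,
    DceSet,
    ExpressionMatrix,
    SampleAnnotation,
)
from dcenet.differential_edges import canonical_edge

# The 16 cross-disease overlap edges published for the Parkinson's (PD) vs
# colon cancer (CC) comparison, with their reported connectivity signs:
# sign -1 = loss of connectivity in disease, +1 = gain.
PUBLISHED_OVERLAP_EDGES = [
    # (node1, node2, sign_PD, sign_CC)
    ("FLJ40288", "LOC101928144", 1, 1),
    ("LINC01365", "LINC00868", -1, 1),
    ("LINC01210", "LOC101929441", -1, 1),
    ("MIR4300HG", "LINC00523", -1, 1),
    ("LINC00642", "LOC101928443", -1, 1),
    ("LINC00642", "MIR4313", -1, 1),
    ("LOC105375875", "PRRX2-AS1", -1, 1),
    ("LOC101929657", "SLFNL1-AS1", -1, 1),
    ("LOC101928443", "MIR4313", -1, 1),
    ("LOC101928443", "LOC283194", -1, 1),
    ("OGFRP1", "LOC100996694", -1, 1),
    ("NAV2-AS5", "LOC101929441", -1, 1),
    ("LOC101928476", "LOC101929441", -1, 1),
    ("LOC283194", "GABRG3-AS1", -1, 1),
    ("DTX2P1-UPK3BP1-PMS2P11", "MORC2-AS1", -1, 1),
    ("MIR100HG", "LOC339803", -1, 1),
]


def dce_set_from_signs(edge_signs, cohort: str, cutoff: float = 0.3) -> DceSet:
    """Build a DCE-set stub from (node1, node2, sign) rows.

    Magnitudes are not part of the published table, so each record carries a
    delta of +/-0.5 -- comfortably beyond the default cutoff -- purely to
    satisfy the record invariants.  Only edge identity and sign matter.
    """
    params = DceParams(cutoff=cutoff)
    records = {}
    for node1, node2, sign in edge_signs:
        edge = canonical_edge(node1, node2)
        delta = 0.5 * sign
        records[edge] = DceRecord(
            edge=edge,
            adj_disease=max(delta, 0.0),
            adj_control=max(-delta, 0.0),
            delta=delta,
            sign=sign,
        )
    return DceSet(cohort_label=cohort, params=params, records=records)


def brute_force_dces(
    expr_disease: ExpressionMatrix,
    expr_control: ExpressionMatrix,
    beta: int,
    cutoff: float,
    method: str = "spearman",
):
    """Independent per-pair oracle: correlate, power, subtract, threshold.

    Returns {canonical edge: sign} using scipy per-pair correlation, with no
    shared code path with the matrix implementation.
    """
    assert expr_disease.feature_ids == expr_control.feature_ids
    ids = expr_disease.feature_ids
    xd = np.array(expr_disease.values)
    xc = np.array(expr_control.values)
    out = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if method == "spearman":
                rd = stats.spearmanr(xd[i], xd[j]).statistic
                rc = stats.spearmanr(xc[i], xc[j]).statistic
            else:
                rd = stats.pearsonr(xd[i], xd[j]).statistic
                rc = stats.pearsonr(xc[i], xc[j]).statistic
            rd = 0.0 if np.isnan(rd) else rd
            rc = 0.0 if np.isnan(rc) else rc
            delta = abs(rd) ** beta - abs(rc) ** beta
            if abs(delta) > cutoff:
                out[canonical_edge(ids[i], ids[j])] = 1 if delta > 0 else -1
    return out


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 5 samples with simple hand-checkable values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 1.0, 4.0, 3.0, 5.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
        ]
    )
    return ExpressionMatrix(("GA", "GB", "GC"), ("s1", "s2", "s3", "s4", "s5"), values)


@pytest.fixture
def two_group_annotation() -> SampleAnnotation:
    table = pd.DataFrame(
        {
            "sample_id": ["d1", "d2", "d3", "c1", "c2", "c3"],
            "group": ["disease"] * 3 + ["control"] * 3,
            "cohort": ["coh1"] * 6,
        }
    )
    return SampleAnnotation(table)
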