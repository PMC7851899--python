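"""Signed differentially correlated edge (DCE) calling and cross-cohort overlap.

An edge (i, j) is differentially correlated when the absolute difference of
its soft-threshold adjacencies between disease and control exceeds a fixed
cutoff (default 0.3, corresponding roughly to a strong correlation, |r| above
about 0.8, in one group versus a mild-to-moderate one in the other at
beta = 6).  The sign of ``a_disease - a_control`` classifies the edge: +1 is
a gain of connectivity in disease, -1 a loss.

Note the statistic is built on |r|**beta, so it is blind to pure sign flips
of the correlation (r = +0.9 vs -0.9 gives identical adjacency).  The
per-group correlation signs can be carried along as a diagnostic; the edge
statistic itself never uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dcenet.coexpression import AdjacencyMatrix
from dcenet.errors import ParameterError, ValidationError

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Unordered pair stored with the lexicographically smaller id first."""
    if a == b:
        raise ValidationError(f"self-edge on '{a}' is not allowed")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class DceParams:
    """Threshold on \\|adjacency difference\\| plus the network parameters."""

    cutoff: float = 0.3
    beta: int = 6
    method: str = "spearman"

    def __post_init__(self):
        if not (0.0 < self.cutoff < 1.0):
            raise ParameterError(
                f"cutoff must lie strictly in (0, 1), got {self.cutoff}"
            )


@dataclass(frozen=True)
class DceRecord:
    """One differentially correlated edge with its per-group adjacencies.

    ``sign`` is +1 for a connectivity gain in disease, -1 for a loss;
    ``corr_sign_disease``/``corr_sign_control`` are optional diagnostics
    recording the sign of the underlying correlation in each group.
    """

    edge: Edge
    adj_disease: float
    adj_control: float
    delta: float
    sign: int
    corr_sign_disease: int | None = None
    corr_sign_control: int | None = None

    def __post_init__(self):
        if self.edge != canonical_edge(*self.edge):
            raise ValidationError(f"edge {self.edge} is not in canonical order")
        if self.sign not in (-1, 1):
            raise ValidationError(f"sign must be -1 or +1, got {self.sign}")
        if self.sign * self.delta <= 0:
            raise ValidationError(
                f"sign {self.sign} inconsistent with delta {self.delta}"
            )


@dataclass(frozen=True)
class DceSet:
    """All DCEs of one cohort, keyed by canonical edge."""

    cohort_label: str
    params: DceParams
    records: dict[Edge, DceRecord] = field(repr=False)

    def __post_init__(self):
        for edge, rec in self.records.items():
            if edge != rec.edge:
                raise ValidationError(f"record keyed {edge} but holds {rec.edge}")
            if abs(rec.delta) <= self.params.cutoff:
                raise ValidationError(
                    f"edge {edge}: |delta| = {abs(rec.delta)} does not exceed "
                    f"cutoff {self.params.cutoff}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records.values() if r.sign > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records.values() if r.sign < 0)

    def edges(self) -> set[Edge]:
        return set(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node1": r.edge[0],
                "node2": r.edge[1],
                "adj_disease": r.adj_disease,
                "adj_control": r.adj_control,
                "delta": r.delta,
                "sign": r.sign,
            }
            for r in sorted(self.records.values(), key=lambda r: r.edge)
        ]
        return pd.DataFrame(
            rows,
            columns=["node1", "node2", "adj_disease", "adj_control", "delta", "sign"],
        )


@dataclass(frozen=True)
class OverlapReport:
    """Edges present in two cohorts' DCE sets, with both signs."""

    shared_edges: tuple[tuple[Edge, int, int], ...]  # (edge, sign_A, sign_B)
    cohort_a: str = "A"
    cohort_b: str = "B"

    @property
    def n_shared(self) -> int:
        return len(self.shared_edges)

    @property
    def n_same(self) -> int:
        return sum(1 for _, sa, sb in self.shared_edges if sa == sb)

    @property
    def n_opposite(self) -> int:
        return sum(1 for _, sa, sb in self.shared_edges if sa != sb)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node1": e[0],
                "node2": e[1],
                f"sign_{self.cohort_a}": sa,
                f"sign_{self.cohort_b}": sb,
                "concordance": "same" if sa == sb else "opposite",
            }
            for e, sa, sb in self.shared_edges
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "node1",
                "node2",
                f"sign_{self.cohort_a}",
                f"sign_{self.cohort_b}",
                "concordance",
            ],
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def signed_adjacency_difference(
    adj_disease: AdjacencyMatrix, adj_control: AdjacencyMatrix
) -> pd.DataFrame:
    """Delta_ij = a_disease_ij - a_control_ij as a symmetric DataFrame."""
    if adj_disease.feature_ids != adj_control.feature_ids:
        missing = sorted(
            set(adj_disease.feature_ids) ^ set(adj_control.feature_ids)
        )
        raise ValidationError(
            "adjacency matrices disagree on features; symmetric difference: "
            + (", ".join(missing) if missing else "(same set, different order)")
        )
    if adj_disease.beta != adj_control.beta:
        raise ValidationError(
            f"beta mismatch: {adj_disease.beta} vs {adj_control.beta}"
        )
    delta = np.array(adj_disease.values) - np.array(adj_control.values)
    ids = list(adj_disease.feature_ids)
    return pd.DataFrame(delta, index=ids, columns=ids)


def identify_dces(
    delta: pd.DataFrame,
    params: DceParams,
    cohort_label: str = "",
    corr_disease: pd.DataFrame | None = None,
    corr_control: pd.DataFrame | None = None,
) -> DceSet:
    """Call edges with \\|delta\\| strictly greater than the cutoff.

    The inequality is strict, so boundary edges (|delta| exactly equal to the
    cutoff) are excluded, and a zero delta can never produce a record --
    every record's sign is therefore well-defined in {-1, +1}.

    If per-group correlation matrices are supplied, each record also carries
    the sign of the underlying correlation in each group as a diagnostic.
    """
    ids = list(delta.index)
    if list(delta.columns) != ids:
        raise ValidationError("delta matrix rows and columns disagree")
    vals = delta.to_numpy(dtype=float)
    if np.abs(vals - vals.T).max(initial=0.0) > 1e-12:
        raise ValidationError("delta matrix is not symmetric")

    iu, ju = np.triu_indices(len(ids), k=1)
    hits = np.abs(vals[iu, ju]) > params.cutoff
    records: dict[Edge, DceRecord] = {}
    for i, j in zip(iu[hits], ju[hits]):
        d = float(vals[i, j])
        edge = canonical_edge(ids[i], ids[j])
        csd = ccs = None
        if corr_disease is not None:
            csd = int(np.sign(corr_disease.iat[i, j])) or 1
        if corr_control is not None:
            ccs = int(np.sign(corr_control.iat[i, j])) or 1
        records[edge] = DceRecord(
            edge=edge,
            adj_disease=float("nan"),
            adj_control=float("nan"),
            delta=d,
            sign=1 if d > 0 else -1,
            corr_sign_disease=csd,
            corr_sign_control=ccs,
        )
    return DceSet(cohort_label=cohort_label, params=params, records=records)


def dces_from_adjacencies(
    adj_disease: AdjacencyMatrix,
    adj_control: AdjacencyMatrix,
    params: DceParams,
    cohort_label: str = "",
) -> DceSet:
    """Convenience: difference + thresholding, keeping per-group adjacencies."""
    delta = signed_adjacency_difference(adj_disease, adj_control)
    base = identify_dces(delta, params, cohort_label)
    ids = list(adj_disease.feature_ids)
    pos = {f: k for k, f in enumerate(ids)}
    ad = np.array(adj_disease.values)
    ac = np.array(adj_control.values)
    records = {}
    for edge, rec in base.records.items():
        i, j = pos[edge[0]], pos[edge[1]]
        records[edge] = DceRecord(
            edge=edge,
            adj_disease=float(ad[i, j]),
            adj_control=float(ac[i, j]),
            delta=rec.delta,
            sign=rec.sign,
        )
    return DceSet(cohort_label=cohort_label, params=params, records=records)


def overlap_dce_sets(set_a: DceSet, set_b: DceSet) -> OverlapReport:
    """Edges called in both cohorts, sorted by edge key, with both signs."""
    shared = sorted(set_a.edges() & set_b.edges())
    rows = tuple(
        (e, set_a.records[e].sign, set_b.records[e].sign) for e in shared
    )
    return OverlapReport(
        shared_edges=rows,
        cohort_a=set_a.cohort_label or "A",
        cohort_b=set_b.cohort_label or "B",
    )


def concordance_summary(report: OverlapReport) -> dict:
    """Counts of shared / same-sign / opposite-sign edges plus the proportion."""
    n = report.n_shared
    return {
        "n_shared": n,
        "n_opposite": report.n_opposite,
        "n_same": report.n_same,
        "proportion_opposite": (report.n_opposite / n) if n else 0.0,
    }


def _pct(numerator: int, denominator: int) -> float:
    """Percentage to two decimals, rounding half away from zero."""
    if denominator == 0:
        return 0.0
    raw = 100.0 * numerator / denominator
    return float(np.floor(raw * 100 + 0.5) / 100) if raw >= 0 else float(
        -np.floor(-raw * 100 + 0.5) / 100
    )


def sign_proportion(dce_set: DceSet) -> dict:
    """Counts and percentages of gain (+1) and loss (-1) edges in a DCE set."""
    n_total = len(dce_set)
    n_pos = dce_set.n_positive
    n_neg = dce_set.n_negative
    return {
        "n_total": n_total,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "pct_positive": _pct(n_pos, n_total),
        "pct_negative": _pct(n_neg, n_total),
        "empty": n_total == 0,
    }
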