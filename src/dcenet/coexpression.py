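"""Per-group correlation matrices and WGCNA-style soft-threshold adjacency.

The adjacency between genes i and j in one group is ``|r_ij|**beta`` where
r_ij is their Spearman (default) or Pearson correlation across that group's
samples.  Raising to a power beta > 1 suppresses weak correlations and pushes
the weighted network toward scale-free topology; beta = 6 is the conventional
default for unsigned networks.  The scale-free fit index (binned log-log R^2
of the degree distribution) is provided as a diagnostic only -- beta is a
user parameter, never auto-selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dcenet.errors import ParameterError, ValidationError
from dcenet.expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

METHOD_SPEARMAN = "spearman"
METHOD_PEARSON = "pearson"
VALID_METHODS = (METHOD_SPEARMAN, METHOD_PEARSON)

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of pairwise gene-gene correlations in [-1, 1]."""

    feature_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    method: str = METHOD_SPEARMAN

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        n = len(self.feature_ids)
        if vals.shape != (n, n):
            raise ValidationError(f"correlation matrix shape {vals.shape} != ({n},{n})")
        if self.method not in VALID_METHODS:
            raise ValidationError(f"unknown correlation method '{self.method}'")
        if np.abs(vals - vals.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValidationError("correlation matrix is not symmetric")
        if np.any(np.abs(vals) > 1 + _SYMMETRY_TOL):
            raise ValidationError("correlation entries outside [-1, 1]")
        if not np.allclose(np.diag(vals), 1.0):
            raise ValidationError("correlation diagonal is not 1")
        vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(vals, 1.0)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))


@dataclass(frozen=True)
class AdjacencyParams:
    """Soft-threshold power and correlation method for network construction."""

    beta: int = 6
    method: str = METHOD_SPEARMAN

    def __post_init__(self):
        if int(self.beta) != self.beta or self.beta < 1:
            raise ParameterError(f"beta must be a positive integer, got {self.beta}")
        if self.method not in VALID_METHODS:
            raise ParameterError(f"correlation method must be one of {VALID_METHODS}")
        object.__setattr__(self, "beta", int(self.beta))


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Soft-threshold adjacency: off-diagonal ``|r|**beta``, diagonal 0.

    The diagonal is defined as 0 so that node connectivity excludes
    self-edges and differential-edge calling can never emit a self-edge.
    """

    feature_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    beta: int
    group_label: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        n = len(self.feature_ids)
        if vals.shape != (n, n):
            raise ValidationError(f"adjacency shape {vals.shape} != ({n},{n})")
        if np.abs(vals - vals.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValidationError("adjacency matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0):
            raise ValidationError("adjacency diagonal must be 0")
        if vals.min(initial=0.0) < 0 or vals.max(initial=0.0) > 1 + _SYMMETRY_TOL:
            raise ValidationError("adjacency entries outside [0, 1]")
        vals = np.clip(vals, 0.0, 1.0)
        np.fill_diagonal(vals, 0.0)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.values),
            index=list(self.feature_ids),
            columns=list(self.feature_ids),
        )


def correlation_matrix(expr: ExpressionMatrix, method: str = METHOD_SPEARMAN) -> CorrelationMatrix:
    """Pairwise correlation of features across samples.

    Spearman uses average (mid-) ranks for ties.  A zero-variance feature has
    no defined correlation with anything; its correlations are set to 0 with a
    logged warning so downstream matrices stay finite.
    """
    if method not in VALID_METHODS:
        raise ParameterError(f"correlation method must be one of {VALID_METHODS}")
    if expr.n_samples < 3:
        raise ValidationError(
            f"need at least 3 samples for correlation, got {expr.n_samples}"
        )
    if expr.n_features < 2:
        raise ValidationError(
            f"need at least 2 features for a network, got {expr.n_features}"
        )
    x = np.array(expr.values)
    if method == METHOD_SPEARMAN:
        x = stats.rankdata(x, axis=1)  # average ranks on ties
    sd = x.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    if degenerate.any():
        names = [expr.feature_ids[i] for i in np.flatnonzero(degenerate)]
        logger.warning(
            "zero-variance feature(s) %s: correlations set to 0", ", ".join(names)
        )
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(expr.feature_ids, corr, method)


def soft_threshold_adjacency(
    corr: CorrelationMatrix, beta: int = 6, group_label: str = ""
) -> AdjacencyMatrix:
    """Raise \\|correlation\\| to the power beta; zero the diagonal."""
    if int(beta) != beta or beta < 1:
        raise ParameterError(f"beta must be a positive integer, got {beta}")
    adj = np.abs(np.array(corr.values)) ** int(beta)
    np.fill_diagonal(adj, 0.0)
    return AdjacencyMatrix(corr.feature_ids, adj, int(beta), group_label)


def node_connectivity(adj: AdjacencyMatrix) -> pd.Series:
    """Weighted connectivity k_i = sum_{j != i} a_ij per feature."""
    k = np.array(adj.values).sum(axis=1)  # diagonal is 0 by invariant
    return pd.Series(k, index=list(adj.feature_ids), name="connectivity")


def scale_free_fit_index(adj: AdjacencyMatrix, n_bins: int = 10) -> float:
    """Scale-free topology fit: R^2 of log10(freq) on log10(mean k) over bins.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins are
    dropped.  A power-law degree distribution gives collinear points and an
    R^2 near 1.  Diagnostic only.
    """
    if n_bins < 2:
        raise ParameterError(f"need at least 2 bins, got {n_bins}")
    k = node_connectivity(adj).to_numpy()
    k = k[k > 0]
    if k.size == 0:
        raise ValidationError("all connectivities are zero")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size:
            mean_k.append(members.mean())
            freq.append(members.size / k.size)
    if len(mean_k) < 2:
        raise ValidationError("degenerate degree distribution (single bin)")
    log_k = np.log10(mean_k)
    log_f = np.log10(freq)
    r = stats.pearsonr(log_k, log_f).statistic
    return float(r**2)
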