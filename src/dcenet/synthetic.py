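"""Synthetic two-group expression data with planted differential edges.

The generator draws each group's samples from a multivariate Gaussian with
unit variances and a specified correlation matrix (a Gaussian copula with
normal margins): background correlation everywhere, with selected gene pairs
"planted" at different correlations in the two groups.  Because the data are
Gaussian, the population Spearman correlation of a pair with Pearson
correlation r is known in closed form, rho_s = (6/pi) * arcsin(r/2), so the
expected soft-threshold adjacency difference of every planted edge -- and
hence the ground-truth DCE set at a given beta and cutoff -- is exact.

This emulates the structure of two-cohort case/control microarray studies
(tens of diseased samples versus around ten to twenty controls per cohort);
it does not emulate probe-level noise, batch structure or heavy-tailed
expression margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dcenet.differential_edges import DceSet, canonical_edge, Edge
from dcenet.errors import ParameterError, ValidationError
from dcenet.expression_io import ExpressionMatrix

#: Baseline log2 expression level of every gene (typical microarray signal).
BASELINE_LOG2 = 8.0


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Design of a two-group dataset with known differential correlations.

    Parameters
    ----------
    n_genes
        Number of genes.
    planted_edges
        ``(i, j, r_disease, r_control)`` tuples giving each planted pair's
        population Pearson correlation in the two groups (gene indices).
    n_samples_per_group
        ``(n_disease, n_control)``; study-scale defaults.
    background_r
        Pearson correlation of all non-planted pairs (default 0).
    noise_sd
        Standard deviation of every gene's marginal (a pure scale; it does
        not change correlations).
    seed
        Seed of the single random stream used for both groups.
    """

    n_genes: int
    planted_edges: tuple[tuple[int, int, float, float], ...] = ()
    n_samples_per_group: tuple[int, int] = (16, 9)
    background_r: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ParameterError(f"need at least 2 genes, got {self.n_genes}")
        if self.noise_sd <= 0:
            raise ParameterError(f"noise_sd must be positive, got {self.noise_sd}")
        if abs(self.background_r) >= 1:
            raise ParameterError("background_r must satisfy |r| < 1")
        seen = set()
        for i, j, rd, rc in self.planted_edges:
            if i == j:
                raise ParameterError(f"planted self-pair ({i},{i})")
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes):
                raise ParameterError(f"planted pair ({i},{j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ParameterError(f"planted pair {key} listed twice")
            seen.add(key)
            if abs(rd) >= 1 or abs(rc) >= 1:
                raise ParameterError(
                    f"planted correlations for pair {key} must satisfy |r| < 1"
                )
        object.__setattr__(self, "planted_edges", tuple(self.planted_edges))
        object.__setattr__(
            self, "n_samples_per_group", tuple(self.n_samples_per_group)
        )

    def gene_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_genes - 1))
        return tuple(f"G{idx:0{width}d}" for idx in range(self.n_genes))

    def correlation_matrix(self, group: str) -> np.ndarray:
        """Population Pearson correlation matrix for 'disease' or 'control'."""
        col = 2 if group == "disease" else 3
        r = np.full((self.n_genes, self.n_genes), float(self.background_r))
        np.fill_diagonal(r, 1.0)
        for entry in self.planted_edges:
            i, j = entry[0], entry[1]
            r[i, j] = r[j, i] = float(entry[col])
        return r


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated expression for both groups plus the ground-truth edge set."""

    expr_disease: ExpressionMatrix
    expr_control: ExpressionMatrix
    truth: dict[Edge, int] = field(repr=False)  # edge -> expected sign
    spec: PlantedNetworkSpec = field(repr=False, default=None)


def population_spearman_from_pearson(r: float) -> float:
    """Population Spearman correlation of a bivariate Gaussian pair.

    For jointly Gaussian variables with Pearson correlation r the Spearman
    correlation is (6/pi) * arcsin(r/2).
    """
    if abs(r) > 1:
        raise ParameterError(f"|r| must be <= 1, got {r}")
    return (6.0 / math.pi) * math.asin(r / 2.0)


def _cholesky_or_fail(r: np.ndarray, group: str) -> np.ndarray:
    """Cholesky factor, or an error naming the first non-positive minor.

    Non-PSD designs are rejected outright rather than projected to the
    nearest PSD matrix, so the planted truth stays exact.
    """
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        for k in range(1, r.shape[0] + 1):
            if np.linalg.det(r[:k, :k]) <= 0:
                raise ValidationError(
                    f"{group} correlation matrix is not positive definite: "
                    f"leading principal minor of order {k} is non-positive"
                ) from None
        raise ValidationError(
            f"{group} correlation matrix is not positive definite"
        ) from None


def expected_truth(
    spec: PlantedNetworkSpec, beta: int = 6, margin: float = 0.3
) -> dict[Edge, int]:
    """Planted edges whose population adjacency difference clears ``margin``.

    The pipeline's default statistic is Spearman-based, so each planted
    Pearson value is first mapped to its population Spearman; the expected
    adjacency difference is then ``|rho_d|**beta - |rho_c|**beta``.
    """
    ids = spec.gene_ids()
    truth: dict[Edge, int] = {}
    for i, j, rd, rc in spec.planted_edges:
        sd = abs(population_spearman_from_pearson(rd)) ** beta
        sc = abs(population_spearman_from_pearson(rc)) ** beta
        delta = sd - sc
        if abs(delta) > margin:
            truth[canonical_edge(ids[i], ids[j])] = 1 if delta > 0 else -1
    return truth


def generate_two_group_expression(
    spec: PlantedNetworkSpec, beta: int = 6, truth_margin: float = 0.3
) -> SyntheticDataset:
    """Draw both groups from their planted Gaussian correlation structures.

    Samples are i.i.d. multivariate normal with mean ``BASELINE_LOG2``,
    standard deviation ``noise_sd`` per gene and the group's planted
    correlation matrix.  All randomness comes from one generator seeded with
    ``spec.seed``; the same spec always yields bit-identical matrices.
    """
    rng = np.random.default_rng(spec.seed)
    ids = spec.gene_ids()
    n_dis, n_ctl = spec.n_samples_per_group
    matrices = {}
    for group, n in (("disease", n_dis), ("control", n_ctl)):
        if n < 1:
            raise ParameterError(f"{group} group needs >= 1 sample, got {n}")
        corr = spec.correlation_matrix(group)
        chol = _cholesky_or_fail(corr, group)
        z = rng.standard_normal((spec.n_genes, n))
        x = BASELINE_LOG2 + spec.noise_sd * (chol @ z)
        samples = tuple(f"{group[:3].upper()}{k + 1:03d}" for k in range(n))
        matrices[group] = ExpressionMatrix(ids, samples, x)
    return SyntheticDataset(
        expr_disease=matrices["disease"],
        expr_control=matrices["control"],
        truth=expected_truth(spec, beta=beta, margin=truth_margin),
        spec=spec,
    )


def evaluate_recovery(called: DceSet, truth: dict[Edge, int]) -> dict:
    """Compare a called DCE set with planted ground truth.

    A true positive must match on both edge identity and sign.  Sensitivity
    is true positives over planted edges; ``false_discoveries`` counts called
    edges that were not planted (regardless of sign); ``sign_accuracy`` is
    the fraction of recovered planted edges with the correct sign.
    """
    called_signs = {e: r.sign for e, r in called.records.items()}
    if not truth:
        return {
            "sensitivity": float("nan"),
            "false_discoveries": len(called_signs),
            "sign_accuracy": float("nan"),
            "empty_truth": True,
        }
    recovered = set(called_signs) & set(truth)
    tp = sum(1 for e in recovered if called_signs[e] == truth[e])
    return {
        "sensitivity": tp / len(truth),
        "false_discoveries": len(set(called_signs) - set(truth)),
        "sign_accuracy": (tp / len(recovered)) if recovered else float("nan"),
        "empty_truth": False,
    }
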