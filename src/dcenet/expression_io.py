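"""Expression-matrix I/O, validation and probe-level pre-processing.

Expression values are assumed to be on the log2 scale (the output of standard
microarray normalisation such as fRMA, or log2(CPM+1) for sequencing data).
Normalisation and batch correction are deliberately not performed here: the
pipeline consumes matrices that are already normalised and batch-corrected.

The one substantive pre-processing rule housed in this module is the
probe-collapse rule: when several probe sets map to the same gene symbol, the
probe with the largest absolute log fold change (disease minus control group
mean) is retained as the gene's representative row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dcenet.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Smallest group size accepted for downstream correlation analysis.
MIN_GROUP_SIZE = 3

GROUP_DISEASE = "disease"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_DISEASE, GROUP_CONTROL)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples matrix of log2 expression values.

    Parameters
    ----------
    feature_ids
        Unique feature identifiers (probe ids or gene symbols), row order.
    sample_ids
        Unique sample identifiers, column order.
    values
        Real matrix of shape ``(len(feature_ids), len(sample_ids))``; every
        entry must be finite after validation.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        feats = tuple(str(f) for f in self.feature_ids)
        samps = tuple(str(s) for s in self.sample_ids)
        vals = np.asarray(self.values, dtype=float)
        if len(set(feats)) != len(feats):
            dupes = _duplicates(feats)
            raise ValidationError(f"duplicate feature ids: {', '.join(dupes)}")
        if len(set(samps)) != len(samps):
            dupes = _duplicates(samps)
            raise ValidationError(f"duplicate sample ids: {', '.join(dupes)}")
        if vals.ndim != 2 or vals.shape != (len(feats), len(samps)):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(feats)} features x {len(samps)} samples"
            )
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite expression value at feature "
                f"'{feats[bad[0]]}', sample '{samps[bad[1]]}'"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "feature_ids", feats)
        object.__setattr__(self, "sample_ids", samps)
        object.__setattr__(self, "values", vals)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.values),
            index=list(self.feature_ids),
            columns=list(self.sample_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            feature_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Return the matrix restricted to ``sample_ids`` (given order)."""
        wanted = [str(s) for s in sample_ids]
        missing = [s for s in wanted if s not in self.sample_ids]
        if missing:
            raise ValidationError(f"unknown sample ids: {', '.join(missing)}")
        idx = [self.sample_ids.index(s) for s in wanted]
        return ExpressionMatrix(
            self.feature_ids, tuple(wanted), np.array(self.values)[:, idx]
        )


def _duplicates(items) -> list[str]:
    seen, dupes = set(), []
    for it in items:
        if it in seen and it not in dupes:
            dupes.append(it)
        seen.add(it)
    return dupes


@dataclass(frozen=True)
class SampleAnnotation:
    """Maps sample ids to group (disease/control), cohort and optional batch."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        required = {"sample_id", "group", "cohort"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(
                f"sample annotation missing columns: {', '.join(sorted(missing))}"
            )
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in annotation: {dupes}")
        bad = set(t["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValidationError(
                f"invalid group labels {sorted(bad)}; expected one of {VALID_GROUPS}"
            )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def samples_in_group(self, group: str, cohort: str | None = None) -> list[str]:
        t = self.table
        mask = t["group"] == group
        if cohort is not None:
            mask &= t["cohort"] == cohort
        return t.loc[mask, "sample_id"].tolist()

    def check_group_sizes(self, cohort: str | None = None) -> None:
        """Reject any referenced (cohort, group) cell smaller than 3 samples."""
        for group in VALID_GROUPS:
            n = len(self.samples_in_group(group, cohort))
            if n < MIN_GROUP_SIZE:
                where = f" in cohort '{cohort}'" if cohort else ""
                raise ValidationError(
                    f"group '{group}'{where} has {n} samples; "
                    f"at least {MIN_GROUP_SIZE} are required for rank correlation"
                )


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe -> gene symbol mapping. Many probes per gene; one gene per probe."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        required = {"probe_id", "gene_symbol"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(
                f"probe annotation missing columns: {', '.join(sorted(missing))}"
            )
        if t["probe_id"].duplicated().any():
            dupes = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValidationError(f"duplicated probe rows: {dupes}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def gene_for(self) -> dict[str, str]:
        return dict(zip(self.table["probe_id"], self.table["gene_symbol"]))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_tsv(path, drop_missing: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The first column holds feature ids (header ``feature_id``), remaining
    columns are samples.  Any non-finite cell is an error unless
    ``drop_missing`` is set, in which case features containing missing values
    are dropped and the count logged.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if frame.shape[0] == 0:
        raise FormatError(f"{path}: no features (header-only file)")
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature id(s): {', '.join(map(str, dupes))}")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        fresh_nan = converted.isna() & frame[col].notna()
        if fresh_nan.any():
            row = frame.index[fresh_nan.argmax()]
            raise FormatError(
                f"{path}: non-numeric value at feature '{row}', sample '{col}'"
            )
        frame[col] = converted
    if drop_missing:
        keep = np.isfinite(frame.to_numpy(dtype=float)).all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropped %d features with missing values", n_dropped)
        frame = frame.loc[keep]
        if frame.shape[0] == 0:
            raise FormatError(f"{path}: all features dropped by missing-value policy")
    return ExpressionMatrix.from_frame(frame)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix in the dialect `read_expression_tsv` reads."""
    frame = expr.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_annotation_tsv(path) -> SampleAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleAnnotation(table)


def read_probe_annotation_tsv(path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return ProbeAnnotation(table)


def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line allowlist; '#' starts a comment."""
    symbols: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.add(line)
    return symbols


# ---------------------------------------------------------------------------
# Pre-processing operations
# ---------------------------------------------------------------------------

def log_fold_change(expr: ExpressionMatrix, ann: SampleAnnotation,
                    cohort: str | None = None) -> pd.Series:
    """Per-feature log fold change: disease group mean minus control group mean.

    Valid because expression is already on the log2 scale, so a difference of
    group means is a log2 fold change.
    """
    vals = expr.to_frame()
    disease = [s for s in ann.samples_in_group(GROUP_DISEASE, cohort)
               if s in expr.sample_ids]
    control = [s for s in ann.samples_in_group(GROUP_CONTROL, cohort)
               if s in expr.sample_ids]
    if not disease or not control:
        raise ValidationError(
            f"log_fold_change requires non-empty groups "
            f"(disease: {len(disease)}, control: {len(control)})"
        )
    lfc = vals[disease].mean(axis=1) - vals[control].mean(axis=1)
    lfc.name = "lfc"
    return lfc


def collapse_probes_by_max_lfc(
    expr: ExpressionMatrix,
    probes: ProbeAnnotation,
    ann: SampleAnnotation,
    cohort: str | None = None,
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    For each gene with multiple probes the probe with the largest \\|LFC\\| is
    retained; ties are broken by the lexicographically smallest probe id so
    the result is deterministic.  Output feature ids are gene symbols, ordered
    by first appearance of the gene among the input probes.
    """
    mapping = probes.gene_for()
    unmapped = [f for f in expr.feature_ids if f not in mapping]
    if unmapped:
        raise ValidationError(
            f"probes missing from annotation: {', '.join(unmapped)}"
        )
    lfc = log_fold_change(expr, ann, cohort)

    chosen: dict[str, str] = {}  # gene -> winning probe
    order: list[str] = []
    for probe in expr.feature_ids:
        gene = mapping[probe]
        if gene not in chosen:
            chosen[gene] = probe
            order.append(gene)
        else:
            incumbent = chosen[gene]
            a, b = abs(lfc[probe]), abs(lfc[incumbent])
            if a > b or (a == b and probe < incumbent):
                chosen[gene] = probe

    frame = expr.to_frame()
    collapsed = frame.loc[[chosen[g] for g in order]]
    collapsed.index = order
    logger.info(
        "collapsed %d probes to %d genes", expr.n_features, len(order)
    )
    return ExpressionMatrix.from_frame(collapsed)


def filter_to_gene_list(expr: ExpressionMatrix, allowlist: set[str]) -> ExpressionMatrix:
    """Restrict rows to gene symbols in ``allowlist``, preserving row order."""
    if not allowlist:
        raise ValidationError("gene allowlist is empty")
    keep = [f for f in expr.feature_ids if f in allowlist]
    dropped = expr.n_features - len(keep)
    if not keep:
        raise ValidationError(
            "no features left after allowlist filtering (disjoint gene sets)"
        )
    logger.info("allowlist filter: retained %d, dropped %d", len(keep), dropped)
    return ExpressionMatrix.from_frame(expr.to_frame().loc[keep])
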