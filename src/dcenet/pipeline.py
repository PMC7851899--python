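"""End-to-end orchestration: per-cohort DCE calling and cross-cohort overlap.

A run is described by a :class:`RunConfig` (usually loaded from a YAML file).
Each cohort runs the same chain: read expression -> optional probe collapse ->
optional allowlist filter -> per-group correlation -> soft-threshold
adjacency -> signed adjacency difference -> DCE calling -> hub ranking.  Every
stage failure is re-raised with the stage name attached.  All outputs are
plain text written deterministically (sorted rows, fixed float formatting),
and a manifest records parameters, input checksums and result counts so a
rerun on unchanged inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from dcenet.coexpression import (
    AdjacencyParams,
    correlation_matrix,
    soft_threshold_adjacency,
)
from dcenet.differential_edges import (
    DceParams,
    DceSet,
    OverlapReport,
    concordance_summary,
    dces_from_adjacencies,
    overlap_dce_sets,
    sign_proportion,
)
from dcenet.errors import StageError, ValidationError
from dcenet.expression_io import (
    GROUP_CONTROL,
    GROUP_DISEASE,
    collapse_probes_by_max_lfc,
    filter_to_gene_list,
    read_expression_tsv,
    read_gene_list,
    read_probe_annotation_tsv,
    read_sample_annotation_tsv,
)
from dcenet.hubs import (
    HubList,
    build_dce_graph,
    export_sif,
    overlap_hub_lists,
    rank_hubs_by_degree,
)

logger = logging.getLogger(__name__)

#: TSV float formatting: 6 significant digits.
FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class CohortConfig:
    """Input files for one cohort."""

    expression: str
    annotation: str
    probe_annotation: str | None = None  # enables probe collapse
    allowlist: str | None = None         # enables gene-symbol filtering


@dataclass(frozen=True)
class RunConfig:
    """Parameters and inputs of a full two-cohort run."""

    cohorts: dict[str, CohortConfig]
    adjacency: AdjacencyParams = field(default_factory=AdjacencyParams)
    dce: DceParams = field(default_factory=DceParams)
    top_k: int = 50
    output_dir: str = "dcenet_output"
    seed: int = 0

    def __post_init__(self):
        if self.top_k < 1:
            raise ValidationError(f"top_k must be >= 1, got {self.top_k}")
        # keep the network parameters and the DCE record of them consistent
        object.__setattr__(
            self,
            "dce",
            DceParams(
                cutoff=self.dce.cutoff,
                beta=self.adjacency.beta,
                method=self.adjacency.method,
            ),
        )

    def validate_paths(self) -> None:
        for name, cohort in self.cohorts.items():
            for label, p in (
                ("expression", cohort.expression),
                ("annotation", cohort.annotation),
                ("probe_annotation", cohort.probe_annotation),
                ("allowlist", cohort.allowlist),
            ):
                if p is not None and not Path(p).is_file():
                    raise ValidationError(
                        f"cohort '{name}': {label} file not found: {p}"
                    )


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration; keyword overrides beat file values."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cohorts = {
        name: CohortConfig(**entry) for name, entry in raw.get("cohorts", {}).items()
    }
    adjacency = AdjacencyParams(
        beta=int(raw.get("beta", 6)), method=raw.get("cor_method", "spearman")
    )
    dce = DceParams(
        cutoff=float(raw.get("cutoff", 0.3)),
        beta=adjacency.beta,
        method=adjacency.method,
    )
    return RunConfig(
        cohorts=cohorts,
        adjacency=adjacency,
        dce=dce,
        top_k=int(raw.get("top_k", 50)),
        output_dir=str(raw.get("output_dir", "dcenet_output")),
        seed=int(raw.get("seed", 0)),
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: run fn, tag any error with the stage."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_cohort(config: RunConfig, cohort: str) -> tuple[DceSet, HubList]:
    """Run the full single-cohort analysis; write TSV/SIF artifacts + manifest."""
    if cohort not in config.cohorts:
        raise ValidationError(f"unknown cohort '{cohort}'")
    cc = config.cohorts[cohort]
    outdir = Path(config.output_dir) / cohort
    outdir.mkdir(parents=True, exist_ok=True)

    checksums = {
        "expression": _sha256(cc.expression),
        "annotation": _sha256(cc.annotation),
    }

    with _stage("read"):
        expr = read_expression_tsv(cc.expression)
        ann = read_sample_annotation_tsv(cc.annotation)
        ann_cohort = cohort if cohort in set(ann.table["cohort"]) else None
        ann.check_group_sizes(ann_cohort)
        logger.info(
            "read: %d features x %d samples", expr.n_features, expr.n_samples
        )

    if cc.probe_annotation is not None:
        with _stage("collapse"):
            probes = read_probe_annotation_tsv(cc.probe_annotation)
            checksums["probe_annotation"] = _sha256(cc.probe_annotation)
            expr = collapse_probes_by_max_lfc(expr, probes, ann, ann_cohort)

    if cc.allowlist is not None:
        with _stage("allowlist"):
            allow = read_gene_list(cc.allowlist)
            checksums["allowlist"] = _sha256(cc.allowlist)
            expr = filter_to_gene_list(expr, allow)

    with _stage("correlation"):
        groups = {}
        for group in (GROUP_DISEASE, GROUP_CONTROL):
            samples = [
                s for s in ann.samples_in_group(group, ann_cohort)
                if s in expr.sample_ids
            ]
            sub = expr.subset_samples(samples)
            groups[group] = correlation_matrix(sub, config.adjacency.method)
            logger.info(
                "correlation (%s): %d features x %d samples",
                group, sub.n_features, sub.n_samples,
            )

    with _stage("adjacency"):
        adj = {
            g: soft_threshold_adjacency(c, config.adjacency.beta, g)
            for g, c in groups.items()
        }

    with _stage("dce"):
        dce_set = dces_from_adjacencies(
            adj[GROUP_DISEASE], adj[GROUP_CONTROL], config.dce, cohort
        )
        props = sign_proportion(dce_set)
        logger.info(
            "dce: %d edges (%d gains, %d losses)",
            props["n_total"], props["n_positive"], props["n_negative"],
        )

    with _stage("hubs"):
        graph = build_dce_graph(dce_set)
        hubs = rank_hubs_by_degree(graph, config.top_k)

    with _stage("write"):
        dce_set.to_frame().to_csv(
            outdir / "dce_edges.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT, lineterminator="\n",
        )
        hubs.to_frame().to_csv(
            outdir / "hub_genes.tsv", sep="\t", index=False, lineterminator="\n"
        )
        export_sif(graph, outdir / "dce_network.sif", hubs=hubs, induced=True)
        manifest = {
            "cohort": cohort,
            "parameters": {
                "beta": config.adjacency.beta,
                "cor_method": config.adjacency.method,
                "cutoff": config.dce.cutoff,
                "top_k": config.top_k,
                "seed": config.seed,
            },
            "input_checksums": checksums,
            "counts": {
                "features": expr.n_features,
                "dce_total": props["n_total"],
                "dce_gain": props["n_positive"],
                "dce_loss": props["n_negative"],
                "graph_nodes": graph.number_of_nodes(),
                "hub_list_length": len(hubs),
            },
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return dce_set, hubs


def run_cross_cohort(config: RunConfig) -> tuple[OverlapReport, list[str], dict]:
    """Run both cohorts, overlap their DCE sets and hub lists, write summary."""
    names = list(config.cohorts)
    if len(names) != 2:
        raise ValidationError(
            f"cross-cohort analysis needs exactly 2 cohorts, got {len(names)}"
        )
    results = {name: run_cohort(config, name) for name in names}
    (set_a, hubs_a), (set_b, hubs_b) = results[names[0]], results[names[1]]

    with _stage("overlap"):
        if not (set_a.edges() or set_b.edges()):
            logger.warning("both DCE sets empty; overlap is trivially empty")
        universe_a = {g for e in set_a.edges() for g in e}
        universe_b = {g for e in set_b.edges() for g in e}
        if universe_a and universe_b and not (universe_a & universe_b):
            logger.warning("cohorts share no genes; overlap is empty")
        report = overlap_dce_sets(set_a, set_b)
        shared_hubs = overlap_hub_lists(hubs_a, hubs_b)
        summary = concordance_summary(report)
        summary["shared_hub_genes"] = shared_hubs
        summary["sign_proportion"] = {
            names[0]: sign_proportion(set_a),
            names[1]: sign_proportion(set_b),
        }

    with _stage("write-overlap"):
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(
            outdir / "dce_overlap.tsv", sep="\t", index=False, lineterminator="\n"
        )
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        lines = [
            f"cohorts: {names[0]} vs {names[1]}",
            f"shared DCEs: {summary['n_shared']} "
            f"(opposite sign: {summary['n_opposite']}, same sign: {summary['n_same']})",
            f"proportion opposite: {summary['proportion_opposite']:.4f}",
            f"shared hub genes ({len(shared_hubs)}): {', '.join(shared_hubs) or '-'}",
        ]
        (outdir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    return report, shared_hubs, summary
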