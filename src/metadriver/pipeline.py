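"""End-to-end orchestration: filter → DEGs → cover → modules → flow → rank.

The pipeline mirrors the integrative workflow: somatic filtering and
group-specific mutation calling on the variant side; DEG detection,
co-expression module discovery and TF enrichment on the expression side;
then, for every candidate mutant gene (the exclusive-coverage selection
united with all genes mutated only in high-risk samples), a network-flow
ILP searching the Pearson-weighted interactome for a subnetwork linking the
mutant to the signature TFs, and a final ranking by maximum pathway weight.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import coverage, expression, filtering, flow, modules
from .io import (
    HRM,
    CohortLabels,
    VariantRecord,
    read_expression,
    read_gmt,
    read_labels,
    read_network,
    read_variants,
    write_variants,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All stage parameters with their decided defaults, plus input paths."""

    tumor: str | None = None
    normal: str | None = None
    labels: str | None = None
    expression: str | None = None
    network: str | None = None
    tf_targets: str | None = None

    af_threshold: float = 0.1
    min_frac: float = 0.09
    p_threshold: float = 0.01
    fold_threshold: float = 2.0
    pseudocount: float = 0.1
    lambda_cover: float = 1.0
    K: int | None = None  # None: smallest K reaching full coverage
    penalty_mode: str = "lambda_over_K"
    cover_solver: str = "auto"
    r_min: float = 0.7
    p_max: float = 0.01
    module_penalty: float = 2.0
    min_size: int = 3
    min_density: float = 0.5
    overlap_max: float = 0.8
    R: int = 20
    lambda_flow: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineReport:
    """Per-stage counts and the final ranking of one pipeline run."""

    n_tumor_variants: int = 0
    n_filtered_variants: int = 0
    n_group_specific: int = 0
    burden_p: float = float("nan")
    n_degs: int = 0
    K: int = 0
    selected_mutations: list = field(default_factory=list)
    coverage_fraction: float = float("nan")
    n_modules: int = 0
    n_signature_modules: int = 0
    signature_tfs: list = field(default_factory=list)
    n_candidates: int = 0
    n_feasible_pathways: int = 0
    ranking: list = field(default_factory=list)  # [gene, Pw] pairs
    status: str = "ok"
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def hrm_only_mutant_genes(
    variants: list[VariantRecord], labels: CohortLabels
) -> set[str]:
    """Genes whose (filtered) mutations occur exclusively in HRM samples."""
    in_hrm, in_lrm = set(), set()
    for v in variants:
        (in_hrm if labels[v.sample_id] == HRM else in_lrm).add(v.gene)
    return in_hrm - in_lrm


def run_pipeline_data(
    tumor: list[VariantRecord],
    normal: list[VariantRecord],
    labels: CohortLabels,
    expr: pd.DataFrame,
    ppi: nx.Graph,
    tfmap: dict[str, frozenset[str]],
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Run the full pipeline on in-memory inputs; see module docstring.

    With *outdir*, every intermediate result is written to disk
    (filtered variants, mutation matrix, DEG table, coverage solution,
    signatures, pathways, report.json).
    """
    cfg = cfg or PipelineConfig()
    report = PipelineReport(n_tumor_variants=len(tumor))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: somatic filtering and group-specific mutations -------
    filtered = filtering.filter_somatic_variants(tumor, normal, cfg.af_threshold)
    report.n_filtered_variants = len(filtered)
    if not filtered:
        report.status = "no variants survive filtering"
        return _finish(report, out)
    mm = filtering.build_mutation_matrix(filtered, labels)
    report.burden_p = filtering.summarize_burden(mm, labels).p_value
    specific = filtering.find_group_specific_mutations(mm, labels, cfg.min_frac)
    report.n_group_specific = len(specific)
    if out is not None:
        write_variants(filtered, out / "filtered_variants.tsv")
        mm.to_frame().to_csv(out / "mutation_matrix.tsv", sep="\t")

    # --- stage 2: DEGs --------------------------------------------------
    degs = expression.detect_degs(
        expr, labels, cfg.p_threshold, cfg.fold_threshold, cfg.pseudocount
    )
    report.n_degs = int(degs["deg"].sum())
    if out is not None:
        degs.to_csv(out / "degs.tsv", sep="\t")

    # --- stage 3: exclusive coverage over HRM-specific mutations --------
    candidates: set[str] = hrm_only_mutant_genes(filtered, labels)
    if specific:
        hrm_samples = [s for s in mm.samples if labels[s] == HRM]
        mm_hrm = mm.restrict(samples=hrm_samples, mutations=specific)
        K = cfg.K if cfg.K is not None else coverage.choose_K(
            mm_hrm, cfg.lambda_cover, cfg.penalty_mode
        )
        inst = coverage.CoverageInstance.from_matrix(
            mm_hrm, K, cfg.lambda_cover, cfg.penalty_mode
        )
        sol = coverage.solve(inst, solver=cfg.cover_solver)
        report.K = K
        report.selected_mutations = [list(k) for k in sol.selected]
        report.coverage_fraction = sol.coverage_fraction
        candidates |= {gene for gene, _ in sol.selected}
        if out is not None:
            with (out / "coverage.json").open("w") as fh:
                json.dump(
                    {
                        "K": K,
                        "selected": [list(k) for k in sol.selected],
                        "objective": sol.objective,
                        "coverage_fraction": sol.coverage_fraction,
                        "solver": sol.solver,
                    },
                    fh,
                    indent=2,
                )
    else:
        report.status = "no group-specific mutations"
        logger.warning("stage cover: no group-specific mutations found")

    # --- stage 4: co-expression modules and signature TFs ----------------
    hrm_cols = [s for s in labels.group(HRM) if s in expr.columns]
    expr_hrm = expr[hrm_cols]
    net = modules.build_coexpression_network(expr_hrm, cfg.r_min, cfg.p_max)
    mods = modules.detect_modules(
        net, cfg.module_penalty, cfg.min_size, cfg.min_density, cfg.overlap_max
    )
    report.n_modules = len(mods)
    universe = set(expr.index)
    signatures = modules.select_signatures(mods, degs, tfmap, universe, cfg.p_threshold)
    report.n_signature_modules = len(signatures.modules)
    report.signature_tfs = sorted(signatures.tfs)
    if out is not None:
        with (out / "signatures.json").open("w") as fh:
            json.dump(
                {
                    "modules": [
                        {
                            "genes": sorted(m.genes),
                            "cohesiveness": m.cohesiveness,
                            "deg_enrichment_p": m.deg_enrichment_p,
                        }
                        for m in signatures.modules
                    ],
                    "tfs": sorted(signatures.tfs),
                },
                fh,
                indent=2,
            )
    if not signatures.tfs:
        report.status = "no signature TFs: flow stage skipped"
        return _finish(report, out)

    # --- stage 5: network flow per candidate mutant gene -----------------
    report.n_candidates = len(candidates)
    weighted = flow.weight_network(ppi, expr_hrm)
    results = []
    for gene in sorted(candidates):
        fp = flow.build_flow_program(
            weighted, gene, signatures.tfs, cfg.R, cfg.lambda_flow
        )
        results.append(flow.solve_pathway(fp))
    report.n_feasible_pathways = sum(r.feasible for r in results)
    ranking = flow.rank_mutants(results)
    report.ranking = [[g, float(p)] for g, p in ranking.itertuples(index=False)]
    if out is not None:
        with (out / "pathways.json").open("w") as fh:
            json.dump(
                [
                    {
                        "mutant": r.mutant_gene,
                        "feasible": r.feasible,
                        "reason": r.reason,
                        "nodes": list(r.selected_nodes),
                        "edges": [[a, b, w] for a, b, w in r.selected_edges],
                        "best_path": list(r.best_path),
                        "Pw": None if not r.feasible else r.Pw,
                    }
                    for r in results
                ],
                fh,
                indent=2,
            )
    return _finish(report, out)


def _finish(report: PipelineReport, out: Path | None) -> PipelineReport:
    if out is not None:
        report.to_json(out / "report.json")
    return report


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineReport:
    """File-based entry point: read every input named in *cfg* and run."""
    for name in ("tumor", "normal", "labels", "expression", "network", "tf_targets"):
        if getattr(cfg, name) is None:
            raise ValueError(f"config is missing input path {name!r}")
    tumor = read_variants(cfg.tumor)
    normal = read_variants(cfg.normal)
    labels = read_labels(cfg.labels)
    expr = read_expression(cfg.expression)
    ppi = read_network(cfg.network)
    tfmap = read_gmt(cfg.tf_targets)
    return run_pipeline_data(tumor, normal, labels, expr, ppi, tfmap, cfg, outdir)
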