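"""End-to-end discovery workflow: marks -> CREs -> specificity ->
regulatory domains -> gene categories -> expression filter.

:func:`run_discovery` operates on in-memory objects and is what the
tests and the synthetic-data harness call; :func:`run_from_config`
builds those objects from a YAML config of file paths and writes every
intermediate to disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import classify as cls
from .cre import (
    CRESet,
    ENHANCER,
    MarkPanel,
    PROMOTER,
    call_enhancers,
    call_promoters,
    tissue_specific,
    ubiquitous,
)
from .domains import (
    BASAL_DOWNSTREAM,
    BASAL_UPSTREAM,
    MAX_EXTENSION,
    CREAssignment,
    RegulatoryDomain,
    assign_cres,
    extend_domains,
)
from .intervals import IntervalSet
from .io import (
    ChromSizes,
    ExpressionTable,
    GeneModel,
    read_bed,
    read_chrom_sizes,
    read_expression,
    read_tss_table,
    write_bed,
)


@dataclass
class PipelineParams:
    """Every threshold the workflow uses, echoed into the report."""

    expression_threshold: float = cls.EXPRESSION_THRESHOLD
    min_overlap_bp: int = 1
    basal_up_bp: int = BASAL_UPSTREAM
    basal_down_bp: int = BASAL_DOWNSTREAM
    max_extension: int = MAX_EXTENSION
    exclude_promoter_overlap: bool = False


@dataclass
class RunReport:
    """All numbers a discovery run produces, plus the settings that
    produced them."""

    target: str
    tissues: list[str]
    params: PipelineParams
    cre_counts: dict[str, dict[str, int]]  # tissue -> kind -> n CREs
    specific_counts: dict[str, int]  # kind -> n target-specific CREs
    ubiquitous_counts: dict[str, int]
    n_genes: int
    n_domains: int
    n_unassigned_cres: int
    category_table: pd.DataFrame
    category_summary: dict[str, dict[str, float]]
    expression_percentile: float
    specific_assignments: list[CREAssignment] = field(repr=False, default_factory=list)
    ubiquitous_assignments: list[CREAssignment] = field(repr=False, default_factory=list)
    domains: list[RegulatoryDomain] = field(repr=False, default_factory=list)

    def genes_in_category(self, cat: str, expressed_only: bool = False) -> set[str]:
        t = self.category_table
        mask = t["category"] == cat
        if expressed_only:
            mask &= t["passes_expression"]
        return set(t.index[mask])

    def summary_dict(self) -> dict:
        return {
            "target": self.target,
            "tissues": self.tissues,
            "params": vars(self.params),
            "cre_counts": self.cre_counts,
            "specific_counts": self.specific_counts,
            "ubiquitous_counts": self.ubiquitous_counts,
            "n_genes": self.n_genes,
            "n_domains": self.n_domains,
            "n_unassigned_cres": self.n_unassigned_cres,
            "n_classified_genes": int(len(self.category_table)),
            "category_summary": self.category_summary,
            "expression_percentile": self.expression_percentile,
        }


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_discovery(
    panels: Mapping[str, MarkPanel],
    target: str,
    genes: list[GeneModel],
    chrom_sizes: ChromSizes,
    expression: ExpressionTable,
    params: PipelineParams | None = None,
) -> RunReport:
    """Run the full discovery workflow for one target tissue.

    ``panels`` maps every tissue (target included) to its mark panel;
    ``expression`` is the target tissue's FPKM table.  Deterministic:
    no randomness anywhere in the workflow.
    """
    params = params or PipelineParams()
    if target not in panels:
        raise StageError(f"cre-calling: target tissue {target!r} not in panel {sorted(panels)}")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"{name}: {exc}") from exc

    # 1. call CREs per tissue
    promoters = {t: stage("call-promoters", call_promoters, p) for t, p in panels.items()}
    enhancers = {
        t: stage(
            "call-enhancers", call_enhancers, p, exclude_promoter_overlap=params.exclude_promoter_overlap
        )
        for t, p in panels.items()
    }
    cre_counts = {
        t: {PROMOTER: len(promoters[t]), ENHANCER: len(enhancers[t])} for t in panels
    }

    # 2. specificity of the target tissue's CREs (kind-matched)
    others_p = [promoters[t] for t in panels if t != target]
    others_e = [enhancers[t] for t in panels if t != target]
    if others_p:
        spec_p = stage("specificity", tissue_specific, promoters[target], others_p, params.min_overlap_bp)
        spec_e = stage("specificity", tissue_specific, enhancers[target], others_e, params.min_overlap_bp)
        ubiq_p = stage("specificity", ubiquitous, promoters[target], others_p, params.min_overlap_bp)
        ubiq_e = stage("specificity", ubiquitous, enhancers[target], others_e, params.min_overlap_bp)
    else:
        # single-tissue panel: everything is vacuously target-specific
        spec_p = CRESet(target, PROMOTER, promoters[target].intervals, "target_specific")
        spec_e = CRESet(target, ENHANCER, enhancers[target].intervals, "target_specific")
        ubiq_p = CRESet(target, PROMOTER, IntervalSet(), "ubiquitous")
        ubiq_e = CRESet(target, ENHANCER, IntervalSet(), "ubiquitous")

    # 3. regulatory domains and CRE assignment
    domains = stage(
        "domains",
        extend_domains,
        genes,
        chrom_sizes,
        params.basal_up_bp,
        params.basal_down_bp,
        params.max_extension,
    )
    results = [
        stage("assignment", assign_cres, cre_set, domains, params.min_overlap_bp)
        for cre_set in (spec_p, spec_e, ubiq_p, ubiq_e)
    ]
    specific_assignments = results[0].assignments + results[1].assignments
    ubiquitous_assignments = results[2].assignments + results[3].assignments
    n_unassigned = sum(len(r.unassigned) for r in results)

    # 4. classification + expression filter
    table = stage("classification", cls.classify_genes, specific_assignments, ubiquitous_assignments)
    table = stage("expression", cls.attach_expression, table, expression, params.expression_threshold)
    expressed, percentile = stage("expression", cls.filter_expressed, expression, params.expression_threshold)
    summary = cls.category_summary(table, expressed)

    return RunReport(
        target=target,
        tissues=list(panels),
        params=params,
        cre_counts=cre_counts,
        specific_counts={PROMOTER: len(spec_p), ENHANCER: len(spec_e)},
        ubiquitous_counts={PROMOTER: len(ubiq_p), ENHANCER: len(ubiq_e)},
        n_genes=len(genes),
        n_domains=len(domains),
        n_unassigned_cres=n_unassigned,
        category_table=table,
        category_summary=summary,
        expression_percentile=percentile,
        specific_assignments=specific_assignments,
        ubiquitous_assignments=ubiquitous_assignments,
        domains=domains,
    )


# -- file-based entry point -------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("tissues", "target", "tss_table", "chrom_sizes", "expression"):
        if key not in cfg:
            raise StageError(f"config: missing key {key!r}")
    return cfg


def run_from_config(config_path: str | Path, out_dir: str | Path) -> RunReport:
    """Run the workflow from a YAML config of file paths.

    Config layout::

        target: heart
        tissues:
          heart: {H3K4me1: h_me1.bed, H3K4me3: h_me3.bed, H3K27ac: h_ac.bed}
          brain: {...}
        tss_table: genes.tsv
        chrom_sizes: chrom.sizes
        expression: heart_expression.tsv   # target tissue
        params: {expression_threshold: 20.0, ...}   # optional

    Writes CRE/domain BEDs, the assignment and category TSVs, and a
    JSON summary into ``out_dir``.
    """
    cfg = load_config(config_path)
    base = Path(config_path).parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    panels = {}
    for tissue, marks in cfg["tissues"].items():
        panels[tissue] = MarkPanel(
            tissue, {mark: read_bed(resolve(path)) for mark, path in marks.items()}
        )
    genes = read_tss_table(resolve(cfg["tss_table"]))
    sizes = read_chrom_sizes(resolve(cfg["chrom_sizes"]))
    expression = read_expression(resolve(cfg["expression"]))
    params = PipelineParams(**cfg.get("params", {}))

    report = run_discovery(panels, cfg["target"], genes, sizes, expression, params)
    write_report(report, out_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.category_table.to_csv(out / "categories.tsv", sep="\t")
    rows = [
        (a.cre.chrom, a.cre.start, a.cre.end, a.kind, a.specificity, a.gene_id, a.signed_distance)
        for a in report.specific_assignments + report.ubiquitous_assignments
    ]
    pd.DataFrame(
        rows,
        columns=["cre_chrom", "cre_start", "cre_end", "kind", "specificity", "gene_id", "signed_distance"],
    ).to_csv(out / "assignments.tsv", sep="\t", index=False)
    write_bed(out / "domains_extended.bed", (d.extended for d in report.domains))
    write_bed(out / "domains_basal.bed", (d.basal for d in report.domains))
    (out / "report.json").write_text(json.dumps(report.summary_dict(), indent=1, sort_keys=True))
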