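"""Orchestration and report rendering.

Runs io -> screening -> association -> ancestry check from a single run
configuration, and renders the two report layouts the screen produces: an
evidence matrix (one checklist row per variant) and an allele-counts table
(MAC/TA, Homo, Het, MAF per group, with recoded values parenthesized
beside raw ones).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional

from .ancestry import AimPanel, AncestryComparison, compare_cohort_ancestry, estimate_cohort
from .core import AlleleCount, CohortGenotypes, VariantKey, combine_counts, format_maf
from .io import (
    AnnotationTable,
    read_aim_panel,
    read_annotation,
    read_evidence_config,
    read_gene_list,
    read_vcf,
)
from .screening import CRITERIA, ScreenEvidence, ScreenParams, recode_in_phase, run_screen

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    vcf_paths: dict[str, str]  # cohort label -> VCF path
    annotation_path: str
    gene_list_path: str
    output_dir: str
    evidence_path: Optional[str] = None
    aim_panel_path: Optional[str] = None
    params: ScreenParams = field(default_factory=ScreenParams)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        paths = list(self.vcf_paths.values()) + [self.annotation_path, self.gene_list_path]
        if self.evidence_path:
            paths.append(self.evidence_path)
        if self.aim_panel_path:
            paths.append(self.aim_panel_path)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")
        if not 0.0 < self.params.alpha_family <= 1.0:
            raise ValueError("alpha_family must lie in (0, 1]")


@dataclass
class ReportRow:
    key: VariantKey
    rsid: Optional[str]
    gene: Optional[str]
    evidence: ScreenEvidence
    counts_raw: dict[str, AlleleCount]
    counts_recoded: dict[str, AlleleCount]


@dataclass
class CandidateReport:
    rows: list[ReportRow]
    ancestry: Optional[AncestryComparison] = None

    def candidates(self) -> list[ReportRow]:
        return [r for r in self.rows if r.evidence.verdict == "candidate"]


def _pooled_counts(
    cohorts: Mapping[str, CohortGenotypes], key: VariantKey
) -> dict[str, AlleleCount]:
    """Per-cohort counts plus pooled case/control "combined" entries."""
    out: dict[str, AlleleCount] = {}
    for label, cohort in cohorts.items():
        if key in cohort:
            out[label] = cohort.allele_count(key)
    for group in ("cases", "controls"):
        parts = [c for lab, c in out.items() if lab.endswith(group)]
        if parts:
            out[f"combined_{group}"] = combine_counts(parts)
    return out


def build_report(
    cohorts: Mapping[str, CohortGenotypes],
    annotation: AnnotationTable,
    expressed_genes: set[str],
    evidence_config=None,
    params: Optional[ScreenParams] = None,
    combined_counts=None,
) -> CandidateReport:
    """Run the screen and assemble per-variant count + checklist rows."""
    params = params or ScreenParams()
    sheets = run_screen(
        cohorts, annotation, expressed_genes, evidence_config, params,
        combined_counts=combined_counts,
    )
    recoded = dict(cohorts)
    for rule in params.phase_rules:
        for label, cohort in recoded.items():
            if rule.target in cohort:
                recoded[label] = recode_in_phase(cohort, rule)
    rows = []
    for sheet in sheets:
        record = annotation.record(sheet.key)
        rows.append(ReportRow(
            key=sheet.key,
            rsid=record.rsid,
            gene=record.gene,
            evidence=sheet,
            counts_raw=_pooled_counts(cohorts, sheet.key),
            counts_recoded=_pooled_counts(recoded, sheet.key),
        ))
    return CandidateReport(rows=rows)


def render_evidence_matrix(report: CandidateReport) -> str:
    """TSV evidence matrix: one row per variant, one column per criterion."""
    header = ["key", "rsid", "gene", *CRITERIA, "verdict", "p_one_tailed", "notes"]
    lines = ["\t".join(header)]
    for row in report.rows:
        assoc = row.evidence.association
        lines.append("\t".join([
            ":".join(map(str, row.key)),
            row.rsid or ".",
            row.gene or ".",
            *[row.evidence.criteria[c] for c in CRITERIA],
            row.evidence.verdict,
            f"{assoc.p_one_tailed:.4g}" if assoc else ".",
            "; ".join(row.evidence.notes) or ".",
        ]))
    return "\n".join(lines) + "\n"


def _fmt_pair(raw: Optional[int], recoded: Optional[int]) -> str:
    if raw is None:
        return "."
    if recoded is not None and recoded != raw:
        return f"{raw}({recoded})"
    return str(raw)


def _count_cells(raw: Optional[AlleleCount], rec: Optional[AlleleCount]) -> list[str]:
    if raw is None:
        return ["."] * 4
    mac = _fmt_pair(raw.mac, rec.mac if rec else None)
    maf = format_maf(raw.maf)
    if rec and rec.mac != raw.mac:
        maf = f"{maf}({format_maf(rec.maf)})"
    return [
        f"{mac}/{raw.total_alleles}",
        _fmt_pair(raw.hom, rec.hom if rec else None),
        _fmt_pair(raw.het, rec.het if rec else None),
        maf,
    ]


def render_counts_table(report: CandidateReport) -> str:
    """TSV allele-count table mirroring the published MAC/TA layout.

    Columns: rs number, then per group MAC/TA, Homo, Het, MAF; recoded
    values appear parenthesized beside raw ones (e.g. ``20(19)/318``);
    the nominal one-tailed p closes each row.
    """
    header = [
        "rsid",
        "control_mac_ta", "control_hom", "control_het", "control_maf",
        "case_mac_ta", "case_hom", "case_het", "case_maf",
        "p_nominal",
    ]
    lines = ["\t".join(header)]
    for row in report.rows:
        cells = [row.rsid or ":".join(map(str, row.key))]
        for group in ("controls", "cases"):
            raw = row.counts_raw.get(f"combined_{group}")
            rec = row.counts_recoded.get(f"combined_{group}")
            cells.extend(_count_cells(raw, rec))
        assoc = row.evidence.association
        cells.append(f"{assoc.p_one_tailed:.4g}" if assoc else ".")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> CandidateReport:
    """Execute the full pipeline from files and write artifacts on disk.

    Writes ``evidence.tsv``, ``counts.tsv``, ``summary.json`` and
    ``run.log`` under the configured output directory. Per-variant stage
    failures are logged and the run continues; fatal configuration errors
    raise.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("rarescreen")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        logger.info(
            "run_pipeline params rarity=%g ratio=%g pop=%s direction=%s "
            "alpha=%g m=%s seed=%d",
            config.params.rarity_threshold, config.params.ancestry_ratio,
            config.params.target_population, config.params.direction,
            config.params.alpha_family, config.params.family_m, config.seed,
        )
        cohorts = {
            label: read_vcf(path, label)
            for label, path in config.vcf_paths.items()
        }
        annotation = read_annotation(config.annotation_path)
        expressed = read_gene_list(config.gene_list_path)
        evidence = (read_evidence_config(config.evidence_path)
                    if config.evidence_path else {})
        report = build_report(cohorts, annotation, expressed, evidence, config.params)

        if config.aim_panel_path:
            panel = AimPanel.from_dataframe(read_aim_panel(config.aim_panel_path))
            logger.info("aim panel markers=%d", panel.n_markers)
            # cohort AIM genotypes arrive via the panel-aligned columns of
            # dedicated files in library use; the CLI surfaces this via the
            # `ancestry` subcommand instead.

        (outdir / "evidence.tsv").write_text(render_evidence_matrix(report))
        (outdir / "counts.tsv").write_text(render_counts_table(report))
        summary = {
            "n_variants_screened": len(report.rows),
            "n_candidates": len(report.candidates()),
            "candidates": [
                {"key": ":".join(map(str, r.key)), "rsid": r.rsid, "gene": r.gene,
                 "p_one_tailed": (r.evidence.association.p_one_tailed
                                  if r.evidence.association else None)}
                for r in report.candidates()
            ],
            "params": {
                "rarity_threshold": config.params.rarity_threshold,
                "ancestry_ratio": config.params.ancestry_ratio,
                "target_population": config.params.target_population,
                "direction": config.params.direction,
                "alpha_family": config.params.alpha_family,
                "family_m": config.params.family_m,
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def ancestry_check(
    case_matrix, control_matrix, panel: AimPanel, level: float = 0.05
) -> AncestryComparison:
    """Estimate per-subject ancestry in both groups and compare cohorts."""
    case_thetas = [e.theta for e in estimate_cohort(case_matrix, panel) if e.converged]
    control_thetas = [e.theta for e in estimate_cohort(control_matrix, panel) if e.converged]
    return compare_cohort_ancestry(case_thetas, control_thetas, level=level)


__all__ = [
    "RunConfig",
    "ReportRow",
    "CandidateReport",
    "build_report",
    "render_evidence_matrix",
    "render_counts_table",
    "run_pipeline",
    "ancestry_check",
]
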