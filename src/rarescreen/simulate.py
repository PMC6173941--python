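"""Synthetic case/control cohorts with the structure the screen assumes.

Generates discovery and replication cohorts under Hardy-Weinberg sampling
at configured allele frequencies: planted risk variants with distinct
case/control frequencies, an optional in-phase modifier SNP drawn
conditionally on target carriage, neutral rare background nonsense
variants, admixture-linked ancestry-informative markers (AIMs) with
per-subject ancestry proportions drawn from truncated normal distributions,
and a truth table. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ancestry import AimPanel
from .core import CohortGenotypes, PopulationFrequencies, VariantRecord
from .io import AnnotationTable, write_annotation, write_vcf

#: Default cohort sizes: the discovery exome panel plus replication waves
#: sized so that pooled totals match the combined MAC/TA tables
#: (347 cases / 375 controls overall).
DEFAULT_COHORT_SIZES = {
    "discovery_cases": 76,
    "discovery_controls": 43,
    "replication_cases": 271,
    "replication_controls": 332,
}

#: Default ancestry-proportion distributions (mean, SD of the truncated
#: normal on [0, 1]) per phenotype group: West African ancestry fractions
#: reported for the study populations.
DEFAULT_ANCESTRY = {
    "cases": (0.695, 0.073),
    "controls": (0.698, 0.087),
}

#: Point masses the neutral background allele frequencies are drawn from.
BACKGROUND_AF_CHOICES = (1e-4, 2.5e-4, 5e-4, 1e-3, 2.5e-3, 5e-3)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModifierSpec:
    """In-phase modifier SNP riding on target-carrier haplotypes.

    Each carried target allele independently also carries the modifier
    minor allele with probability ``co_carriage_prob``.
    """

    record: VariantRecord
    co_carriage_prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.co_carriage_prob <= 1.0:
            raise ConfigError("co_carriage_prob must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedVariant:
    """A risk (or protective) variant planted at known frequencies."""

    record: VariantRecord
    case_af: float
    control_af: float
    pop_afs: Mapping[str, float] = field(default_factory=dict)
    ancestry_label: Optional[str] = "AFR"
    modifier: Optional[ModifierSpec] = None

    def __post_init__(self) -> None:
        for af in (self.case_af, self.control_af):
            if not 0.0 <= af <= 1.0:
                raise ConfigError(f"planted allele frequency {af} outside [0, 1]")


@dataclass(frozen=True)
class AimSpec:
    """AIM panel shape: marker count and minimum ancestral-frequency gap."""

    n_markers: int = 500
    delta_min: float = 0.4
    delta_max: float = 0.5


@dataclass
class SimulationConfig:
    seed: int
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    planted: list[PlantedVariant] = field(default_factory=list)
    n_background: int = 100
    background_af_choices: Sequence[float] = BACKGROUND_AF_CHOICES
    aims: Optional[AimSpec] = field(default_factory=AimSpec)
    ancestry: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY)
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for label, n in self.cohort_sizes.items():
            if n < 1:
                raise ConfigError(f"cohort {label} must have >= 1 subject")


@dataclass(frozen=True)
class TruthRecord:
    key: tuple
    is_risk: bool
    case_af: float
    control_af: float


@dataclass
class SimulatedStudy:
    cohorts: dict[str, CohortGenotypes]
    annotation: AnnotationTable
    expressed_genes: set[str]
    truth: list[TruthRecord]
    aim_panel: Optional[AimPanel] = None
    aim_genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    ancestry_truth: dict[str, np.ndarray] = field(default_factory=dict)


def truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int,
    low: float = 0.0, high: float = 1.0,
) -> np.ndarray:
    """Normal(mean, sd) truncated to [low, high] by rejection sampling."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        keep = draw[(draw >= low) & (draw <= high)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _hwe_column(rng: np.random.Generator, af: float, n: int) -> np.ndarray:
    """Hardy-Weinberg dosages: Binomial(2, af) per subject."""
    return rng.binomial(2, af, size=n).astype(np.int8)


def simulate_aim_panel(rng: np.random.Generator, spec: AimSpec) -> AimPanel:
    """Panel with |f_afr - f_eur| >= delta_min at every marker."""
    f_eur = rng.uniform(0.05, 0.5, size=spec.n_markers)
    delta = rng.uniform(spec.delta_min, spec.delta_max, size=spec.n_markers)
    f_afr = np.minimum(f_eur + delta, 0.99)
    markers = tuple(f"AIM{i:04d}" for i in range(spec.n_markers))
    return AimPanel(markers=markers, f_pop1=f_afr, f_pop2=f_eur)


def simulate_aim_genotypes(
    rng: np.random.Generator, panel: AimPanel, thetas: np.ndarray
) -> np.ndarray:
    """Subjects x markers dosage matrix given per-subject theta."""
    p = thetas[:, None] * panel.f_pop1[None, :] + (1 - thetas[:, None]) * panel.f_pop2[None, :]
    return rng.binomial(2, p).astype(np.int8)


#: Fractions of neutral background nonsense variants surviving each
#: annotation-based stage, emulating the published funnel in which a few
#: hundred case-only nonsense variants reduce to a handful carried into
#: replication: high-confidence LoF calls, ancestry-concentrated reference
#: frequencies, and fetal-membrane expression with literature support.
BACKGROUND_FUNNEL = {
    "p_lof_hc": 0.9,
    "p_ancestry_specific": 0.6,
    "p_expressed": 0.15,
}


def _background_record(i: int, seed_tag: int, lof_hc: bool) -> VariantRecord:
    # spread across synthetic positions on one autosome; gene symbols are
    # synthetic and unique per variant
    return VariantRecord(
        chrom="chr2",
        pos=10_000_000 + 1_000 * i,
        ref="C",
        alt="T",
        rsid=None,
        gene=f"BGN{seed_tag % 97:02d}G{i:04d}",
        transcript=None,
        consequence="stop_gained",
        lof_confidence="HC" if lof_hc else "LC",
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Draw a full synthetic study from one seed.

    Planted variants use their case AF in ``*_cases`` cohorts and control
    AF in ``*_controls`` cohorts; background variants share one frequency
    across groups (no effect). Modifier SNPs are drawn per carried target
    allele. Ancestry is simulated independently of risk-variant carriage.
    """
    rng = np.random.default_rng(config.seed)

    for planted in config.planted:
        if planted.modifier is not None and planted.modifier.record.key == planted.record.key:
            raise ConfigError("modifier must differ from its target")

    background_afs = rng.choice(
        np.asarray(config.background_af_choices, dtype=float),
        size=config.n_background,
    )
    funnel = BACKGROUND_FUNNEL
    bg_hc = rng.random(config.n_background) < funnel["p_lof_hc"]
    bg_specific = rng.random(config.n_background) < funnel["p_ancestry_specific"]
    bg_expressed = rng.random(config.n_background) < funnel["p_expressed"]
    background = [
        (_background_record(i, config.seed, bool(bg_hc[i])), float(background_afs[i]))
        for i in range(config.n_background)
    ]

    truth: list[TruthRecord] = []
    ann_entries = []
    expressed: set[str] = set()

    for planted in config.planted:
        truth.append(TruthRecord(planted.record.key, planted.case_af != planted.control_af,
                                 planted.case_af, planted.control_af))
        af_by_pop = {pop: planted.pop_afs.get(pop, 0.0) for pop in
                     ("AFR", "AMR", "EAS", "SAS", "EUR")}
        ann_entries.append((
            planted.record,
            PopulationFrequencies(af_global=planted.control_af, af_by_pop=af_by_pop,
                                  source_version="simulated"),
            planted.ancestry_label,
        ))
        expressed.add(planted.record.gene or "")
        if planted.modifier is not None:
            mod = planted.modifier.record
            ann_entries.append((
                mod,
                PopulationFrequencies(
                    af_global=planted.control_af * planted.modifier.co_carriage_prob,
                    af_by_pop={p: 0.0 for p in ("AFR", "AMR", "EAS", "SAS", "EUR")},
                    source_version="simulated",
                ),
                planted.ancestry_label,
            ))
    for i, (record, af) in enumerate(background):
        truth.append(TruthRecord(record.key, False, af, af))
        if bg_specific[i]:
            af_by_pop = {"AFR": min(5 * af, 1.0), "AMR": 0.0, "EAS": 0.0,
                         "SAS": 0.0, "EUR": 0.0}
        else:  # frequency spread across populations -> not ancestry-specific
            af_by_pop = {p: af for p in ("AFR", "AMR", "EAS", "SAS", "EUR")}
        ann_entries.append((
            record,
            PopulationFrequencies(af_global=af, af_by_pop=af_by_pop,
                                  source_version="simulated"),
            "AFR" if bg_specific[i] else None,
        ))
        if bg_expressed[i]:
            expressed.add(record.gene or "")
    annotation = AnnotationTable.from_records(ann_entries)

    cohorts: dict[str, CohortGenotypes] = {}
    for label, n in config.cohort_sizes.items():
        is_case = label.endswith("cases")
        records: list[VariantRecord] = []
        columns: list[np.ndarray] = []
        for planted in config.planted:
            af = planted.case_af if is_case else planted.control_af
            target_col = _hwe_column(rng, af, n)
            records.append(planted.record)
            columns.append(target_col)
            if planted.modifier is not None:
                mod_col = rng.binomial(
                    target_col.astype(np.int64), planted.modifier.co_carriage_prob
                ).astype(np.int8)
                records.append(planted.modifier.record)
                columns.append(mod_col)
        for record, af in background:
            records.append(record)
            columns.append(_hwe_column(rng, af, n))
        matrix = (np.column_stack(columns) if columns
                  else np.zeros((n, 0), dtype=np.int8))
        subjects = [f"{label}_{i:04d}" for i in range(n)]
        cohorts[label] = CohortGenotypes(
            label=label, subjects=subjects, variants=records, genotypes=matrix
        )

    study = SimulatedStudy(
        cohorts=cohorts,
        annotation=annotation,
        expressed_genes={g for g in expressed if g},
        truth=truth,
    )

    if config.aims is not None:
        study.aim_panel = simulate_aim_panel(rng, config.aims)
        for label, n in config.cohort_sizes.items():
            group = "cases" if label.endswith("cases") else "controls"
            mean, sd = config.ancestry.get(group, DEFAULT_ANCESTRY[group])
            thetas = truncated_normal(rng, mean, sd, n)
            study.ancestry_truth[label] = thetas
            study.aim_genotypes[label] = simulate_aim_genotypes(
                rng, study.aim_panel, thetas
            )
    return study


def defb1_like_variant(modifier: bool = False) -> PlantedVariant:
    """A planted risk variant at the combined-cohort frequency contrast of
    the study's index stop-gain (case AF 0.0144 vs control AF 0.0013)."""
    record = VariantRecord(
        chrom="chr8", pos=6_728_299, ref="G", alt="T", rsid="rs5743490",
        gene="DEFB1", consequence="stop_gained", lof_confidence="HC",
    )
    spec = None
    if modifier:
        spec = ModifierSpec(
            record=VariantRecord(
                chrom="chr8", pos=6_728_300, ref="G", alt="T",
                gene="DEFB1", consequence="missense", lof_confidence="none",
            ),
            co_carriage_prob=0.05,
        )
    return PlantedVariant(
        record=record, case_af=0.0144, control_af=0.0013,
        pop_afs={"AFR": 0.003}, ancestry_label="AFR", modifier=spec,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write a simulated study through the standard formats.

    One VCF per cohort, the annotation TSV, the expressed-gene list, the
    AIM panel TSV plus per-cohort AIM dosage TSVs, ancestry truth, and the
    variant truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, cohort in study.cohorts.items():
        write_vcf(cohort, outdir / f"{label}.vcf")
    write_annotation(study.annotation, outdir / "annotation.tsv")
    (outdir / "expressed_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(study.expressed_genes))
    )
    pd.DataFrame(
        [{"key": ":".join(map(str, t.key)), "is_risk": t.is_risk,
          "case_af": t.case_af, "control_af": t.control_af} for t in study.truth]
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if study.aim_panel is not None:
        pd.DataFrame({
            "marker": study.aim_panel.markers,
            "chrom": "chr1",
            "pos": np.arange(1, study.aim_panel.n_markers + 1) * 1000,
            "counted_allele": "A",
            "f_afr": study.aim_panel.f_pop1,
            "f_eur": study.aim_panel.f_pop2,
        }).to_csv(outdir / "aim_panel.tsv", sep="\t", index=False)
        for label, matrix in study.aim_genotypes.items():
            pd.DataFrame(
                matrix, columns=list(study.aim_panel.markers),
                index=study.cohorts[label].subjects,
            ).to_csv(outdir / f"aims_{label}.tsv", sep="\t")
        for label, thetas in study.ancestry_truth.items():
            pd.DataFrame({
                "subject": study.cohorts[label].subjects, "theta": thetas
            }).to_csv(outdir / f"ancestry_truth_{label}.tsv", sep="\t", index=False)


__all__ = [
    "DEFAULT_COHORT_SIZES",
    "DEFAULT_ANCESTRY",
    "BACKGROUND_AF_CHOICES",
    "ConfigError",
    "ModifierSpec",
    "PlantedVariant",
    "AimSpec",
    "SimulationConfig",
    "TruthRecord",
    "SimulatedStudy",
    "truncated_normal",
    "simulate_aim_panel",
    "simulate_aim_genotypes",
    "simulate_cohort",
    "defb1_like_variant",
    "write_study",
]
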