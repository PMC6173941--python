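"""The nine-criterion selection strategy as an executable filter cascade.

A discovery exome screen for rare, ancestry-specific, high-confidence
nonsense alleles present only in cases, followed by manual evidence flags
(Sanger validation, selective pressure, heterozygous impact, plausible
pathophysiology — supplied by config, never computed), an in-phase
modifier-SNP recoding rule, and a replication association test. The cascade
is monotone: each stage's survivors are a subset of its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .association import AssociationResult, associate, bonferroni_alpha
from .core import (
    AlleleCount,
    CohortGenotypes,
    NONSENSE_CONSEQUENCES,
    POPULATIONS,
    VariantKey,
    VariantRecord,
    combine_counts,
)
from .io import AnnotationTable

logger = logging.getLogger(__name__)

#: Criterion names in checklist order.
CRITERIA = (
    "case_only",
    "validated",
    "rare",
    "ancestry_specific",
    "selective_pressure",
    "het_impact_plausible",
    "expressed",
    "plausible_pathophysiology",
    "replicated",
)

#: Criteria the pipeline computes (the rest are manual evidence flags).
COMPUTATIONAL_CRITERIA = frozenset(
    {"case_only", "rare", "ancestry_specific", "expressed", "replicated"}
)

_MANUAL_MAP = {
    "validated": "sanger_validated",
    "selective_pressure": "selective_pressure",
    "het_impact_plausible": "heterozygous_impact_plausible",
    "plausible_pathophysiology": "plausible_pathophysiology",
}

PASS, FAIL, UNKNOWN = "pass", "fail", "unknown"


@dataclass(frozen=True)
class PhaseRule:
    """Declared in-phase pair: a modifier allele rescuing a nonsense allele.

    Subjects co-carrying both minor alleles are reclassified as carrying the
    combined-haplotype consequence (typically a benign missense) instead of
    the nonsense allele.
    """

    target: VariantKey
    modifier: VariantKey
    effect: str = "missense"

    def __post_init__(self) -> None:
        if self.target == self.modifier:
            raise ValueError("phase rule target and modifier must differ")
        if self.target[0] != self.modifier[0]:
            raise ValueError("phase rule pair must be on the same chromosome")


@dataclass
class ScreenEvidence:
    """Nine-criterion checklist for one variant, with a final verdict.

    verdict is ``candidate`` iff no criterion is *fail* and every
    computational criterion is *pass*; ``rejected`` iff any criterion is
    *fail*; otherwise ``indeterminate``. Manual criteria left *unknown* do
    not block candidacy but are reported.
    """

    key: VariantKey
    criteria: dict[str, str] = field(
        default_factory=lambda: {c: UNKNOWN for c in CRITERIA}
    )
    notes: list[str] = field(default_factory=list)
    association: Optional[AssociationResult] = None

    @property
    def verdict(self) -> str:
        values = self.criteria.values()
        if FAIL in values:
            return "rejected"
        if all(self.criteria[c] == PASS for c in COMPUTATIONAL_CRITERIA):
            return "candidate"
        return "indeterminate"


@dataclass
class ScreenParams:
    """Tunable screen parameters (all surfaced in reports and logs)."""

    rarity_threshold: float = 0.01
    ancestry_ratio: float = 5.0
    target_population: str = "AFR"
    direction: str = "case_only"  # or "control_only" for protective screens
    alpha_family: float = 0.05
    family_m: Optional[int] = None  # default: number of variants reaching replication
    phase_rules: list[PhaseRule] = field(default_factory=list)


# ---------------------------------------------------------------------------
# individual filters


def filter_damaging_nonsense(annotation: AnnotationTable) -> set[VariantKey]:
    """Step-1 consequence filter: high-confidence nonsense records only.

    Keeps stop-gain / stop-loss / start-loss records whose loss-of-function
    call is high confidence (HC). Frameshift and splicing records never
    enter the table by construction.
    """
    kept = {
        key
        for key in annotation.keys()
        if annotation.record(key).consequence in NONSENSE_CONSEQUENCES
        and annotation.record(key).lof_confidence == "HC"
    }
    logger.info("filter=damaging_nonsense in=%d out=%d", len(annotation), len(kept))
    return kept


def case_only_filter(
    variants: Iterable[VariantKey],
    cases: CohortGenotypes,
    controls: CohortGenotypes,
    direction: str = "case_only",
) -> set[VariantKey]:
    """Keep variants carried only in one phenotype group of the discovery panel.

    ``case_only`` keeps keys with MAC >= 1 in cases and MAC = 0 in controls;
    ``control_only`` (a protective-variant screen) reverses the roles. A
    variant absent from a cohort counts as unobserved (MAC 0) with a warning.
    """
    if direction not in ("case_only", "control_only"):
        raise ValueError(f"unknown direction {direction!r}")
    carrier, clean = (cases, controls) if direction == "case_only" else (controls, cases)
    kept = set()
    variants = set(variants)
    for key in variants:
        for cohort in (cases, controls):
            if key not in cohort:
                logger.warning(
                    "variant %s absent from cohort %s; treated as unobserved",
                    key, cohort.label,
                )
        mac_carrier = carrier.allele_count(key).mac if key in carrier else 0
        mac_clean = clean.allele_count(key).mac if key in clean else 0
        if mac_carrier >= 1 and mac_clean == 0:
            kept.add(key)
    logger.info("filter=%s in=%d out=%d", direction, len(variants), len(kept))
    return kept


def rarity_filter(
    variants: Iterable[VariantKey],
    annotation: AnnotationTable,
    threshold: float = 0.01,
) -> tuple[set[VariantKey], set[VariantKey]]:
    """Step-3 rarity filter: global reference AF strictly below threshold.

    Returns (kept, indeterminate); a key with no reported global frequency
    is routed to the indeterminate set, never dropped silently.
    """
    kept, indeterminate = set(), set()
    variants = set(variants)
    for key in variants:
        af = annotation.frequencies(key).af_global if key in annotation else None
        if af is None:
            indeterminate.add(key)
        elif af < threshold:
            kept.add(key)
    logger.info(
        "filter=rarity threshold=%g in=%d out=%d indeterminate=%d",
        threshold, len(variants), len(kept), len(indeterminate),
    )
    return kept, indeterminate


def ancestry_specificity(
    key: VariantKey,
    annotation: AnnotationTable,
    target_pop: str = "AFR",
    ratio: float = 5.0,
) -> str:
    """Ancestry-specificity call for one variant: pass / fail / indeterminate.

    Passes iff the target-population AF is positive and at least ``ratio``
    times the largest AF in any other population; indeterminate if any
    population's AF is unreported. The ratio rule quantifies the study's
    qualitative "of <target> ancestry" criterion and is parameterized so it
    stays visible in reports.
    """
    if target_pop not in POPULATIONS:
        raise ValueError(f"unknown population code {target_pop!r}")
    freqs = annotation.frequencies(key).af_by_pop
    values = {pop: freqs.get(pop) for pop in POPULATIONS}
    if any(v is None for v in values.values()):
        return UNKNOWN
    target_af = values[target_pop]
    other_max = max(v for pop, v in values.items() if pop != target_pop)
    if target_af > 0 and target_af >= ratio * other_max:
        return PASS
    return FAIL


def expression_filter(
    variants: Iterable[VariantKey],
    annotation: AnnotationTable,
    expressed_genes: set[str],
) -> set[VariantKey]:
    """Step-7 tissue-expression filter (case-insensitive gene-symbol match)."""
    expressed = {g.upper() for g in expressed_genes}
    variants = set(variants)
    kept = {
        key
        for key in variants
        if key in annotation
        and (annotation.record(key).gene or "").upper() in expressed
    }
    logger.info("filter=expression in=%d out=%d", len(variants), len(kept))
    return kept


def recode_in_phase(cohort: CohortGenotypes, rule: PhaseRule) -> CohortGenotypes:
    """Reclassify co-carried nonsense + modifier alleles as the joint haplotype.

    Per subject, the target (nonsense) dosage is reduced by
    ``min(target dosage, modifier dosage)`` — assuming the two minor alleles
    are in cis whenever co-carried — and the removed dosage is credited to a
    synthetic record appended to the cohort carrying the combined-haplotype
    consequence. Total site dosage is conserved per subject. If the modifier
    column is absent the cohort is returned unchanged with a warning.
    """
    if rule.target not in cohort:
        raise KeyError(f"phase-rule target {rule.target} absent from cohort {cohort.label}")
    if rule.modifier not in cohort:
        logger.warning(
            "phase-rule modifier %s absent from cohort %s; recoding skipped",
            rule.modifier, cohort.label,
        )
        return cohort
    out = cohort.copy()
    target_col = out.column(rule.target)
    modifier_col = out.column(rule.modifier)
    called = (target_col >= 0) & (modifier_col >= 0)
    moved = np.where(called, np.minimum(target_col, modifier_col), 0).astype(np.int8)
    target_col -= moved  # in-place on the copy's matrix
    target_rec = out.record(rule.target)
    synthetic = VariantRecord(
        chrom=target_rec.chrom,
        pos=target_rec.pos,
        ref=target_rec.ref,
        # synthetic joint-haplotype record: distinct key via lowercase-free
        # convention is impossible within ACGT, so extend the alt allele
        alt=target_rec.alt + rule.modifier[3],
        rsid=None,
        gene=target_rec.gene,
        transcript=target_rec.transcript,
        consequence=rule.effect if rule.effect in
        {"missense", "synonymous", "other"} else "other",
        lof_confidence="none",
    )
    moved_masked = np.where(target_col >= 0, moved, np.int8(-1))
    result = out.with_variant(synthetic, moved_masked)
    n_recoded = int(moved.sum())
    if n_recoded:
        logger.info(
            "recode_in_phase cohort=%s target=%s modifier=%s alleles_moved=%d",
            cohort.label, rule.target, rule.modifier, n_recoded,
        )
    return result


# ---------------------------------------------------------------------------
# full screen


def _count_for(
    key: VariantKey,
    cohorts: Mapping[str, CohortGenotypes],
    labels: Sequence[str],
) -> Optional[AlleleCount]:
    counts = [
        cohorts[lab].allele_count(key)
        for lab in labels
        if lab in cohorts and key in cohorts[lab]
    ]
    return combine_counts(counts) if counts else None


def run_screen(
    cohorts: Mapping[str, CohortGenotypes],
    annotation: AnnotationTable,
    expressed_genes: set[str],
    evidence: Mapping[VariantKey, Mapping[str, Optional[bool]]] | None = None,
    params: ScreenParams | None = None,
    combined_counts: Mapping[VariantKey, tuple[AlleleCount, AlleleCount]] | None = None,
) -> list[ScreenEvidence]:
    """Run the full selection cascade and emit one checklist per variant.

    Stages, in order: damaging-nonsense filter -> case-only filter on the
    discovery panel -> rarity -> ancestry specificity -> expression ->
    manual evidence flags -> in-phase recoding -> replication association.
    Replication counts come either from replication cohorts in ``cohorts``
    (pooled with discovery) or from ``combined_counts`` mapping each key to
    a (case, control) AlleleCount pair; with neither, the replication
    criterion stays *unknown*.

    A stage failure for one variant never aborts the run; the failure is
    recorded on that variant's checklist.
    """
    params = params or ScreenParams()
    evidence = evidence or {}
    if "discovery_cases" not in cohorts or "discovery_controls" not in cohorts:
        raise ValueError("discovery_cases and discovery_controls cohorts are required")
    cases = cohorts["discovery_cases"]
    controls = cohorts["discovery_controls"]

    step1 = filter_damaging_nonsense(annotation)
    sheets = {key: ScreenEvidence(key=key) for key in sorted(step1)}

    survivors = set(step1)

    # discovery presence/absence
    kept = case_only_filter(survivors, cases, controls, params.direction)
    for key in survivors:
        sheets[key].criteria["case_only"] = PASS if key in kept else FAIL
    survivors = kept

    # reference-database rarity
    kept, indeterminate = rarity_filter(survivors, annotation, params.rarity_threshold)
    for key in survivors:
        if key in kept:
            sheets[key].criteria["rare"] = PASS
        elif key in indeterminate:
            sheets[key].criteria["rare"] = UNKNOWN
            sheets[key].notes.append("no reference allele frequency reported")
        else:
            sheets[key].criteria["rare"] = FAIL
    survivors = kept

    # ancestry specificity
    next_survivors = set()
    for key in survivors:
        call = ancestry_specificity(
            key, annotation, params.target_population, params.ancestry_ratio
        )
        sheets[key].criteria["ancestry_specific"] = call
        label = annotation.ancestry_label(key)
        if call == PASS and label and label != params.target_population:
            sheets[key].notes.append(
                f"curated ancestry label {label} disagrees with computed "
                f"{params.target_population} call"
            )
            logger.warning("variant %s: curated label %s vs computed %s",
                           key, label, params.target_population)
        if call == PASS:
            next_survivors.add(key)
    survivors = next_survivors

    # fetal-membrane expression
    kept = expression_filter(survivors, annotation, expressed_genes)
    for key in survivors:
        sheets[key].criteria["expressed"] = PASS if key in kept else FAIL
    survivors = kept

    # manual evidence flags (three-state; unknown never blocks candidacy)
    for key, sheet in sheets.items():
        flags = evidence.get(key, {})
        for criterion, config_name in _MANUAL_MAP.items():
            flag = flags.get(config_name)
            sheet.criteria[criterion] = (
                UNKNOWN if flag is None else (PASS if flag else FAIL)
            )

    # in-phase recoding on every cohort that carries both columns
    recoded_cohorts = dict(cohorts)
    for rule in params.phase_rules:
        for label, cohort in recoded_cohorts.items():
            if rule.target in cohort:
                recoded_cohorts[label] = recode_in_phase(cohort, rule)
                if rule.target in survivors:
                    sheets[rule.target].notes.append(
                        f"in-phase recoding applied against modifier {rule.modifier}"
                    )

    # replication association on the survivors
    case_labels = ["discovery_cases", "replication_cases"]
    control_labels = ["discovery_controls", "replication_controls"]
    has_replication = (
        "replication_cases" in cohorts and "replication_controls" in cohorts
    )
    m = params.family_m or max(len(survivors), 1)
    for key in sorted(survivors):
        sheet = sheets[key]
        pair: Optional[tuple[AlleleCount, AlleleCount]] = None
        if combined_counts and key in combined_counts:
            pair = combined_counts[key]
        elif has_replication:
            case_count = _count_for(key, recoded_cohorts, case_labels)
            control_count = _count_for(key, recoded_cohorts, control_labels)
            if case_count and control_count:
                pair = (case_count, control_count)
        if pair is None:
            sheet.criteria["replicated"] = UNKNOWN
            sheet.notes.append("no replication data available")
            continue
        try:
            result = associate(key, pair[0], pair[1], params.alpha_family, m)
        except ValueError as exc:
            sheet.criteria["replicated"] = UNKNOWN
            sheet.notes.append(f"replication test failed: {exc}")
            logger.warning("variant %s replication error: %s", key, exc)
            continue
        sheet.association = result
        sheet.criteria["replicated"] = PASS if result.significant else FAIL
        maf = float(pair[0].maf)
        if maf >= params.rarity_threshold:
            sheet.notes.append(
                f"cohort case MAF {maf:.3f} exceeds rarity threshold "
                f"{params.rarity_threshold:g}"
            )
    logger.info(
        "screen complete variants=%d replication_family_m=%d candidates=%d",
        len(sheets), m,
        sum(1 for s in sheets.values() if s.verdict == "candidate"),
    )
    return list(sheets.values())


__all__ = [
    "CRITERIA",
    "COMPUTATIONAL_CRITERIA",
    "PASS",
    "FAIL",
    "UNKNOWN",
    "PhaseRule",
    "ScreenEvidence",
    "ScreenParams",
    "filter_damaging_nonsense",
    "case_only_filter",
    "rarity_filter",
    "ancestry_specificity",
    "expression_filter",
    "recode_in_phase",
    "run_screen",
]
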