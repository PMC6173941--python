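"""Core domain types and allele-count arithmetic.

The whole pipeline reasons about single-alt-allele variant records, cohort
genotype matrices of minor-allele dosages, and the MAC/TA (minor allele
count / total alleles) summaries that case/control exome reports tabulate.
Missing genotypes shrink the denominator: only high-confidence calls enter
either the numerator or the total-allele count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: Sentinel for a missing (un-called) genotype in dosage matrices.
MISSING: int = -1

#: Valid functional-consequence labels for a split variant record.
CONSEQUENCES = frozenset(
    {"stop_gained", "stop_lost", "start_lost", "missense", "synonymous", "other"}
)

#: Consequences classed as nonsense (premature stop / lost stop / lost start).
NONSENSE_CONSEQUENCES = frozenset({"stop_gained", "stop_lost", "start_lost"})

#: Loss-of-function confidence vocabulary (gnomAD-style LOFTEE calls).
LOF_CONFIDENCE = frozenset({"HC", "LC", "none"})

#: Continental population codes used for per-population allele frequencies.
POPULATIONS = ("AFR", "AMR", "EAS", "SAS", "EUR")

VariantKey = tuple[str, int, str, str]


class InvalidGenotypeError(ValueError):
    """A dosage outside {0, 1, 2, missing} was encountered."""


class UndefinedFrequencyError(ZeroDivisionError):
    """A frequency was requested over zero total alleles."""


class CountMismatchError(ValueError):
    """Allele counts for different variants were combined."""


@dataclass(frozen=True)
class VariantRecord:
    """One alternate allele at one genomic site.

    Multi-allelic sites are split upstream so each record carries exactly one
    ``alt``; ``(chrom, pos, ref, alt)`` is the unique key. Coordinates are
    1-based and chromosome names are kept verbatim ("chr"-prefixed).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None
    gene: Optional[str] = None
    transcript: Optional[str] = None
    consequence: str = "other"
    lof_confidence: str = "none"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"{name} must be a nonempty ACGT string, got {allele!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.lof_confidence not in LOF_CONFIDENCE:
            raise ValueError(f"unknown lof_confidence {self.lof_confidence!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_nonsense(self) -> bool:
        return self.consequence in NONSENSE_CONSEQUENCES


@dataclass(frozen=True)
class PopulationFrequencies:
    """Global and per-population allele frequencies for one variant.

    ``None`` in ``af_by_pop`` means the frequency is unreported for that
    population (distinct from zero).
    """

    af_global: Optional[float]
    af_by_pop: Mapping[str, Optional[float]] = field(default_factory=dict)
    source_version: str = ""

    def __post_init__(self) -> None:
        for name, value in [("af_global", self.af_global)] + [
            (pop, af) for pop, af in self.af_by_pop.items()
        ]:
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"frequency {name}={value} outside [0, 1]")


@dataclass(frozen=True)
class AlleleCount:
    """Hom/het/MAC/total-allele summary for one variant in one cohort.

    Invariants: ``mac = 2*hom + het`` and ``mac <= total_alleles``. Counts
    derived from diploid genotype columns always have an even
    ``total_alleles``; counts transcribed from published tables may not
    (published totals occasionally include half-called subjects).
    """

    hom: int
    het: int
    total_alleles: int
    key: Optional[VariantKey] = None

    def __post_init__(self) -> None:
        if min(self.hom, self.het, self.total_alleles) < 0:
            raise ValueError("counts must be nonnegative")
        if self.mac > self.total_alleles:
            raise ValueError(
                f"mac {self.mac} exceeds total alleles {self.total_alleles}"
            )

    @property
    def mac(self) -> int:
        return 2 * self.hom + self.het

    @property
    def maf(self) -> Fraction:
        return compute_maf(self.mac, self.total_alleles)


def count_alleles(
    column: Sequence[int] | np.ndarray, key: Optional[VariantKey] = None
) -> AlleleCount:
    """Tally an AlleleCount from a genotype-dosage column.

    Dosages must be in {0, 1, 2, MISSING}; missing entries are excluded from
    both the carrier tallies and the total-allele denominator.
    """
    arr = np.asarray(column, dtype=np.int64)
    valid = {0, 1, 2, MISSING}
    seen = set(np.unique(arr).tolist())
    if seen - valid:
        raise InvalidGenotypeError(f"dosages outside {{0,1,2,missing}}: {sorted(seen - valid)}")
    called = arr[arr != MISSING]
    hom = int(np.count_nonzero(called == 2))
    het = int(np.count_nonzero(called == 1))
    return AlleleCount(hom=hom, het=het, total_alleles=2 * called.size, key=key)


def compute_maf(mac: int, total_alleles: int) -> Fraction:
    """Minor allele frequency as an exact ratio.

    Rounding for display is a formatting concern; see :func:`format_maf`.
    """
    if total_alleles == 0:
        raise UndefinedFrequencyError("MAF undefined over zero total alleles")
    if not 0 <= mac <= total_alleles:
        raise ValueError(f"mac {mac} outside [0, {total_alleles}]")
    return Fraction(mac, total_alleles)


def format_maf(maf: Fraction | float, decimals: Optional[int] = None) -> str:
    """Display-round a frequency: 4 decimals below 0.05, else 3.

    Matches the mixed precision of published MAC/TA tables (e.g. 0.0144 and
    0.0013 for rare alleles, 0.060 for common ones).
    """
    value = float(maf)
    if decimals is None:
        decimals = 4 if value < 0.05 else 3
    return f"{value:.{decimals}f}"


def combine_counts(counts: Iterable[AlleleCount]) -> AlleleCount:
    """Component-wise sum of allele counts across cohorts of one phenotype.

    All counts must refer to the same variant (when keys are attached);
    combining is associative and commutative and an empty-cohort count is the
    identity.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("cannot combine an empty sequence of counts")
    keys = {c.key for c in counts if c.key is not None}
    if len(keys) > 1:
        raise CountMismatchError(f"mixed variant keys: {sorted(keys)}")
    key = keys.pop() if keys else None
    return AlleleCount(
        hom=sum(c.hom for c in counts),
        het=sum(c.het for c in counts),
        total_alleles=sum(c.total_alleles for c in counts),
        key=key,
    )


@dataclass
class CohortGenotypes:
    """Subjects x variants minor-allele dosage matrix for one labelled cohort.

    ``genotypes[i, j]`` is the dosage of the alt allele of ``variants[j]`` in
    ``subjects[i]``; dosage is defined against the alt allele of the split
    record, never against "the minor allele at the site" (two alt alleles of
    one rsid are two columns).
    """

    label: str
    subjects: list[str]
    variants: list[VariantRecord]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} != "
                f"({len(self.subjects)}, {len(self.variants)})"
            )
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys in cohort")
        self._index = {k: j for j, k in enumerate(keys)}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def keys(self) -> list[VariantKey]:
        return [v.key for v in self.variants]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index

    def record(self, key: VariantKey) -> VariantRecord:
        return self.variants[self._index[key]]

    def column(self, key: VariantKey) -> np.ndarray:
        """Dosage column for one variant key."""
        return self.genotypes[:, self._index[key]]

    def allele_count(self, key: VariantKey) -> AlleleCount:
        return count_alleles(self.column(key), key=key)

    def with_variant(self, record: VariantRecord, column: np.ndarray) -> "CohortGenotypes":
        """Return a copy with one extra variant column appended."""
        column = np.asarray(column, dtype=np.int8).reshape(-1, 1)
        return CohortGenotypes(
            label=self.label,
            subjects=list(self.subjects),
            variants=list(self.variants) + [record],
            genotypes=np.hstack([self.genotypes, column]),
        )

    def copy(self) -> "CohortGenotypes":
        return CohortGenotypes(
            label=self.label,
            subjects=list(self.subjects),
            variants=list(self.variants),
            genotypes=self.genotypes.copy(),
        )


def column_from_counts(hom: int, het: int, n_subjects: int, n_missing: int = 0) -> np.ndarray:
    """Build a deterministic dosage column realizing (hom, het) carriers.

    Carriers occupy the lowest subject indices (homozygotes first), missing
    calls the highest; counting the column recovers (hom, het) exactly.
    """
    if hom + het + n_missing > n_subjects:
        raise ValueError("carriers plus missing exceed cohort size")
    col = np.zeros(n_subjects, dtype=np.int8)
    col[:hom] = 2
    col[hom : hom + het] = 1
    if n_missing:
        col[n_subjects - n_missing :] = MISSING
    return col


__all__ = [
    "MISSING",
    "CONSEQUENCES",
    "NONSENSE_CONSEQUENCES",
    "LOF_CONFIDENCE",
    "POPULATIONS",
    "VariantKey",
    "VariantRecord",
    "PopulationFrequencies",
    "AlleleCount",
    "CohortGenotypes",
    "count_alleles",
    "compute_maf",
    "format_maf",
    "combine_counts",
    "column_from_counts",
    "InvalidGenotypeError",
    "UndefinedFrequencyError",
    "CountMismatchError",
]
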