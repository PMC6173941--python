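"""Exact allele-count association and related statistics.

The 2x2 tables here count *alleles*, not subjects, exactly as MAC/TA tables
tabulate them: ``a`` case minor alleles out of ``a+b`` case alleles versus
``c`` control minor alleles out of ``c+d``. The non-independence of the two
alleles within a diploid subject is a documented limitation, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import AlleleCount, VariantKey


@dataclass(frozen=True)
class TwoByTwo:
    """Allele-count contingency table.

    a: case minor alleles, b: case major alleles,
    c: control minor alleles, d: control major alleles.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    variant_key: Optional[VariantKey | str]
    table: TwoByTwo
    p_one_tailed: float
    odds_ratio: float
    alpha_adjusted: float
    significant: bool


def _log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeom(N, K, n) via log-gamma accumulation."""
    def logC(m: int, r: int) -> float:
        return math.lgamma(m + 1) - math.lgamma(r + 1) - math.lgamma(m - r + 1)

    return logC(K, k) + logC(N - K, n - k) - logC(N, n)


def fisher_one_tailed(table: TwoByTwo) -> float:
    """One-tailed Fisher exact p for enrichment of minor alleles in cases.

    Computes the upper hypergeometric tail P(X >= a) with
    X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b), accumulating exact log-factorial
    terms; the alternative is over-representation in the case group.
    """
    a, N, K, n = table.a, table.n, table.a + table.c, table.a + table.b
    if N == 0:
        raise ValueError("empty table")
    k_max = min(K, n)
    if a > k_max:  # impossible observation given margins
        raise ValueError(f"a={a} exceeds max support {k_max}")
    # Sum from the extreme tail downward for stable accumulation.
    total = 0.0
    for k in range(k_max, a - 1, -1):
        if n - k > N - K:
            continue
        total += math.exp(_log_hypergeom_pmf(k, N, K, n))
    return min(total, 1.0)


def bonferroni_alpha(alpha_family: float, m: int) -> float:
    """Per-test threshold alpha_family / m."""
    if not 0.0 < alpha_family <= 1.0:
        raise ValueError(f"alpha_family {alpha_family} outside (0, 1]")
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    return alpha_family / m


def odds_ratio(table: TwoByTwo) -> float:
    """Sample odds ratio (a*d)/(b*c); infinity when b*c = 0 and a*d > 0.

    No Haldane correction is applied; a table with an empty diagonal both
    ways (a*d = 0 = b*c) reports nan.
    """
    num, den = table.a * table.d, table.b * table.c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def associate(
    variant_key: Optional[VariantKey | str],
    case_count: AlleleCount,
    control_count: AlleleCount,
    alpha_family: float = 0.05,
    m: int = 1,
) -> AssociationResult:
    """Allele-count association of one variant: cases vs controls.

    The 2x2 is (mac, total - mac) per group; significance is the nominal
    one-tailed p against the Bonferroni-adjusted threshold alpha_family/m.
    """
    if case_count.total_alleles == 0 or control_count.total_alleles == 0:
        raise ValueError("undefined test: zero total alleles in a group")
    if (case_count.key is not None and control_count.key is not None
            and case_count.key != control_count.key):
        raise ValueError(
            f"case/control counts for different variants: "
            f"{case_count.key} vs {control_count.key}"
        )
    table = TwoByTwo(
        a=case_count.mac,
        b=case_count.total_alleles - case_count.mac,
        c=control_count.mac,
        d=control_count.total_alleles - control_count.mac,
    )
    p = fisher_one_tailed(table)
    alpha = bonferroni_alpha(alpha_family, m)
    return AssociationResult(
        variant_key=variant_key,
        table=table,
        p_one_tailed=p,
        odds_ratio=odds_ratio(table),
        alpha_adjusted=alpha,
        significant=p < alpha,
    )


def burden_tally(cohort, qualifying: Sequence[VariantKey] | set) -> np.ndarray:
    """Per-subject sum of non-missing dosages over the qualifying variants."""
    keys = [k for k in qualifying if k in cohort]
    out = np.zeros(cohort.n_subjects, dtype=np.int64)
    for key in keys:
        col = cohort.column(key).astype(np.int64)
        out += np.where(col >= 0, col, 0)
    return out


def burden_permutation_test(
    case_burdens: Sequence[int],
    control_burdens: Sequence[int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided label-permutation p for higher mean burden in cases.

    p = (1 + #{permutations with mean(case) - mean(control) >= observed})
        / (n_perm + 1), seeded and reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cases = np.asarray(case_burdens, dtype=float)
    controls = np.asarray(control_burdens, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both burden sequences must be nonempty")
    observed = cases.mean() - controls.mean()
    pooled = np.concatenate([cases, controls])
    rng = np.random.default_rng(seed)
    n_case = cases.size
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[:n_case].mean() - perm[n_case:].mean()
        if stat >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def detection_power(maf: float, n_subjects: int) -> float:
    """Probability of observing >= 1 copy of an allele in a diploid sample.

    1 - (1 - maf)^(2 * n_subjects): the chance a cohort of the given size
    contains the allele at all, the relevant "power" for a discovery screen
    whose first filter is presence in cases.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf {maf} outside [0, 1]")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return 1.0 - (1.0 - maf) ** (2 * n_subjects)


__all__ = [
    "TwoByTwo",
    "AssociationResult",
    "fisher_one_tailed",
    "bonferroni_alpha",
    "odds_ratio",
    "associate",
    "burden_tally",
    "burden_permutation_test",
    "detection_power",
]
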