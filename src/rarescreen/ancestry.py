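"""Admixture-proportion estimation from ancestry-informative markers.

A two-ancestral-population model (here West African vs European): given a
panel of markers with counted-allele frequencies f1 and f2 in the two
ancestral populations, each of a subject's allele copies is an independent
draw carrying the counted allele with probability
``p(theta) = theta * f1 + (1 - theta) * f2``. The per-subject admixture
proportion theta is the maximum-likelihood value on [0, 1]. This is the
standard independent-loci admixture approximation; linkage between markers
is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import MISSING


@dataclass(frozen=True)
class AimPanel:
    """Ancestry-informative marker panel.

    ``f_pop1[j]`` / ``f_pop2[j]`` are the counted-allele frequencies of
    marker j in the two ancestral populations. A marker is informative when
    the two frequencies differ.
    """

    markers: tuple[str, ...]
    f_pop1: np.ndarray
    f_pop2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "f_pop1", np.asarray(self.f_pop1, dtype=float))
        object.__setattr__(self, "f_pop2", np.asarray(self.f_pop2, dtype=float))
        if not (len(self.markers) == self.f_pop1.size == self.f_pop2.size):
            raise ValueError("panel arrays must have equal length")
        for f in (self.f_pop1, self.f_pop2):
            if ((f < 0) | (f > 1)).any():
                raise ValueError("panel frequencies must lie in [0, 1]")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def informative(self) -> np.ndarray:
        return self.f_pop1 != self.f_pop2

    def swapped(self) -> "AimPanel":
        """Panel with the two ancestral populations exchanged."""
        return AimPanel(self.markers, self.f_pop2.copy(), self.f_pop1.copy())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AimPanel":
        return cls(
            markers=tuple(str(m) for m in df["marker"]),
            f_pop1=df["f_afr"].to_numpy(dtype=float),
            f_pop2=df["f_eur"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class AdmixtureEstimate:
    subject: str
    theta: float
    loglik: float
    n_markers_used: int
    converged: bool


@dataclass(frozen=True)
class AncestryComparison:
    """Cohort-level stratification check between two groups of estimates."""

    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    t_statistic: float
    p_value: float
    stratified: bool


def _loglik_terms(dosages: np.ndarray, f1: np.ndarray, f2: np.ndarray):
    """Return a binomial log-likelihood function of theta.

    Terms with a zero multiplier contribute nothing even when the
    corresponding log is -inf (impossible-data guard: only dosage > 0 needs
    log p, only dosage < 2 needs log(1-p)).
    """
    def loglik(theta: float) -> float:
        p = theta * f1 + (1.0 - theta) * f2
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(p)
            lq = np.log(1.0 - p)
            carried = np.where(dosages > 0, dosages * lp, 0.0)
            absent = np.where(dosages < 2, (2 - dosages) * lq, 0.0)
        return float(np.sum(carried + absent))
    return loglik


def estimate_admixture(
    genotypes: Sequence[int] | np.ndarray,
    panel: AimPanel,
    subject: str = "",
    grid_points: int = 201,
    tol: float = 1e-6,
) -> AdmixtureEstimate:
    """ML admixture proportion for one subject.

    ``genotypes`` are counted-allele dosages aligned to the panel's markers;
    missing entries (``MISSING``) are dropped, not imputed. The likelihood
    is maximized over theta in [0, 1] by a coarse grid followed by bounded
    scalar refinement to ``tol``; boundary optima return exactly 0 or 1.
    With zero informative markers the estimate is indeterminate
    (theta = nan, converged = False).
    """
    dosages = np.asarray(genotypes, dtype=float)
    if dosages.size != panel.n_markers:
        raise ValueError(
            f"got {dosages.size} genotypes for a {panel.n_markers}-marker panel"
        )
    called = dosages != MISSING
    usable = called & panel.informative
    n_used = int(usable.sum())
    if n_used == 0:
        return AdmixtureEstimate(subject, math.nan, math.nan, 0, False)
    d = dosages[usable]
    f1 = panel.f_pop1[usable]
    f2 = panel.f_pop2[usable]
    loglik = _loglik_terms(d, f1, f2)

    grid = np.linspace(0.0, 1.0, grid_points)
    values = np.array([loglik(t) for t in grid])
    best = int(np.argmax(values))
    if not np.isfinite(values[best]):
        return AdmixtureEstimate(subject, math.nan, math.nan, n_used, False)
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    if hi - lo < tol:
        theta = float(grid[best])
    else:
        res = optimize.minimize_scalar(
            lambda t: -loglik(t), bounds=(lo, hi), method="bounded",
            options={"xatol": tol},
        )
        theta = float(res.x)
        if loglik(theta) < values[best]:
            theta = float(grid[best])
    # snap to the boundary when the optimum sits against it
    if theta < tol:
        theta = 0.0
    elif theta > 1.0 - tol:
        theta = 1.0
    return AdmixtureEstimate(subject, theta, loglik(theta), n_used, True)


def estimate_cohort(
    genotypes: np.ndarray,
    panel: AimPanel,
    subjects: Optional[Sequence[str]] = None,
) -> list[AdmixtureEstimate]:
    """Per-subject estimates for a subjects x markers dosage matrix."""
    genotypes = np.asarray(genotypes)
    if subjects is None:
        subjects = [f"S{i}" for i in range(genotypes.shape[0])]
    return [
        estimate_admixture(genotypes[i], panel, subject=str(subjects[i]))
        for i in range(genotypes.shape[0])
    ]


def compare_cohort_ancestry(
    case_thetas: Sequence[float],
    control_thetas: Sequence[float],
    level: float = 0.05,
) -> AncestryComparison:
    """Welch two-sample comparison of admixture proportions between groups.

    Flags stratification when the two-sided p falls below ``level``; groups
    with fewer than two subjects have no defined SD and are an error.
    """
    cases = np.asarray(case_thetas, dtype=float)
    controls = np.asarray(control_thetas, dtype=float)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("each group needs >= 2 subjects for an SD")
    t_stat, p = stats.ttest_ind(cases, controls, equal_var=False)
    if math.isnan(p):  # zero variance in both groups with equal means
        t_stat, p = 0.0, 1.0
    return AncestryComparison(
        case_mean=float(cases.mean()),
        case_sd=float(cases.std(ddof=1)),
        control_mean=float(controls.mean()),
        control_sd=float(controls.std(ddof=1)),
        t_statistic=float(t_stat),
        p_value=float(p),
        stratified=bool(p < level),
    )


__all__ = [
    "AimPanel",
    "AdmixtureEstimate",
    "AncestryComparison",
    "estimate_admixture",
    "estimate_cohort",
    "compare_cohort_ancestry",
]
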