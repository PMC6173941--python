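# Methods

This note documents the models, defaults, numerical choices, and
limitations behind `rarescreen`. It states no empirical result the test
suite or `scripts/acceptance.py` does not itself compute.

## Allele-count model

All counting is diploid and per split record: a variant is one alternate
allele at one site, keyed by (chrom, pos, ref, alt), and dosage counts
that alt allele — never "the minor allele at the site". This matters in
practice: a single rsid can have two alternate alleles with different
consequences and different ancestries (one creating a stop codon, the
other synonymous), and they must be screened independently.

Missing genotypes are excluded from both the carrier tallies and the
total-allele denominator, so total alleles = 2 × (genotyped subjects);
only high-confidence calls should enter the matrices upstream. Counts
produced from genotype columns therefore always have an even total.
Counts transcribed from published tables are allowed an odd total (one
published term-control total, 751 alleles, cannot be expressed as full
diploid calls; the constructor accepts it verbatim rather than silently
adjusting a published number). Frequencies are carried as exact rationals
(`fractions.Fraction`); display rounding — 4 decimals below 0.05, 3 above,
matching the mixed precision of published MAC/TA tables — happens only in
report rendering.

Sex chromosomes are treated as diploid throughout: the discovery tables
this package reconstructs report chrX hom/het counts on a diploid scale
and never state hemizygote handling, so no ploidy correction is invented.

## The screen

The cascade applies, in order: damaging-nonsense filter (stop-gain /
stop-loss / start-loss **and** high-confidence LoF call), case-only filter
on the discovery panel, reference rarity, ancestry specificity, tissue
expression, manual evidence merge, in-phase recoding, replication
association. Each stage's survivors are a subset of its input (property
tested). Frameshift and splicing variants are excluded by construction —
they are disproportionately sequencing artifacts in exome data and never
enter the annotation vocabulary.

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `rarity_threshold` | 0.01 | global reference AF must be strictly below |
| `ancestry_ratio` | 5.0 | target-population AF must be ≥ ratio × every other population's AF (and > 0) |
| `target_population` | AFR | the ancestry the screen targets |
| `direction` | case_only | `control_only` screens for protective alleles by swapping group roles (the test's tail never changes) |
| `alpha_family` | 0.05 | family-wise level for replication |
| `family_m` | n carried into replication | Bonferroni family size; the reconstructed study carries 3 |

The ancestry-specificity rule is this package's quantification of a
qualitative "of population X ancestry" criterion; it is parameterized and
surfaced in reports precisely because the underlying criterion is a
judgment call. A curated ancestry label may disagree with the computed
call; the computed call wins and the disagreement is logged.

Manual criteria (Sanger validation, selective pressure, heterozygous
impact, pathophysiological plausibility) are literature/lab judgments. They
are config-supplied three-state flags (true / false / unknown); unknown is
never coerced to false and never blocks candidacy, but is reported. A
variant is a **candidate** iff no criterion fails and every computational
criterion passes; any failure rejects; otherwise the verdict is
indeterminate.

Rarity is judged twice, deliberately: against the reference database
(filter stage) and against the realized cohort frequency (reported as a
note when the cohort MAF exceeds the threshold). A variant can be
reference-rare yet common in the study population; both facts are reported
independently rather than attributing rejection to a single stage.

## In-phase recoding

When a declared modifier SNP rides the same haplotype as a nonsense
allele and converts it to a benign missense, subjects co-carrying both
minor alleles are reclassified. Per subject, the nonsense dosage is
reduced by min(target dosage, modifier dosage) — i.e. the two minor
alleles are assumed in cis whenever co-carried, which extends the
published subject-level rule to the hom+het combination it never shows —
and the moved dosage is credited to a synthetic joint-haplotype record so
total site dosage is conserved (property tested). Phase is **declared**,
not inferred; statistical phasing is out of scope.

## Association

The 2×2 table counts alleles, not subjects, exactly as MAC/TA tables are
built. The one-tailed alternative is fixed as enrichment in the carrier
group of interest. The p-value is the exact upper hypergeometric tail,
accumulated from the extreme tail downward in log-gamma space; agreement
with exhaustive rational-arithmetic enumeration is tested to 1e-12, and
with an independent library implementation to 1e-10. Known limitation,
inherited deliberately: the two alleles within a diploid subject are not
independent, and no correction is applied — the allele-level table is the
field's reporting convention for this design, and the package mirrors it
rather than "fixing" it. Odds ratios are reported without Haldane
correction (infinity when the control diagonal is empty), since zero
cells are the norm for case-only rare alleles.

The burden test is a one-sided label-permutation test on mean per-subject
qualifying-allele counts, p = (1 + #{perm ≥ observed}) / (n_perm + 1),
seeded and bit-reproducible. The permutation form is this package's
choice; the screening design only calls for "a test of genetic burden".

`detection_power(q, n) = 1 − (1 − q)^(2n)` is the probability the cohort
contains the allele at all — the binding constraint for a screen whose
first filter is presence in cases. At q = 0.005 it gives 0.533 for n = 76
and 0.778 for n = 150. A previously quoted figure of 78% at the discovery
cohort size is **not** reproduced by this closed form at n = 76 (it
matches ≈300 alleles); the power model behind that figure is unstated, so
the package exposes the closed form with an explicit n instead of
reproducing the figure.

## Admixture estimation

Two ancestral populations only (the study frames ancestry as a single
West African proportion); K > 2 is out of scope. Given panel frequencies
(f₁ⱼ, f₂ⱼ), allele copies are independent Bernoulli(θf₁ⱼ + (1−θ)f₂ⱼ)
draws — the standard admixture approximation, ignoring linkage between
markers. The likelihood is maximized on [0, 1] by a 201-point grid
followed by bounded scalar minimization to 1e-6 in the bracketing
interval; the returned optimum is checked against every grid point
(property tested), boundary optima snap to exactly 0 or 1, and a panel
with no informative markers yields an indeterminate estimate rather than
an arbitrary number. Missing marker genotypes are dropped per subject,
not imputed.

At 500 markers with ancestral frequency gaps ≥ 0.4, the per-subject
standard error is ≈ 0.033 (matching the Fisher information), so
individual estimates are typically — not uniformly — within 0.05 of
truth; cohort means are far tighter. The estimator is validated only on
synthetic data; with real AIMs, linkage and panel misspecification would
add error the tests do not capture.

The stratification check is a Welch two-sample t-test on per-subject
proportions, flagging at p < 0.05 (two-sided).

## Synthetic data

The generator defines the study conditions the tests exercise:

- cohort sizes: discovery 76 cases / 43 controls; replication 271 / 332,
  chosen so pooled totals match the combined allele-count tables
  (347 cases; 375 controls — the published term total of 751 alleles is
  odd, so 750 is the closest diploid realization);
- planted variants: Hardy–Weinberg dosages at a case AF and a control AF
  (the index-variant contrast is 0.0144 vs 0.0013); modifier SNPs ride
  each carried target allele with a co-carriage probability;
- background variants: neutral (same AF in both groups), AFs drawn from
  point masses in [1e-4, 5e-3]; each draws annotation funnel features —
  high-confidence LoF with probability 0.9, ancestry-concentrated
  reference frequencies with probability 0.6, tissue expression with
  probability 0.15 — emulating the real funnel in which a few hundred
  case-only nonsense variants reduce to a handful carried into
  replication. This keeps the replication family size realistic (~1–3);
- ancestry: per-subject proportions from Normal(0.695, 0.073) for cases
  and Normal(0.698, 0.087) for controls, truncated to [0, 1] by rejection
  sampling (exact at these parameters); AIM genotypes Binomial(2, p(θ)).
  Ancestry is independent of risk carriage by default, matching the
  no-stratification finding the conditions encode;
- everything is reproducible from one integer seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: genotyping error and platform heterogeneity
between discovery and replication waves, linkage disequilibrium beyond
the single declared in-phase pair, relatedness, batch effects, and
reference-database error in the annotation. Fixture carrier placement is
deterministic (lowest subject indices) because published tables give
counts, not carrier identities; every statistic downstream depends only
on counts.

## Problem sizes in the validation suite

The end-to-end simulation checks use 20 planted replicates and 200 null
replicates at the default cohort sizes with 50 background variants, the
Hardy–Weinberg goodness-of-fit check uses 100 seeds at n = 2000, and the
admixture checks use 500-marker panels with 76–100 subjects. These sizes
make the binomial error bounds in the assertions meaningful while keeping
the suite fast.

## Known limitations

- Diploid chrX handling (above) misstates male hemizygote counts if raw
  male X genotypes are supplied as haploid calls.
- Indels pass through unnormalized with a warning; the pipeline targets
  single-base substitutions, and left-alignment is out of scope.
- Combined cohorts pool waves genotyped on different platforms; no
  heterogeneity test is implemented because none is specified for this
  design.
- The case-only filter discards true risk alleles that by chance appear
  in a control; this is a property of the screening design itself.
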