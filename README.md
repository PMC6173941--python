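# rarescreen

Rare ancestry-specific nonsense-variant screening for case/control exome
cohorts.

## The problem

Preterm premature rupture of membranes (PPROM) — and spontaneous preterm
birth generally — shows marked disparities between ancestral populations,
yet common-variant association studies have not explained them. One
hypothesis is that risk is carried by **multiple rare, population-specific
damaging variants** in the fetal genome, each too rare for GWAS but with
moderate-to-large effect. Screening for such variants in modestly sized
whole-exome cohorts needs a disciplined funnel: most nonsense variants seen
only in cases are noise, and the few real signals must survive annotation,
biology, and independent replication.

`rarescreen` implements that funnel as a tested, reusable pipeline:

1. keep predicted damaging nonsense alleles (stop-gain / stop-loss /
   start-loss with a high-confidence loss-of-function call);
2. keep alleles present **only in cases** in the discovery panel (or only
   in controls, for protective-variant screens);
3. keep alleles rare in a reference database (global AF < 0.01);
4. keep alleles concentrated in the target ancestral population;
5. fold in manual evidence flags (Sanger validation, selective pressure,
   heterozygous impact, pathophysiological plausibility) as three-state
   config values — never computed;
6. keep alleles in genes expressed in the relevant tissue (fetal
   membranes);
7. reclassify subjects carrying an **in-phase modifier SNP** that converts
   the stop codon to a benign missense on the joint haplotype;
8. test replication by exact allele-count association in independent
   cohorts under a Bonferroni threshold.

Alongside the screen, the package provides per-subject burden tallies with
a permutation test, the rare-allele detection (presence) probability, and
per-subject admixture-proportion estimation from ancestry-informative
markers (AIMs) with a cohort stratification check — plus a seeded
synthetic-cohort simulator for validating the whole chain against planted
truth.

## The statistics

**Association.** Alleles are the sampling units, exactly as MAC/TA (minor
allele count / total alleles) tables tabulate them. For a variant with *a*
minor among *a+b* case alleles and *c* minor among *c+d* control alleles,
the one-tailed Fisher exact p-value is the upper hypergeometric tail

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ a), X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b),

computed by exact log-gamma accumulation (verified to 1e-12 against
rational-arithmetic enumeration). Significance is judged against the
Bonferroni-adjusted per-test threshold α/m, where m defaults to the number
of variants carried into replication.

**Detection probability.** The chance a diploid cohort of n subjects
contains an allele of frequency q at all: 1 − (1 − q)^(2n).

**Admixture.** A two-ancestral-population model: each allele copy at AIM j
carries the counted allele with probability θ·f₁ⱼ + (1−θ)·f₂ⱼ. The
per-subject proportion θ ∈ [0, 1] is the maximum-likelihood value (grid
plus bounded refinement); cohorts are compared with a Welch two-sample
test.

**Simulation.** Genotypes are drawn under Hardy–Weinberg sampling
(dosage ~ Binomial(2, q)); modifier SNPs ride carried target alleles with
a configurable co-carriage probability; ancestry proportions follow
truncated normal distributions and drive AIM genotypes.

## Worked example

```python
from rarescreen import associate, bonferroni_alpha
from rarescreen.fixtures import COMBINED_COUNTS_RECODED, DEFB1_KEY

case, control = COMBINED_COUNTS_RECODED[DEFB1_KEY]   # 10/694 vs 1/751
res = associate(DEFB1_KEY, case, control, alpha_family=0.05, m=3)
print(round(res.p_one_tailed, 4), res.significant)
```

prints

```
0.0039 True
```

— the stop-gain allele appears in 10 of 694 combined case alleles versus
1 of 751 control alleles; the one-tailed exact p of 0.0039 is below the
family threshold 0.05/3 ≈ 0.017, so the variant replicates. Running
`python examples/01_count_and_test.py` shows all three index variants: the
two defensin/lectin stop-gains replicate (p = 0.0039 and 0.0144) while the
recoded methyltransferase stop-gain does not (p = 0.1257), and
`examples/02_screen_fixture.py` prints the full nine-criterion verdict
matrix for the reconstructed discovery panel. The other `examples/`
scripts cover in-phase recoding, simulation-and-recovery, admixture
estimation, and burden/power, each printing a line on what its numbers
mean.

A thin CLI mirrors the library: `rarescreen screen --config run.yaml`,
`rarescreen assoc --counts counts.tsv --m 3`, `rarescreen simulate`,
`rarescreen power --maf 0.005 --n 76`, `rarescreen ancestry`.

## Layout

- `src/rarescreen/core.py` — variant records, cohort dosage matrices, the
  MAC/TA allele-count algebra
- `src/rarescreen/io.py` — VCF (GT-only), annotation TSV, gene list,
  evidence checklist, AIM panel, counts TSV
- `src/rarescreen/screening.py` — the filter cascade, in-phase recoding,
  verdicts
- `src/rarescreen/association.py` — exact test, Bonferroni, burden,
  detection probability
- `src/rarescreen/ancestry.py` — admixture ML estimation, stratification
  check
- `src/rarescreen/simulate.py` — synthetic-cohort generator
- `src/rarescreen/fixtures.py` — deterministic reconstruction of the
  published study tables
- `src/rarescreen/pipeline.py`, `cli.py` — orchestration, reports, CLI

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
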