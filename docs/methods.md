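# Methods

This note records the models behind `burdenscan`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices a maintainer would want spelled out.

## Burden counting and the outlier rule

A gene's burden in a group is the number of *distinct* variants whose
alternate allele is carried by at least one subject of that group. Missing
genotypes count as non-carriers (conservative: a variant is never credited
to a group on the strength of a no-call). A variant overlapping several
genes is counted for each; variants in no gene are excluded. Multiallelic
records are split per alternate allele, each identified by
`chrom:pos:ref:alt` — the key that also matches variants across cohorts.

Control counts are regressed on case counts by OLS **with intercept**
(a configurable through-origin mode exists). Outliers are raw residuals
outside `[Q1 − m·IQR, Q3 + m·IQR]` with `m = 6`; quartiles use linear
interpolation between order statistics (the common default; the test-suite
oracle implements the same definition independently). Residuals *below* the
lower fence are Group A: with control counts on the y-axis, a gene whose
case count is inflated sits right of the line, i.e. its observed control
count falls short of the prediction. Genes with zero variants in both
groups are dropped before fitting (uninformative, zero leverage). A zero
residual IQR makes every gene an "outlier" and is rejected as degenerate.

Two properties of this rule worth knowing:

- It is **not transpose-symmetric in pathological regimes.** Swapping the
  case/control labels swaps Groups A and B exactly when outliers are sparse
  (the regime the method targets and the tests check at 2,000 genes), but
  OLS of y-on-x is not the inverse of x-on-y, so with gross contamination
  (say 15% of a 40-gene set planted at 3×) the two fits can diverge.
- **Leverage matters.** A strong multiplicative effect on a gene in the
  extreme size tail bends the fitted line itself and manufactures spurious
  fence outliers among other large genes. This is a property of the method,
  not of the implementation.

## Replication

A discovery outlier replicates iff the independent cohort assigns it the
*same* group. No direction-agnostic mode is offered: a gene that flips from
case-enriched to control-enriched contradicts the discovery signal. The
replication rate is `100·|replicated A ∪ B| / |discovery A ∪ B|`, reported
both raw and half-up-rounded to integer percent (printed percentages in
this field use half-up: 141/746 → 19%).

## Variant spectrum

Each gene's variants split into case-only / control-only / shared by carrier
group. The compared quantity follows the gene-size-free convention: a set's
**share of the gene's total distinct variants** that belongs to a functional
class (exonic vs everything else; the controlled annotation vocabulary is
exonic, intronic, upstream, downstream, UTR3, UTR5, ncRNA, splicing,
intergenic, with only `exonic` mapping to the exonic class and unknown
labels rejected outright). Distributions over genes are compared by
Wilcoxon rank-sum; a paired signed-rank variant is available behind a flag.
Genes with an empty relevant set contribute no observation (an empty
exclusive set is "no data", not "proportion zero"); both behaviours are
configurable.

Caveat spelled out because it is easy to misread: the share-of-total
quantity folds set *size* and *composition* together. When sharing is
realistic (~60% of a gene's variants in both groups), exclusive and shared
shares differ in location even without any coding enrichment, so the null
comparison is only calibrated when the two sets are size-matched (balanced
sharing, no burden inflation) — which is how the null-uniformity test is
run. On real outlier genes the comparison answers the question actually
asked: does the exclusive set's coding share rise above what its size alone
would give?

## Homogeneity QC

Per subject, observed heterozygosity He = het calls / called sites, and the
method-of-moments inbreeding coefficient
`F = (obs hom − exp hom)/(L − exp hom)` with the expectation taken under
within-cohort allele frequencies over polymorphic sites only (monomorphic
sites carry no information and would dilute the expectation; no small-sample
correction is applied — at cohort sizes of tens of samples the n/(n−1)
factor moves F by <2% of its spread). Groups are compared by Mann–Whitney:
exact p by full enumeration when combined n ≤ 12 and tie-free (so the
worked examples are exact), otherwise the normal approximation with tie and
continuity corrections.

## Selection scan

Panel genotypes are MAF-filtered (≥0.05), centred at the mean dosage and
scaled by `sqrt(p(1−p))`. The Europe–East Asia axis is the principal
component maximizing `|mean_EUR − mean_EAS| / SD` of scores (ties break to
the lowest PC; indices are 1-based as is conventional). Each SNP is scored
`stat = n·r²` against the axis scores — χ²₁ under no differentiation —
rescaled by `λ_gc = median(stat)/0.4549`, with χ²₁ upper-tail p-values and
Benjamini–Hochberg step-up at q = 0.1. Ancestral alleles polarize
significant SNPs into per-population derived-allele frequencies; SNPs whose
recorded ancestral allele matches neither allele are skipped with a
warning. A gene is "under selection" iff ≥1 significant SNP maps into it;
its population label joins those of its SNPs ("Europe, East Asia" when
both occur).

Two deliberate design points:

- **Single-axis statistic.** Only differentiation along the chosen axis is
  tested, not the multi-PC communality of full pcadapt-style scans: the
  question is specifically about the Europe–East Asia axis.
- **Split-half testing.** At panel scale (thousands of SNPs, hundreds of
  samples) a PC of the panel overfits its own noise: testing SNPs against a
  component of the same matrix inflates every statistic by the
  top-eigenvalue excess (λ ≈ 1.4 at 5,000 SNPs × 300 samples; negligible at
  genome scale where SNPs outnumber samples 10⁴:1). `scan_selection`
  therefore assigns SNPs alternately to two folds, trains each fold's axis
  on the *other* fold, and tests every SNP against an axis it did not help
  build, restoring the exact χ²₁ null (measured λ_gc 1.01–1.07, KS < 0.015
  against uniform). Consequence: a solitary differentiated SNP cannot
  support its own axis — the scan detects differentiation shared across
  SNPs, so power simulations plant ≥10 SNPs. The lower-level
  `snp_axis_pvalues` can also subtract a supplied loading (leave-one-out
  axis) when callers test SNPs against a full-panel component.

## Prioritization

Candidates are exactly the intersection of the replicated genes and the
selection-positive genes, joined with pLI (LoF-intolerant iff pLI ≥ 0.9,
boundary included) and the trait catalog; missing table entries are
reported unknown, never an error. Allele frequencies are AC/(2N) with N
diploid subjects, half-up rounded to 4 decimals (1/156 → 0.0064). Follow-up
cohort frequencies, when supplied, are reported as given and are display
only: published follow-up tables often use per-site allele numbers that
cannot be reconstructed from the row itself.

## The synthetic-data generator

The generator's job is planted, recoverable truth for every stage; its
defaults are the study conditions everything downstream is validated under.

- **Cohorts:** 78+78 discovery and 28+28 replication subjects on one gene
  plan (shared planted genes — a real effect is present in both
  populations). Phenotypes: age uniform 51–90; PTAH uniform [40, 110] dB
  for cases, [0, 25] dB for controls (case iff PTAH ≥ 40, control iff
  ≤ 25, all > 50 years).
- **Per-gene burdens:** lognormal, `meanlog = ln 112 ≈ 4.72`,
  `sdlog = (ln 279 − ln 49)/(2·0.6745) ≈ 1.289`, fitted to the observed
  per-gene summaries (median 112, quartiles 49/279) — a heavy right tail
  consistent with a mean (~281) far above the median. Verified at 5,000
  genes: sample quartiles within 10% of targets.
- **Sharing model:** each variant is shared / case-only / control-only.
  The shared count is Binomial(N, 0.6) (~60% shared, matching the observed
  ~19% case-only in case-enriched genes); the exclusive pool is split
  between the groups **evenly with bounded jitter** (Binomial(min(E, 24), ½)
  reassignments; sd ≈ 2.4 variants, |imbalance| ≤ 25 regardless of gene
  size). An independent per-variant split would make the case−control
  discrepancy grow as √N; under the heavy-tailed burden distribution the
  6·IQR fence would then flag dozens of the largest null genes on every
  run — the detector's false positives would measure the size tail, not
  the fence rule. Bounded jitter keeps the null discrepancy homoscedastic
  so planted effects have a well-defined recovery. The trade-off is
  explicit: the generator's null is *cleaner* than real WGS data, where
  the method inherently flags the heteroscedastic tail; passing recovery
  tests here demonstrates fence correctness, not real-data false-positive
  rates.
- **Planted outliers:** chosen among genes with baseline burden in
  [50, 500] — the distribution body. Multiplicative effects on near-empty
  genes are not expressible, and planting on the extreme tail hands those
  genes enough leverage to bend the regression itself (see above); either
  way recovery would measure the size distribution rather than the
  detector. The case (or control) count is multiplied by
  `burden_inflation` (default 3) by adding exclusive variants; Group-A
  case-only variants can additionally be exonic-enriched
  (`case_only_exonic_boost` on the baseline 5% exonic fraction).
- **Genotypes:** every eligible group gets ≥1 carrier per variant
  (1 + Binomial(n−1, 0.03) carriers, 5% of carrier genotypes homozygous);
  1% of non-carrier genotypes are masked as missing (never carriers, so
  the counting truth is preserved). Subjects' He/F therefore reflect only
  these rare variants: planted burden asymmetry shifts them between
  groups, unlike real WGS where common variation dominates He — the QC
  calibration tests accordingly run on unplanted configs.
- **Reference panel:** 100 diploid samples each for AFR/EUR/EAS (scaled
  from the ~500/continent of public panels to keep simulations fast; all
  statistics are frequency-based and insensitive to this). Null SNPs share
  one derived-allele frequency (uniform 0.05–0.95) across populations plus
  Gaussian drift of sd 0.005 — deliberately *mild*, a nearly panmictic
  null, so that scan calibration (λ_gc ≈ 1, uniform p) is interpretable;
  continental-scale Fst (~0.1) would make every SNP differentiated and λ
  meaningless. Planted SNPs receive an exact EUR/EAS derived-frequency gap
  (`daf_gap`, default 0.8; AFR intermediate; which side is higher is
  random); `planted_afr_snps` instead differentiate AFR so African
  structure can dominate PC1. Ancestral allele is ref or alt with equal
  probability; genotypes are Binomial(2, alt frequency).
- **Determinism:** one `numpy` Generator seeded from `SimConfig.seed`
  drives everything in a fixed order; identical configs produce
  byte-identical files.

Not emulated (out of the generator's scope): linkage disequilibrium,
coalescent genealogies, sequencing reads and genotyping error models,
imputation artifacts, relatedness, gene-length/variant-density correlation
beyond the interval layout.

## Problem sizes used by the shipped checks

Planted-outlier recovery: 5,000 genes, 20 planted Group-A genes at 3×, 20
seeds (sensitivity ≥ 0.9, ≤ 2 false positives on average). Null regression:
5,000 genes, 20 seeds (slope ∈ [0.95, 1.05], R² > 0.98; measured ≈ 0.9999 /
0.9999). Scan calibration: one 5,000-SNP × 300-sample null panel
(λ_gc ∈ [0.8, 1.2], KS < 0.05) plus 200 panels of 2,000 SNPs × 150 samples
with 20 planted SNPs at gap 0.8 (mean false-discovery proportion within
2 SE of q = 0.1; recall ≥ 0.9). Oracle equivalence: fences, BH step-up and
exact Mann–Whitney each against independent brute-force implementations on
1,000 random instances. The full suite runs in about a minute; the
acceptance script in under half a minute.

## Known limitations

- The fence rule on raw residuals is heteroscedastic by construction on
  heavy-tailed real data; the generator sidesteps rather than models this
  (see Sharing model).
- The spectrum comparison's share-of-total convention embeds set size; see
  the caveat above.
- The scan tests one axis; selection differentiated only along other axes
  is invisible by design.
- `λ_gc` rescaling assumes a scaled-χ² null; gross model violations would
  distort tails while leaving the median calibrated.
- Exact Mann–Whitney is enumeration-based and restricted to combined
  n ≤ 12 without ties; beyond that the corrected normal approximation is
  used (agreement |Δp| < 0.02 at the crossover).
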