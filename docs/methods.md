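# Methods

## Model and procedure

### Dosage null and the imprinting test

Endosperm inherits two maternal and one paternal genome copy, so under
biallelic expression the expected maternal read fraction at any
parental-distinguishing SNP is 2/3. Reads at each SNP are split by which
parental base they carry; bases matching neither parent ("other" reads,
sequencing error) are excluded from the maternal/paternal sums. Per-SNP
counts are summed over each gene's SNPs separately for the two cross
directions, giving totals (M, P) per direction.

A gene is *allelically analyzable* when M + P ≥ 10 in **each** direction.
The threshold is read as ≥ 10 assignable reads per direction, not ≥ 10
per allele — the per-allele reading would make every near-monoallelic
(i.e. imprinted) gene non-analyzable. An optional expressed-gene filter
(e.g. FPKM ≥ 1 computed upstream) can additionally gate analyzability.

Each direction is tested with a plain Pearson χ² (no continuity
correction) against expected counts (2n/3, n/3), n = M + P, 1 df.
p-values are converted to Benjamini–Hochberg q-values; the FDR family is
the set of analyzable genes of one cross pair, adjusted per direction.
Genes with expected counts below 5 in a cell are tested but counted in
the log.

Classification per cross pair:

* **low-stringency maternal** — q < 0.05 in both directions and maternal
  fraction > 2/3 in both; mirrored for paternal (fraction < 2/3 in both).
  Genes significant with *opposite* parental directions are genotype
  effects and stay biallelic.
* **high-stringency MEG/PEG** — additionally a strict f-fold
  favourable-allele excess over dosage in both directions, with f = 5:
  maternal fraction > 2f/(2f+1) = 10/11 for MEGs, paternal fraction >
  f/(f+2) = 5/7 for PEGs. The cutoffs are derived from (f, dosage) at
  call time, so f is configurable and the published numbers are the f = 5
  special case.
* coding genes are labelled MEG/PEG (or low_MEG/low_PEG); noncoding
  transcripts meeting the low-stringency rule are MNC/PNC (no high/low
  split for noncoding).

Calls from multiple cross pairs merge as a union: a transcript imprinted
in either pair is imprinted; pairs disagreeing on the parental direction
demote the gene to biallelic.

A note on symmetry: at fixed 2:1 dosage the two parental sides are
intrinsically asymmetric (maternal fraction 0.25 is a PEG, but its mirror
0.75 is below the 10/11 MEG cutoff). The exact mirror symmetry — swapping
M↔P together with the 2:1↔1:2 dosage — holds and is property-tested.

### Clusters

Genes sorted by (chrom, start) are scanned once: imprinted transcripts
(by default the high-stringency MEG/PEG plus MNC/PNC set) chain while the
start-to-start gap between consecutive members is ≤ 1 Mb and no
allelically analyzed non-imprinted gene (biallelic or low-stringency-only)
lies between them; non-analyzed genes — typically genes without
informative SNPs — never break a chain. Chains of ≥ 2 members are
clusters; maternal/paternal mixtures are allowed. "Within 1 Mb" is
applied to consecutive gaps (chaining); a strict variant additionally
caps the whole chain span (`strict_total_span=True`). Distances are
start-to-start throughout, including the spacing statistics.

### Methylation levels, profiles, DMRs

All levels are *weighted*: Σ methylated reads / Σ total reads over
qualifying cytosines of one context (CG/CHG/CHH). Bulk levels use sites
with ≥ 5 reads; a region with no qualifying site is missing, never 0.

Metaprofiles bin each gene into a 2-kb upstream flank (fixed 100-bp
bins), 40 scaled gene-body bins and a 2-kb downstream flank, flipping
minus-strand genes so bins run 5′→3′; per-gene bin levels are averaged
across genes ignoring uncovered bins (a pooled-counts mode is available —
the choice between the two is not settled practice, so both exist and
per-gene averaging is the default).

DMRs: 200-bp windows tiled at 20-bp steps, phased from each chromosome's
first covered cytosine (the phase is configurable; it is not a published
choice). Windows need ≥ 1 covered cytosine in both tissues, otherwise
they are skipped rather than scored. Each window's pooled 2×2 table gets
a two-sided Fisher exact p; BH is applied per context over all tested
windows; significant windows need q < 0.01 AND |level difference| > 0.30
(absolute percentage points — the relative-change reading of "differed by
30%" was rejected as it would fire on tiny CHH baselines). Same-direction
significant windows merge when ≤ 200 intervening bases separate them
("within 200 bp" read inclusively); opposite directions never merge, and
the DMR direction (endosperm-hypo vs embryo-hypo) is the sign of the
pooled level difference.

At genome scale the per-window p-values come from a vectorised two-sided
Fisher computation on the hypergeometric log-pmf (sum of probabilities ≤
the observed table's, with the same tie tolerance scipy uses); it is
cross-checked in the tests against both `scipy.stats.fisher_exact` and a
pure enumeration oracle.

### Downstream syntheses

* **Imprinting–DMR association**: a gene is flagged per DMR direction if
  its body ± 2 kb (strict flank) intersects a DMR; genes whose flanked
  span touches no tested window are unassessable and excluded. The 2×2
  table imprinted/other × has/lacks endosperm-hypo DMR gets a two-sided
  Fisher exact test.
* **Conservation**: homolog tables (species, foreign gene, foreign
  MEG/PEG status, local gene) are scored as the fraction of analyzable
  local homologs whose call matches the foreign parental direction, at
  low stringency and separately at high stringency; local ids absent from
  the calls count as non-analyzable. Percentages are per row, so
  duplicated homolog rows cannot change them.
* **Tissue specificity**: a gene is endosperm-specific iff endosperm
  FPKM ≥ 1 and ≥ 4× the maximum over other tissues. This cutoff is a
  package default, not a published criterion, and both numbers are
  configurable.
* **Contamination report**: endosperm FPKM of user-supplied seed-coat
  marker genes, flagged clean below 0.5.

## Synthetic data

The generator emulates the study inputs so that every stage has planted
truth; its defaults are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| genes / cross pairs | 1,000 / 2 | two reciprocal pairs as in the study design; 1,000 genes keeps full runs in seconds |
| MEG / PEG fraction | 5% / 10% | more PEGs than MEGs, as observed |
| noncoding fraction | 2% | exercises MNC/PNC labels |
| maternal fraction | 0.95 (MEG), 0.10 (PEG), 2/3 (biallelic) | beyond the 10/11 and 1 − 5/7 cutoffs in expectation, so high-stringency recovery is well-posed |
| SNPs per gene | 1–8 | genes differ in informativeness |
| depth per SNP | NB(mean 100, dispersion 0.3) | overdispersed depth stresses low-count χ² behaviour |
| base error | 1% | feeds the "other"-read accounting |
| methylome baselines | CG 0.84, CHG 0.68, CHH 0.05 | plant-typical bulk levels |
| site levels | Beta(baseline, concentration 50), shared between tissues | unplanted regions are null by construction |
| site depth | Poisson(10) | bisulfite-typical coverage |
| planted regions | 600 bp, endosperm CG −0.5, at 5′ ends of 25% of PEGs | ≥ 2× the window size; the drop clears the 30-point filter; the linked fraction mirrors the observed PEG–DMR overlap rate |

Gene-linked hypomethylated regions anchor at the strand-aware 5′ end,
extending 200 bp into the flank. Auxiliary generators produce homolog
tables with configured concordance and an FPKM matrix with planted
endosperm-specific fractions, so the conservation and tissue-specificity
operations are testable too. All outputs are byte-identical for a given
config + seed.

What the generator does **not** model: mapping bias and multi-mapping,
maternal seed-coat contamination, biological replicates, bisulfite
conversion failure, linked SNP haplotypes, or realistic gene-length and
expression distributions. Passing recovery tests therefore demonstrates
the correctness of the statistical machinery under the stated model, not
robustness to those real-data artefacts.

## Numerical choices and degenerate inputs

* χ² requires M + P > 0 and raises otherwise; callers pre-filter via the
  analyzability rule.
* BH on an empty p-vector returns an empty vector; a single p is its own q.
* High-stringency threshold comparisons are strict (a fraction exactly
  10/11 stays low-stringency).
* A per-SNP "other"-read fraction > 20% marks the site unreliable and
  drops it from gene sums (configurable; mismapping guard).
* SNPs inside two overlapping genes count for both genes.
* All in-memory coordinates are 1-based inclusive; only BED output
  converts to 0-based half-open. Chromosome names match as exact strings.
* Fisher windows with an all-zero table cannot occur (uncovered windows
  are skipped); a zero margin inside a covered window yields p = 1.
* Cluster spans cover member gene bodies; membership and blocking are
  decided on start positions along the sorted gene order.

## Problem sizes

Default test and acceptance runs use 1,000 genes × 4 samples, ~1 M
cytosines for the gene-space methylome, a 400-kb single-chromosome
methylome with 50 planted regions for DMR recovery, 10,000 genes for null
calibration, and 200 random 50-gene genomes for the cluster-finder
equivalence check — sizes chosen so the full suite completes in well
under a minute of compute per stage while keeping Monte-Carlo error small
relative to the asserted tolerances.

## Known limitations

* No overdispersion (beta-binomial) modelling of allele counts; strong
  technical overdispersion would inflate the χ² type-I error.
* DMR calling pools reads within tissue (no replicate-aware dispersion).
* The cluster rule follows gene starts, not full-body containment, for
  blocking decisions.
* The endosperm-specificity cutoff is heuristic (see above).
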