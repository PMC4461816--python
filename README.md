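# shatterscan

Detection and characterisation of **shattered chromosomes** from short-read
sequencing of uniparental genome-elimination crosses.

When an *Arabidopsis* haploid inducer expressing a variant centromeric
histone (CENH3) is crossed to the wild type, chromosomes of the inducer
missegregate, lag in micronuclei, and are occasionally fragmented and
religated by non-homologous end joining (NHEJ) — chromothripsis — or rebuilt
through replication-fork collapse and template switching —
chromoanasynthesis.  Surviving progeny carry three kinds of altered
chromosome: **numerical** aneuploids (whole-chromosome gain/loss),
**truncated** chromosomes (one or two repaired breaks), and **shattered**
chromosomes whose copy number oscillates among states 1–4 along the
chromosome.  `shatterscan` reimplements the complete downstream analysis as
a tested pipeline, together with a synthetic-data generator that plants all
of the signal with exact truth sets, so that every stage is verifiable
without access to the original sequencing data.

## What it computes

* **Dosage profiles** — reads binned in consecutive non-overlapping windows
  (default 100,000 bp; 500 bp for breakpoint work).  The relative coverage
  of bin *i* is
  `r_i = 2 · (sample%_i / reference%_i)`, with the diploid background set
  at 2, so integer copy states read directly off the plot.  Median-smoothed
  rounding segments each chromosome into copy-state runs, and each
  chromosome is classified euploid / numerical / truncated / shattered.
* **Parental origin** — parent-diagnostic SNPs are discovered from pileups
  of a diploid hybrid (depth ≥ 25, two alleles each ≥ 40% of calls) and of
  the two parents (homozygosity ≥ 97%, depth ≥ 6 and ≥ 1); each read
  overlapping a SNP is assigned to one parent, pooled per 1 Mb bin, and
  intersected with copy-state segments.  In a shattered sample the gained
  states (3, 4) show haploid-inducer allele fractions near 2/3 and 3/4,
  and single-copy loss-of-heterozygosity regions carry the other parent.
* **Breakpoint junctions** — copy-state transitions on a 500 bp dosage
  profile seed local assembly of junction-spanning read pairs (± 2000 bp);
  each contig is split-aligned back to the reference and the anchor
  arithmetic types the join: an overlap of k ≥ 2 contig bases is a
  **microhomology** of k bp (band 2–15), abutting anchors are a **blunt
  fusion**, and unaligned middle bases are a **novel insertion**; anchors
  on opposite strands mark head-to-head / tail-to-tail **inversions**.
* **Feature enrichment at breakpoints** — occupancy of annotation tracks
  (genes, transposons, replication origins, DHS, chromatin states) inside
  1000 / 10,000 bp windows centered on breakpoints versus the remainder of
  the aneuploid chromosome; significance by shuffling breakpoint locations
  (default 1000 times) with the empirical estimator
  `p = (1 + #{shuffled ratio ≥ observed}) / (1 + n)`.
* **Cohort statistics** — ploidy/karyotype tallies across samples and
  Fisher exact tests (plus continuity-corrected chi-square) on 2×2 cross
  outcome tables, including the bundled printed counts for micronucleus
  incidence and haploid-induction frequency with NHEJ-deficient pollen.

## Worked example

Run the full simulated study — 5 chromosomes of 300 kb, a Col/Ler-like SNP
density of 10⁻³/bp, one shattered chromosome with 20 planted junctions of
mixed chemistry, and 50× error-free 2×100 bp reads — end to end:

```bash
shatterscan all --seed 1 --out-dir run1
```

which prints (abridged):

```
n_snps_planted          1459
n_snps_found            1233
karyotype_accuracy_pct  100.0
junction_n_truth        20
junction_n_detected     20
junction_recovered_pct  100.0
junction_exact_chemistry_pct  100.0
state2_pct_parent_a     50.035785288270375
micronuclei_fisher_p    5.155698314844996e-13
lig4_fisher_p           4.2575939502575745e-23
```

All 20 chromosome karyotype calls across the simulated individuals are
correct; every planted junction is reassembled with its exact type,
microhomology length or insertion sequence; 1233 of the 1459 planted SNPs
pass the depth thresholds and all of them are recovered; and copy-state-2
regions sit at 50.0% haploid-inducer alleles.  The per-state allele
fractions from the same run show the expected 2:1 and 3:1 haplotype
mixtures in duplicated and triplicated blocks:

```
state  n_a    n_b    pct_a
1      170    3924   4.2     # loss of heterozygosity: wild-type alleles
2      25168  25132  50.0    # balanced hybrid background
3      1904   947    66.8    # one extra haploid-inducer copy (2 A : 1 B)
4      1753   688    71.8    # two extra copies (3 A : 1 B)
```

A single contingency comparison from the printed cross outcomes:

```bash
$ shatterscan stats --table 89 21 0 21
2x2 table [[89, 21], [0, 21]]: Fisher p = 5.16e-13, OR = 179 (Haldane-corrected), chi2 p = 2.15e-12
```

## Command-line interface

`shatterscan simulate` writes parental FASTAs, the derived chromosome,
reads (FASTQ) and machine-readable truth files (BED blocks, junction and
SNP TSVs).  `shatterscan dosage` computes binned relative coverage from a
SAM file.  `shatterscan summarize` reports junction-type counts, the
inversion fraction and the duplicated-vs-triplicated block-size test.
`shatterscan stats` runs the exact test on a 2×2 table, and
`shatterscan all` executes the whole simulated study from one seed or a
YAML config.  The same functionality is available as a library
(`import shatterscan`); see `docs/methods.md` for the model and parameter
reference.
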