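# Methods

This note documents the models, conventions and numerical choices behind
`shatterscan`, in the order the pipeline runs them.  All internal
coordinates are 0-based half-open; 1-based coordinates appear only in
FASTA/GFF/SAM/TSV files.

## The synthetic study

The generator emulates sequencing of progeny from a genome-elimination
cross between a haploid-inducer parent (parent A, which also serves as the
mapping reference, as a Col-0-like accession does for the real organism)
and a wild-type parent (parent B).

**Parental haplotypes.** Two genomes identical except at planted SNPs:
i.i.d. uniform ACGT sequence, substitution SNPs at a per-base rate of
10⁻³ by default (one per kilobase, the density of a Col/Ler-like hybrid's
informative markers at the scale simulated).  The SNP table is exact by
construction: the test suite asserts that the set of sequence differences
between the parents equals the table.

**The shattered chromosome (replacement model).** A plan is a list of
disjoint source intervals on one chromosome, each with an intended total
copy state 1–4, expanded into an ordered list of oriented occurrences:
a state-s interval appears s−1 times in the derived chromosome.  The
derived chromosome *replaces* the parent-A homolog in the simulated
nucleus, so the total copy state of any source base is 1 (the remaining
parent-B homolog) plus its number of derived occurrences: intervals absent
from the plan or at state 1 are single-copy with loss of heterozygosity,
state 3/4 intervals carry one/two extra parent-A copies.  This reproduces
the observed signature that gained states carry haploid-inducer alleles
while single-copy regions carry only the other parent.

**Junction chemistry.** Adjacent occurrences are joined by one of three
chemistries: microhomology (2–15 bp shared by both flanks, written once),
blunt fusion, or a novel insertion (1–125 bp, uniform ACGT).  Default mix
45% / 25% / 30% — configurable; the published junction spectrum reports
the same three classes without a generative frequency, so the default is
a round mid-range choice, not a figure-derived constant.  Orientations are
drawn with probability 0.5 of inversion, so about half of the junctions
join head-to-head or tail-to-tail.

Three construction details matter for correctness:

1. *Microhomology must exist in the reference.*  A k-bp homology is only
   detectable if the reference carries the shared bases on both sides of
   the join, so planting one edits the opening k bases of the right block
   in the source genome.  The same edits are applied to both parental
   haplotypes (a shared ancestral flank), which keeps the SNP table exact;
   any planted SNP falling inside an edited base is removed.
2. *Guard bases.*  Without them, a 1-in-4 chance match of the next
   reference base beyond either anchor inflates the realized maximal
   overlap (or erodes an insertion) relative to the planted value.  One
   guard base per side is fixed so that the realized chemistry equals the
   recorded chemistry exactly; an independent checker recomputes the
   chance extensions (`f_ext`, `r_ext`) and the suite asserts they are 0.
3. *No duplicate adjacencies.*  Two junctions joining the same pair of
   oriented block ends would be indistinguishable in reference
   coordinates — detection is ill-posed for such a draw, and random
   ligation of distinct fragment ends does not produce it.  The planner
   redraws occurrence order/orientations until every adjacency is unique.
   When a flank edit would conflict with sequence another junction already
   depends on, that junction is downgraded to an insertion and flagged in
   the truth table.

**Reads.**  Uniform fragments, FR-paired mates at the fragment ends
(insert 300 ± 50 bp by default), constant Q40 qualities, optional uniform
substitution errors (0 by default; the pipeline's quality-trimming step is
then a no-op, as intended).  `coverage` is the expected total depth of the
diploid background, i.e. each haplotype copy is sequenced to coverage/2.
There is no GC bias, no indel error and no duplicate structure — so
passing tests certify the algorithms on clean signal, not robustness to
real library artifacts; real data should enter as SAM alignments.

**Annotations.**  Random interval tracks approximating the organism's
genome composition (≈50% genic, 15% transposon, 2% satellite, 3.5%
replication origins, 5% DHS, and nine chromatin states partitioning each
chromosome) with stranded genes, written as GFF3 on request.

## Mapping and pileups

The built-in mapper places a read only at a unique full-length match over
both strands, verified by Hamming distance with a configurable
`max_mismatches` (default 0).  Candidates come from non-overlapping exact
k-mer seeds (k = 20), so a read with m mismatches is guaranteed a clean
seed whenever m < ⌊L/k⌋.  The pipeline maps hybrid data with
`max_mismatches = 5`: reads of the non-reference haplotype overlap on
average 0.1 SNPs per 100 bp and must still place, while junction-spanning
reads (whose overhang mismatches the reference at ~3/4 of its bases) stay
unmapped — exactly the separation the junction stage relies on.  A
brute-force all-positions scan with the same rule is the test oracle.
Real or noisy data should be aligned externally and ingested with
`read_sam` (primary, mapped records; MAPQ floor 20, configurable).

Pileups count the observed read base per position from unique alignments
(no realignment); quality trimming uses a fixed Q20 threshold from the 3'
end with a 30 bp minimum surviving length.

## Dosage, segmentation, karyotype

Reads are assigned to the bin containing their start coordinate.  Relative
coverage is `2 · sample% / reference%` per bin against either a control
individual (default when available) or the cohort mean.  Because
percentages are normalised per sample, an aneuploid sample's extra
chromosomal material deflates every bin; the profile is therefore
re-anchored so the diploid background sits exactly at 2 ("the relative
coverage is set at 2"), using the genome-wide median of ~10 kb aggregated
chunk means — chunk means rather than raw bins because per-bin noise
biases a plain median upward when a sizeable genome fraction is elevated.
The anchor assumes the majority of the genome is euploid; for a haploid
the convention deliberately reports a flat 2 and ploidy is carried by the
parentage track, not the scale.

Segmentation: per-bin state = nearest integer of the median-filtered
profile, clamped to [0, 6]; runs shorter than `min_run` merge into the
flanking state with the closer mean.  The pipeline segments at 500 bp bins
with an 11-bin median window and `min_run` = 4: at 50× the state-4
ratio noise is σ ≈ 0.3 per 500 bp bin, and an 11-bin median suppresses
spurious state flips while preserving step edges to ±1 bin.  The planner's
minimum gap between blocks (3500 bp = 7 bins) keeps true state-1 gaps
wider than the filter's half-window so they cannot be smoothed away.

Karyotype classes per chromosome: one segment at state 2 → euploid; one
segment at another state → numerical; ≤ 2 transitions with exactly one
non-background state → truncated; ≥ `shatter_min` (default 5) transitions
or ≥ 3 distinct states → shattered.  The truncated/shattered boundary is
not published as a number — the source analysis separates "at most two
breaks" from "many oscillations" — so `shatter_min` is explicit and
configurable; chromosomes with 3–4 transitions between two states fall
through to shattered as the nearest class.

## SNP discovery and parentage

Thresholds (all configurable, defaults as published): hybrid depth ≥ 25
with exactly two alleles each ≥ 40% of allelic calls; parental
homozygosity ≥ 97%; parent-A depth ≥ 6; parent-B depth ≥ 1; parental
alleles must differ and match the hybrid's two alleles.  "Exactly two
alleles" is operationalised with a 5% noise floor (bases below it are not
alleles); with error-free input the floor is inert.  Reads are assigned
per overlapped SNP; a read supporting different parents at different SNPs
is conservatively `na` at all of them (chimera guard).  Parentage is
pooled in 1 Mb bins over assigned calls only, and the per-copy-state
summary reports allele-call fractions — in a diploid background plus
extra parent-A copies the expected fractions are 1/2, 2/3 and 3/4 at
states 2, 3 and 4, which is what the synthetic study recovers; the
state-1 fraction is near 0 (parent-B only), not exactly 0, because
segment boundaries are only bin-accurate.

## Junctions

Breakpoints are the shared edges of adjacent copy-state segments on the
500 bp profile.  For each breakpoint, the assembly input is the
junction-informative subset of pairs within ±2000 bp: pairs with one mate
unmapped (junction-spanning) and mapped pairs with a discordant insert
(same strand, or span > insert mean + 6 SD, or reversed order).  This
subset is effectively single-haplotype — concordant reference-consistent
pairs from the other haplotypes are excluded — so a greedy exact
suffix–prefix overlap assembler (min overlap 31, both orientations,
contained reads absorbed as support) suffices; contigs need ≥ 3
supporting reads and twice the read length.  Split alignment finds the
longest exact prefix and suffix placements over both strands (minimum
anchor 30 bp; among equal-length placements the one nearest the
breakpoint wins, remaining ties are flagged ambiguous and excluded from
summaries).  Classification is pure anchor arithmetic (overlap ≥ 2 →
microhomology, overlap 0–1 → blunt, gap → insertion with the middle as
the inserted sequence) and is invariant under reverse-complementing the
contig; a 1 bp overlap is called blunt because the homology band starts
at 2 by convention.  Junctions discovered from both of their flanking
breakpoints are de-duplicated on canonical anchor pairs.

Chimeric-transcript prediction: a junction is flagged when both anchors
fall inside gene bodies and some traversal of the join reads the entering
gene toward the junction and the leaving gene away from it (retained
upstream side ⇒ '+' gene enters; retained downstream ⇒ '+' gene leaves;
mirrored for '−').  This is one defensible operationalisation of
"predicted to generate chimeric gene products"; the original rule is not
published.

## Enrichment

Windows (1000 / 10,000 bp) centered on breakpoints are clipped to the
chromosome and unioned before occupancy sums, so clustered breakpoints are
not double counted; occupancy-in and occupancy-elsewhere recompose the
whole-chromosome occupancy exactly (a tested invariant).  The enrichment
ratio is occupancy-in over occupancy-elsewhere on the same aneuploid
chromosome; shuffled breakpoint sets are drawn uniformly over that
chromosome (no exclusion zones by default), and both one-sided empirical
p-values use the (r+1)/(n+1) estimator, which cannot return 0.  For
sparse features the ratio is discrete — many shuffles tie at ratio 0 — so
the null p distribution is uniform only for features dense enough that
ties are negligible; the calibration check therefore uses a ~50%-coverage
uniformly spread track.  A ratio with zero elsewhere-occupancy is
reported NaN and flagged rather than inflated.

## Cohort statistics

Proportion comparisons between crosses are computed on 2×2 count tables
with Fisher's exact test (two-sided) plus a Yates-corrected chi-square,
and an odds ratio with the Haldane +0.5 correction when a zero cell
exists.  Printed tables that report totals and percentages are
reconstructed by nearest-integer rounding (e.g. 81% of 110 embryos → 89),
with the final category absorbing the remainder; the bundled micronucleus
and haploid-induction tables both yield p < 0.001 under either statistic,
which is the reproducible claim.  Samples with euploid dosage are called
haploid rather than diploid when the genome-wide parent-A allele share is
below 10% or above 90% (dosage alone cannot distinguish them because of
the background-2 convention).

## Problem sizes and determinism

The reference study simulated by the pipeline and the acceptance script
uses 5 chromosomes of 300 kb (the package's unit-test scale; all reported
quantities are rates, fractions or p-values that are well-defined at any
scale), 20 junctions on one shattered chromosome, 50× coverage for the
aneuploid and control individuals, 30× for the extra trisomic and
truncated individuals, and 15× / 8× for the parental libraries.  Every
stage draws its randomness from a seed derived deterministically from the
single run seed; rerunning a config byte-identically reproduces all TSV
outputs, and each output directory records the config and its hash.

## Known limitations

* The built-in mapper and split aligner are exact-match tools for clean
  synthetic reads; real data must be aligned externally and will behave
  differently in repeats (the simulator's i.i.d. sequence has effectively
  no repeats, so ambiguous-placement handling is exercised only by the
  tie-break tests).
* Dosage has no GC or mappability correction, and multi-mapped reads are
  excluded from bins, which would shift pericentromeric bins on real
  genomes.
* The assembler assumes error-free reads; a single sequencing error in a
  junction-spanning read set fragments contigs (mitigated only by read
  filtering, not by consensus).
* Junction recovery presumes paired-end data with inserts long enough to
  span junctions; single-end 50 bp data supports dosage and parentage but
  not assembly.
* Enrichment p-values for very sparse features are conservative near
  ratio ties (see above); the duplicated/triplicated contrast should be
  read jointly with the occupancy percentages, not from p alone.
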