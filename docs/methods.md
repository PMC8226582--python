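# Methods

This note documents the model assumptions, parameter choices and numerical
conventions behind `sbmap`, and what the simulator does and does not emulate.

## Study designs and the quantities scanned

Two parents are involved everywhere: **A**, the mutant-background parent
(whose pre-mutagenesis sequence is taken as the reference), and **B**, the
mapping parent. A cross segregates two kinds of biallelic sites:

- *parental polymorphisms* — ordinary A-vs-B sequence differences, the
  markers of the scan (B carries the non-reference allele);
- *mutant-private mutations* — changes carried only by the mutant line,
  among them the causal one.

The **marker index** of a site in a pool is the fraction of reads carrying
A's allele. Counts arriving in reference orientation are first *oriented*:
the control pool (a resequencing pool of parent B) serves as proxy for the
parental state, and a site whose control index is ≥ 0.9 (B fixed for ALT)
has its ref/alt slots swapped so that "alt" always holds A's allele. Sites
with control index strictly inside (0.1, 0.9) cannot be assigned a parental
allele and are excluded from scans. The **Δmarker-index** is mutant-pool
index minus control-pool index.

Expected values under the two designs, with a B-parent control pool:

| site | HOM_F2 (Δ) | HET_BC after 3 backcrosses (Δ) |
|---|---|---|
| causal locus | 1.0 | 0.5 |
| unlinked marker | 0.5 | 0.0625 (= 1/16) |

which is why region thresholds must sit between the background and causal
levels: 0.6 (or 0.5) for homozygous designs, 0.45 for heterozygous ones.
These thresholds, the > 8-read support filter (applied per pool, the
stricter of the two possible readings, so both indexes are protected), the
100-kb / 20-kb sliding windows and the top-0.1 % G-value rule are the
defaults of `ScanConfig` and all CLI-exposed.

## G statistic

Each site's 2×2 allele-by-pool read-count table is scored with
G = 2 Σ nᵢ ln(nᵢ/n̂ᵢ), expectations n̂ᵢ from the independence margins. The
conventions 0·ln 0 := 0 and "degenerate margin ⇒ G = 0" guarantee finite
output on every table the sampler can produce. G is invariant under swapping
pools and swapping alleles, zero exactly when pool proportions are equal,
and — at fixed margins — non-increasing along integer steps toward the
independence expectation that do not cross it (the discrete minimum can sit
on either neighbour of the continuous one, so steps across the expectation
are not comparable; the tests check the property in exactly this form).

## Window scan

Windows are anchored at position 1 of each chromosome and advance by `step`
while their start is inside the chromosome (count = ⌊(L−1)/step⌋ + 1), so
profiles are bit-reproducible. Means are unweighted site means; windows with
fewer than 3 usable sites are masked rather than imputed, because coverage
gaps are a real feature of 20–40× pools and interpolating across them would
manufacture signal. Candidate regions are maximal runs of unmasked windows
at or above the threshold; a masked window breaks a run. Quantile selection
for G uses ⌈qN⌉ and keeps all ties at the cutoff.

A caveat the tests make explicit: phenotype selection flattens the
allele-frequency profile into a plateau around the causal locus (every
selected plant carries the causal allele, and closely linked sites recombine
rarely), so the scan localizes to *region* scale — a few cM — and the
identity of the single highest window inside the plateau is decided by read
noise. The pooled scan's job is to never lose the locus (tested: the causal
position falls inside a called region in ≥ 95 % of replicates); pinpointing
within the region is the job of the recombinant steps.

## Recombinant narrowing

All plants in a genotype matrix are selected phenotype carriers, so the
causal genotype is HOM_A (F2 design) or HET (backcross design, where the
only informative gamete is the mutant-derived one and a HOM_A call is a
scoring error, flagged and excluded). A plant is *recombinant* at a marker
when its call is inconsistent with complete linkage; in the F2 design a HET
call means one recombinant gamete and HOM_B means two.

Narrowing evaluates every gap between adjacent markers (plus the two
chromosome-end gaps) against each plant under the assumptions the classical
flanking-recombinant argument rests on:

1. a plant carries one breakpoint region — all its recombinant markers lie
   on one side of the causal locus; and
2. no double crossover occurs between the locus and any single marker, so
   moving outward from the candidate gap the per-marker recombinant-gamete
   dose can stay level or increase but never decrease (missing calls are
   skipped, never imputed).

Gaps contradicted by no plant are accepted; contiguous accepted gaps merge
into one interval bounded by the flanking markers' positions (end gaps
extend to position 1 or the chromosome length). If no gap survives, the
run aborts with the minimal-conflict gap and the conflicting plants —
the signature of genotyping error or a second causal locus. A brute-force
oracle that enumerates every per-gamete single-crossover configuration
agrees with this rule on arbitrary matrices; containment of the true
position is a logical certainty exactly when the data respect the two
assumptions, and is asserted at 100 % on matrices drawn from that model.
Real multi-generation data can violate them (a double crossover three
megabases out), which is why the error path reports conflicts instead of
guessing.

Interval sizes are reported in Mbp rounded half-up to two decimals.

## Candidate extraction

Inside the narrowed interval, candidates are sites with Δindex at or above
the design's causal level (closed interval, ≥ threshold). Ordinary parental
polymorphisms are removed by exact (chrom, pos, ref, alt) matching — allele
pair, not position, so a causal change coinciding with a polymorphic
position survives; `parental_from_control` derives the subtraction list
from the control pool itself (control fixed for the non-reference allele).
Annotation against gene models classifies each survivor as
exonic/intronic/intergenic using the reference footprint
[pos, pos + len(ref) − 1]; exonic InDels with length difference not
divisible by 3 get a frameshift flag. Full consequence prediction (codon
effects) is out of scope.

The coverage-gap scan flags mutant-private large deletions: maximal runs of
bins with mutant depth ≤ 2× while every control stays ≥ 10×, at least 5 kb
long. The thresholds suit 20–40× pools, are CLI-exposed, and deliberately
require *every* control to be well covered so that unsequenceable repeats
(where all samples drop out) are not reported.

## Simulator

`cross_sim` emulates the data-generating process end to end:

- **Parents**: `n_sites` parental polymorphisms on a 20-bp position lattice
  (spacing keeps InDel alleles from overlapping; effectively uniform at
  genomic scale), an `indel_fraction` of them InDels with 1–12 bp length
  differences so that gel-marker screening has material to find, plus
  `n_private_mutations` mutant-private sites and one designated causal
  mutation (SNP or +1 bp insertion).
- **Meiosis**: Haldane model — Poisson crossover count over the chromosome's
  map length, uniform positions, no interference — at a uniform 4 cM/Mb,
  a mid-range plant value. Multiple chromosomes are supported; unlinked
  loci are best placed on separate chromosomes.
- **Schemes**: HOM_F2 selfs the F1 and keeps plants homozygous for the
  causal allele (rejection sampling, bounded retries). HET_BC passes the
  lineage through a *single* selected heterozygous carrier per backcross
  generation, as a real breeding program does, and the final population are
  carrier siblings of the last cross; this leaves the 1/16 unlinked
  expectation intact but widens between-population variance, which the
  3-SE acceptance bands (measured across replicate populations) absorb.
- **Pools**: per-site total depth ~ Poisson(depth), ALT reads ~ Binomial
  with a symmetric per-read error rate (default 0.002). Depth tracks draw
  Poisson read starts per 500-bp bin (150-bp reads) scaled back to
  coverage, so bin noise matches what a real binned depth profile shows.
  Mean pool depths follow the worked datasets: 40× mutant, 20× control.
- **Fixtures**: `make_fixture` writes VCF, site TSV, genotype TSV (at
  gel-screenable markers), GFF3 (4-kb two-exon genes tiled every 50 kb,
  the causal site exonic by construction), reference FASTA patched to match
  REF alleles, depth TSV with an optional planted deletion, and a truth
  JSON. All randomness flows from one user seed through named sub-streams,
  so fixtures are byte-identical across reruns.

What the simulator does **not** model — and what passing tests therefore do
not show about real data: alignment and mapping bias, reference errors,
segmental duplications and repeat-mediated false variants, non-uniform
recombination (hot/cold spots, interference), genotyping error in the PCR
matrices, and polyploid genetics. Heterozygous mapping in polyploids is
documented as unsupported.

## Problem sizes in the test-suite and acceptance script

Desk-scale sizes were chosen so each statistical check has clear resolution:
simulation-backed properties use 20-Mb chromosomes with ~6 sites per 100-kb
window (about the point where window masking becomes rare), 30–136-plant
populations matching the worked datasets, 50–100 seeded replicates for
recovery rates, 1000–4000 replicate populations for the 1/16 expectation
(keeping its 3-SE band a few percent wide), and 200 replicates for the
causal-site Δindex. The exhaustive oracles (all 2×2 tables with grand total
≤ 30; all candidate gaps × per-gamete crossover configurations) are exact,
not sampled.
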