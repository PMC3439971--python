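# Methods

This note documents the models and procedures implemented in `natsirna`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions used throughout.

## Coordinates and data model

All intervals are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the I/O boundary and user-facing reports print 1-based
inclusive coordinates. One `GeneModel` represents each gene locus, built
from its longest annotated transcript — the analysis operates at the
gene-locus level and does not resolve isoforms. Introns are derived as
span minus exons. BED6 is the mapped-read interchange format
(name = read sequence, score = collapsed copy count).

## Read pre-processing and perfect-match placement

3′ adaptors are located by the first occurrence of their leading 8-nt
seed; reads with no detectable adaptor are kept untrimmed when already
inside the 17–28 nt window (a `require_adaptor` switch drops them
instead). Identical inserts are collapsed with summed copies; collapsing
conserves total copy number.

Placement is exact (no mismatches), seed-and-verify over a k-mer index
(k = 12): a read is reported at every locus where the forward genome
equals the read or its reverse complement, at full copy weight per locus.
Multi-locus counting is the most literal reading of "reads that match
perfectly"; a `unique_only` mode restricts to single-locus reads. Reads
containing N are never placed.

## Pair discovery and topology

Two genes form a cis-NAT pair when they lie on the same chromosome,
opposite strands, and their genomic spans overlap by **more than 25 nt**
(strict: a 25-nt overlap does not qualify). Overlap is computed on full
genomic spans (introns included) because pairs are defined at the locus
level; whether mature-transcript coordinates should be used instead is an
open question in annotation quality, not in this implementation.
Topology is a trichotomy: containment ⇒ *enclosed* (identical spans count
as enclosed); otherwise the left gene's strand decides — plus-left ⇒
*convergent* (both 3′ ends inside the overlap), minus-left ⇒ *divergent*.

The exclusion filter removes pairs in which either gene is annotated
rRNA, tRNA, snRNA, snoRNA, miRNA, ta-siRNA, or transposon; these loci are
degradation/small-RNA hotspots. An explicit pair-id allowlist overrides
the filter, modeling case-by-case manual retention (e.g. miRNA-target
pairs judged genuine after inspection); no phasing detector is
implemented.

## Region assignment and normalization

A read counts toward a pair when its alignment intersects either gene
span. Zone is `overlap` only under **full containment** in the overlap
interval; boundary-straddling reads fall to `non_overlap`. This keeps
zone counts disjoint and is conservative for overlap totals. Structure is
evaluated on the host gene whose strand matches the read (the gene the
read's transcript derives from), with precedence junction > intron >
exon: any alignment covering ≥ 1 nt of exon and ≥ 1 nt of intron is a
junction read.

Normalization is reads-per-million of each library's genome-mapped copy
total. The 10-rpm production filter uses the **across-library sum** of
per-library normalized overlap counts (inclusive: exactly 10 rpm passes).
Strand bias is max/min of whole-pair per-strand rpm, strict > 2; when one
strand is zero the pair is called biased only if the nonzero side reaches
5 rpm, to avoid single-read artifacts (no published rule exists for the
zero case). The "2× enriched in OR" flag compares densities (rpm/nt),
not raw counts, consistent with the density definition below.

## Density enrichment statistics

For an l-nt region producing n sRNAs, n/l is the density of sRNA loci,
where a **locus** is a distinct (sequence, start, strand) mapping event —
duplicate copies count once (a `count_copies` mode uses copy weights).
Per pair: d_o = N_o/L_o over the overlap and d_g = N_g/L_g over the
pooled non-overlap remainder of both genes. Pairs that spawn no sRNAs, or
with L_g = 0 (identical opposite-strand spans), are excluded from the
test; pairs with reads in only one region are included.

The one-tail paired two-sample t-test (alternative d_o > d_g) is applied
to the testable records; A_o and A_g are the mean densities and
**A_o/A_g is the enrichment score**. Degenerate zero-variance differences
resolve by the sign of the mean (p = 0 / 0.5 / 1). The t statistic is
delegated to `scipy.stats.ttest_rel`; the test suite checks it against an
independently coded textbook formula to 1e-10.

The resampling comparison asks whether NAT overlaps out-produce ordinary
genic regions: each of `n_perm` rounds draws, for every target region, a
window of exactly the target length uniformly placed within a random
non-NAT gene (windows may extend past genes shorter than the target),
and averages the window densities into A_u. The empirical p is the plain
frequency of A_u > A_o — it can be exactly 0; (k+1)/(n+1) is a less
biased estimator but plain frequency is the convention reproduced here.
The comparison is applied per topology (convergent overlaps vs 3′-UTR
-like windows, divergent vs 5′), because the topologies differ
systematically in overlap geometry.

## Pattern classification

Reads mapped to a pair (both strands pooled, ordered by genomic
coordinate from the pair's 5′-most position) are swept greedily: the
first unclustered read founds a cluster and reads whose 5′ positions lie
within the next 10 nt join it, so windows are pairwise disjoint. Clusters
with **more than five** reads (copies, not unique sequences — the
criterion concerns read abundance) are retained. A pair is
**site-specific** when it has no more than ten retained clusters *and*
more than 50% of all reads mapped to the whole pair fall inside them;
otherwise **distributed**. The denominator includes reads in discarded
clusters (the most literal reading of "reads mapped to the whole
cis-NAT").

## Condition fold changes and Rank Product

Per-pair overlap rpm is compared between each treatment library and its
matched control with a 1-rpm pseudocount: r = (t+1)/(c+1), reported as a
signed value (+r up, −r down, |fc| ≥ 1; swapping treatment and control
negates it). The condition with the largest |fc| is reported and |fc| > 2
(strict) flags the pair condition-regulated. The pseudocount bounds fold
changes when a control has zero reads.

Rank Product scores gene g as RP = (∏ⱼ r_gj)^(1/k) over k replicate
pairs, where r_gj is g's fold-change rank in replicate j (rank 1 =
strongest; up- and down-regulation ranked separately). Significance
follows the original permutation convention: values are permuted within
each replicate, which makes each permuted rank column an independent
uniform permutation of 1..n — so the null RP pool is drawn directly from
random rank matrices (mathematically identical, much faster). For each
gene, the expected false positives E = #(null RP ≤ observed)/n_perm and
pfp = E / (rank of the gene by RP); a per-gene p = #(null RP ≤
observed)/(n_perm·n) is also reported. The regulated-NAT caller uses the
up direction only (loss of the processing enzyme de-represses targets)
and requires fc > 1.5, p < 0.05 (permutation p or pfp, caller's choice,
flagged in output), and ≥ 1 siRNA locus antisense to the gene within its
pair.

## AGO loading

nat-siRNA sequences are matched by exact identity (not position) against
each AGO pull-down set; a sequence present in several sets counts in
each. Loading is normalized to rpm of each library's genome-mapped total
and expressed as the AGO's share of total normalized loading, so shares
sum to 100% and are invariant to rescaling all library totals. Size
classes default to 20–22 nt and 23–26 nt for AGO analysis (the long
class in profiling elsewhere is 23–28 nt); both boundaries are
configuration.

## Synthetic data: what it emulates, and what it does not

The generator plants NAT pairs of all three topologies (gene lengths
800–2,000 nt, overlaps 100–400 nt by default; the overlap minimum must
exceed 25 nt or the configuration is rejected as undiscoverable), decoy
non-NAT genes with UTRs, and optional excluded-biotype pairs, on a random
ACGT chromosome. Reads are placed with start-position density ∝ E inside
the overlap and 1 elsewhere (E = 6 by default, matching the magnitude of
enrichment the analysis is designed to detect), with a 50/50 mixture of
20–22 and 23–28 nt lengths, strand bias target 3, and per-pair hotspot
specs (k windows of width w carrying a fraction of reads) for
site-specific pairs. Decoy genes receive reads at the genomic baseline
density so resampling comparisons against non-NAT genes are meaningful.
Four libraries (mock control plus salt, cold, drought) of 50,000 reads
each are the default study conditions — a desk-scale size chosen so the
full pipeline runs in seconds; per-condition effects scale a pair's
expected read count in the treatment library. Expression matrices are
log-normal (baseline log2 ∈ [6,10], noise sd 0.25 log2 units, 5 replicate
pairs) with 50 of 1,000 genes spiked 2-fold in the mutant group.

Everything derives from one master seed through named substreams
(CRC32-hashed stream names), so any component can be regenerated
independently and byte-identically.

**Limitations.** Reads are placed fully inside their zone, so no read
straddles the overlap boundary; there are no sequencing errors, no
quality scores, no splicing-aware gaps, no codon or repeat structure, and
multi-mapping is rare because the genome is random. Passing recovery
tests therefore demonstrates that the statistics recover planted
parameters under the model's own assumptions — not robustness to
adapter chimeras, repetitive genomes, or annotation error.

## Numerical conventions

Report percentages are 100 × numerator/denominator rounded half-up to
one decimal. Ties in greedy clustering are broken by position order
(then strand, then sequence, via stable sorting). Fold-change sign at
r = 1 is +1. Strand-bias ratio with one zero side is reported as
infinity. The empirical resampling p may be exactly 0. Density records
with L_g = 0 are excluded rather than imputed.

## Problem sizes used in the test suite

Recovery properties run at desk scale on one CPU: enrichment-score
recovery uses 20 seeds × 100 pairs × 200 reads/pair per factor
E ∈ {1, 2, 6} (median score within ±20% of E); null-calibration uses 200
seeds × 30 pairs (Kolmogorov–Smirnov test of p-values against U(0,1));
pattern recovery uses 100 hotspot + 100 uniform pairs (≥ 95% correct
labels); Rank Product spike recovery uses 1,000 genes × 5 replicates ×
1,000 permutations over 10 seeds (≥ 90% recovery, ≤ 5 false calls at
pfp ≤ 0.05). These sizes were chosen as the smallest at which the
estimators' sampling noise is well inside the stated tolerances.
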