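# Methods

## Problem

Plant genomes contain gene pairs transcribed from opposite strands of the
same locus whose transcripts overlap — cis-natural antisense transcripts
(cis-NATs). The double-stranded RNA formed in the overlap can be processed
into nat-siRNAs, some of which respond to stress (heat, pathogen infection)
and silence one member of the pair. This package identifies cis-NAT pairs
from a genome annotation, quantifies candidate nat-siRNAs from small-RNA
tag libraries, tests for strand-asymmetric siRNA production and for
heat-responsive differential accumulation, and maps pair conservation
between two species via a homolog table.

## Pair detection and orientation

Two gene models form a cis-NAT pair when they lie on opposite strands of
the same chromosome and their spans overlap by more than 25 nt. The
"shorter than 2000 nt" condition is applied as a cap on the *overlap*
length (default `max_overlap = 1999`); both thresholds are parameters, so
the alternative reading — a cap on gene length — can be run by setting
`max_overlap` high and pre-filtering models. Overlap is computed on
transcript spans, not exon unions: annotations of this kind are span-level
gene models, and the UTR-extension step below already absorbs isoform
structure.

Orientation is classified from the span endpoints of the plus-strand member
`[a1, a2)` and minus-strand member `[b1, b2)`:

* **enclosed** — one span contains the other (tested first; equal
  boundaries count as containment);
* **convergent** — `a1 < b1` and `a2 < b2`: the 3' ends meet;
* **divergent** — `b1 < a1` and `b2 < a2`: the 5' ends meet.

Two symmetries pin the classifier down and are property-tested: exchanging
which member carries the plus strand (same coordinates) swaps
convergent and divergent and fixes enclosed, while a mirror reflection of
the locus (coordinates reflected, each transcript's strand flipping with
it) preserves all three classes — a mirror image does not change which
transcript ends meet.

Pairs in which either member overlaps an annotated pre-miRNA locus by at
least 1 nt (either strand) are excluded from the database, because small
RNAs there may derive from the miRNA hairpin rather than the antisense
duplex; excluded pairs are reported separately.

## UTR extension

Gene models built from coding sequence alone underestimate overlaps,
since many antisense overlaps involve UTRs. `extend_with_assembly` links
each assembled transcript to the same-strand CDS model with the largest
span overlap (ties to the lexicographically smaller gene id), then replaces
each linked model's exon structure with its longest assembly. The new span
is the hull of the CDS span and the assembly span, with terminal exons
widened to cover it — so extension can only grow a model, never shorten
it, even when the longest assembly only partially overlaps the CDS. This
hull rule is this package's design; which transcript "wins" when
assemblies partially cover a model is otherwise under-determined.

## nat-siRNA filters

Tags are unique small-RNA sequences of 17–36 nt (the parsing window) with
per-library raw counts and genomic alignments. A (pair, tag, alignment)
triple is retained as a nat-siRNA candidate iff:

1. the alignment has zero mismatches;
2. the tag is 20–28 nt;
3. the alignment lies **fully inside** the pair's overlap interval
   (containment rather than mere contact keeps only tags that are
   antisense-paired over their whole length; relaxable via
   `require_containment=False`);
4. the tag reaches ≥ 5 RP10M (reads per 10 million,
   `count × 1e7 / total_mapped_reads`) in at least one library. The
   threshold is applied to the normalized abundance, inclusively, for
   cross-library comparability.

A multi-mapping tag contributes its full count to every overlap it maps
into; fractional allocation would require an assignment model the data do
not support. Per pair and library, FR and RR are the summed raw counts of
retained tags on the genome forward and reverse strand of the overlap;
each unique tag counts once per strand even with several alignments inside
the same overlap.

## The count-contrast test

For raw counts x, y in two libraries of total sizes N1, N2, the
conditional probability

    p(y|x) = (N2/N1)^y · (x+y)! / (x! y!) · (1 + N2/N1)^−(x+y+1)

is the Audic–Claverie statistic: the distribution of y given x under a
shared Poisson rate, with a flat prior on that rate. Writing r = N2/N1,
p(y|x) is exactly the negative-binomial pmf with x+1 successes and success
probability 1/(1+r), so the tails are regularized incomplete beta
functions. The implementation evaluates the point probability in log-gamma
space and the tails through `scipy.stats.nbinom` — numerically stable for
counts far beyond anything a direct factorial evaluation could handle, and
vectorizable. Both routes are verified against exact rational
(`fractions.Fraction`) evaluation to 1e-12 relative error in the tests.

The reported significance is the two-sided tail: twice the smaller of
Σ_{k≤y} p(k|x) and Σ_{k≥y} p(k|x), capped at 1. The observed point mass
belongs to both tails, which makes the discrete test conservative — the
realized type-I error at α = 0.01 is below 0.01 (checked by Monte Carlo on
1e5 Poisson null contrasts). One-sided tails are exposed. No
multiple-testing correction is applied anywhere: the procedure this
pipeline reproduces uses raw p < 0.01 throughout, and that choice is kept
deliberately. p-values are never reported as exactly 0 for finite counts.

**Strand bias.** FR and RR come from the same library, so N1 = N2 (the
totals cancel). Because the tail construction conditions on the first
count and the strand playing that role is arbitrary, the caller conditions
on the larger of FR and RR; the call is then invariant under swapping
strands. A pair is strand-biased when FR/RR > 2 or < 0.5 (ratio
conventions: INF when RR = 0 < FR, 0 when FR = 0 < RR, undefined when
both are 0 — undefined is never biased) and the two-sided p < 0.01.

**Heat response.** Per replicate k, the ratio is RP10M-normalized
HT_k/NT_k and the p-value the two-sided test on *raw* counts with the true
library totals (the normalization the statistic itself performs through
N1, N2). A pair is called responsive only when both replicates agree:
both ratios > 2 (up) or both < 0.5 (down), and both p < 0.01.

## Conservation

A species-1 pair (g, h) is conserved when a species-2 pair (g', h')
exists with g' ∈ homologs(g) and h' ∈ homologs(h), member order
normalized. The homolog table is many-to-many and every qualifying
combination is emitted — necessary for species with whole-genome
triplication, where one pair can have two or three homologous copies.
Gene-level homology alone defines conservation; no overlap-region sequence
similarity is required. Genes absent from the table simply have no
homologs.

## Synthetic data

`simulate_annotation` lays pairs along one chromosome with 2 kb spacing:
gene lengths uniform in 800–2500 nt, overlap lengths uniform in
100–500 nt, orientation mix 6 convergent / 2 divergent / 2 enclosed by
default (roughly the ~84/7/10% split observed in real annotations), plus
10 non-overlapping singleton genes and, for the first pair, a 120-nt
pre-miRNA locus inside the plus-strand member (exercising the exclusion
rule). `simulate_srna_libraries` places 3 tag loci per strand uniformly in
each overlap, with lengths drawn 20–28 nt peaked at 21 and the first
nucleotide adenine-biased, matching the length and 5'-nucleotide biases
reported for nat-siRNAs. Counts are Poisson: the reverse strand carries a
base mean of 50 reads at 1e7 depth, the forward strand 50 × the planted
FR:RR ratio (default 8), and HT libraries multiply both by the planted
heat fold (default 4). Means scale with each library's total mapped reads
(defaults 11.25M / 14.67M / 14.61M / 12.77M for NT1/HT1/NT2/HT2), so a
fold of 1 is an honest null for the count test. Background tags (mean 2
per singleton gene, mean 20 reads) land outside all overlaps.

Counts are Poisson without overdispersion — exactly the sampling model
the test assumes — so a green recovery test establishes that the pipeline
implements its own decision rules correctly, *not* that those rules are
calibrated for biologically overdispersed libraries. One global seed
drives a named child stream per consumer (annotation, tag definitions,
each library), so outputs are byte-reproducible and adding a library does
not perturb the others.

## Numerical and formatting choices

* Internal coordinates are 0-based half-open; GFF3/GTF at the file
  boundary are 1-based inclusive. Unstranded (".") records are rejected.
* Intron ordinals for pre-miRNA placement count 1-based in transcription
  order (reverse coordinate order on the minus strand).
* Summary percentages round half-up to two decimals (`decimal`, not
  float rounding), rendered as `"N (P%)"`; ratios serialize with INF for
  division by zero.
* Pair identity strings are `"geneA|geneB"` with the lexicographically
  smaller id first.

## Limitations

Read alignment, transcript assembly and miRNA precursor placement are
upstream of this package: it consumes their outputs. Overlaps are
span-level, so an overlap falling entirely within an intron of both
members would still be counted. Tag abundance thresholds use the tag's
library count, not per-locus sums, for multi-mapping tags. trans-NATs
(overlap-free antisense pairing at different loci) are out of scope.
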