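# Methods

## Non-reference sequence model

A genome graph stores each assembly as a named path (`assembly#sequence`)
over sequence nodes. A node is *present in the reference* when any
reference path traverses it in either orientation — presence of sequence
content, not strand, is what matters for novelty. Non-reference nodes
are those traversed by no reference path; nodes containing an N
(case-insensitive) are discarded before projection, because gap-fill
characters carry no usable sequence.

Projection walks each alternate-assembly path with cumulative offsets
and emits one segment per maximal run of selected nodes, on the forward
strand of the owning sequence, in 0-based half-open coordinates. A
segment's `sources` is the union of assemblies whose paths traverse the
run's nodes, and its node tuple is kept as the canonical identity of the
run across assemblies. Segments overlapping a candidate-misassembly
region by ≥ 1 bp are removed whole, never truncated: the exclusion input
marks untrustworthy *regions*, and a partially suspect segment is not
worth rescuing.

## Merging, classification, filtering

Consecutive segments ≤ 5 bp apart on one sequence merge; bridged gap
bases count as reference bases in the merged non-reference fraction
(the alternative — counting them as novel — would inflate novelty with
reference sequence). Classification is:

| flag | rule | default |
|---|---|---|
| length class | short < 10 bp; intermediate 10–60 bp; large > 60 bp | minimum retained length 61 |
| telomeric | distance to either sequence end < 10 kb, only on sequences > 5 Mb | 10 kb / 5 Mb |
| gap flank | distance to nearest N-run < 1 kb | 1 kb |
| category | novel iff non-reference fraction ≥ 0.95, else haplotype | 0.95 |

The telomere rule carries a chromosome-scale gate because subtelomeric
assembly artefacts are a chromosome phenomenon; on short scaffolds the
flag would only delete real sequence. Tests that exercise the rule on a
1 Mb fixture lower the gate through configuration rather than changing
the rule.

Repeat enrichment uses a one-sided upper-tail test of the segment's
soft-masked base count against a binomial null with the genome-wide mean
masked fraction μ = 0.5399: z = (masked − Lμ)/√(Lμ(1−μ)), p = Φ̄(z). The
variance model behind the published z-score is not stated anywhere we
could find, so the binomial normal approximation is the package's
choice; an exact binomial tail is available (`exact=True`) and the two
agree to within half an order of magnitude at the segment lengths that
matter. The Bonferroni denominator m is the number of segments entering
the repeat test (those passing the four preceding rules); α/m with
m = 62,337 reproduces the published 8 × 10⁻⁷ per-test cutoff. A p-value
exactly equal to the cutoff is dropped (strict >).

Retention requires, in order: large, novel, non-telomeric,
non-gap-flanking, repeat p above the cutoff; a dropped segment records
its first failing rule. One published Methods passage says "more than
50% non-reference bases" for the category rule, which is inconsistent
with the novel/haplotype definition (≥ 95%) used everywhere else in the
same source; the 95% rule is implemented.

Redundancy collapse treats an alignment with identity > 0.99 whose block
spans ≥ 0.95 of the shorter contig as evidence of sameness, groups by
transitive closure (chains are not addressed by the published worked
example; closure is the only order-independent choice) and keeps the
longest contig, ties broken by lexicographic id. Byte-identical contig
sequences — the signature of an insertion shared by several assemblies —
link automatically even when no aligner output is supplied.

## Structural-variant model

Multi-allelic records split into single-allele records; symbolic alleles
keep their declared type, otherwise longer-alt = INS, shorter-alt = DEL,
equal-length non-SNP = CPX, and 1 bp substitutions leave the SV set. The
size of an SV is by convention the reference-allele length; because that
makes explicit-allele insertions 1 bp and would empty the > 500 bp class
of insertions, the pipeline-level default is `max_allele` (the longer
allele), with `reference_allele` available per call. The genomic
footprint is [pos−1, pos−1+size); under reference-allele sizing an
insertion is effectively a point, which the ± 1 kb padding of
optical-map intervals makes meaningful to intersect.

Optical-map records convert to intervals spanning their outermost
confidence bounds padded by 1 kb (the resolution of optical mapping),
clamped at zero; translocations are excluded. Per-sample interval sets
are pooled, coalesced, and restricted to the allowed (autosomal)
sequences.

Cross-sample clustering is single linkage on start positions of
same-type calls within 100 bp — on a line this is chaining of
consecutive gaps, and end positions are ignored because they differ
systematically between callers. The representative is the earliest
start (ties by sample input order); the > 500 bp size filter and the
translocation exclusion apply to representatives after clustering.
Typed intersection matches INS↔INS, DEL↔DEL, INV↔INV, DUP↔DUP; CPX
matches nothing in typed mode; an untyped any-overlap mode serves the
pooled-region comparisons. Three-way support counts each query record
once in its overlap pattern (a record overlapping several records of
another method is still one record).

## Permutation test

Each replicate re-places all query regions uniformly at random:
the placement space is the per-sequence complement of the excluded
intervals (N-gaps by default), a sequence is chosen with probability
proportional to its number of valid start positions for that region
length, and placed regions may overlap each other (the simplest reading
of placing "regions of the same size" independently). The replicate
statistic is the number of regions overlapping ≥ 1 target interval.
Reported: null mean and sd (sample convention), Z, the normal upper-tail
p, and the add-one empirical p = (r+1)/(n+1) with r the count of
replicates ≥ observed. A zero null sd flags the result degenerate
rather than fabricating a Z.

The add-one, tie-inclusive estimator is biased upward when the overlap
count takes only a few distinct values (few queries); the calibration
experiment in the acceptance suite therefore uses 100 query regions per
experiment, at which the null mean empirical p sits within 0.05 of 0.5.

## Variant summaries

Allelic balance is the alt-supporting read fraction AD_alt/(AD_ref +
AD_alt) at heterozygous genotypes (reference bias shows as AB < 0.5),
summarised per variant class and size bin. Ti/Tv counts A↔G and C↔T as
transitions; zero transversions yields an undefined flag, not a crash.
The in-frame fraction is the share of indel sizes divisible by 3.
BH q-values use the step-up rule with a fixed test count m (default
2.7 × 10⁹, the genome-size convention for peak q-scores; m equal to the
list length recovers standard BH). Peak-vs-input subtraction removes a
peak whole iff its overlap with the union of input peaks strictly
exceeds half its length. Percentages are half-up rounded.

## Breed-restricted variants

Variant identity across samples is the exact key (chrom, pos, ref, alt);
fuzzy matching belongs to the clustering stage upstream. The aggregated
record carries a genotype slot for every sample of the target group, so
a sample lacking the call fails the no-missingness rule. The depth bound
is applied per sample by default (the stricter reading of an ambiguous
phrasing); a mean-depth option exists. The allele-count bound is the
only non-strict comparison in the chain (≥ 5).

## Synthetic data

The generator emulates the study's data shapes: a reference assembly of
≥ 10 kb sequences with N-gap runs (default 100–300 bp, per-bp start rate
2 × 10⁻⁶) and 10 kb telomeric margins; alternate assemblies that are the
reference plus spiked insertions — single graph nodes flanked by shared
reference nodes, the simplest structure exercising path-membership
logic. Insertions are the only assembly-level divergence (non-reference
sequence is by definition inserted/divergent); deletions and inversions
exist only as SV-callset truth (defaults: 6 deletions, 3 inversions,
600–5,000 bp). Default spiked insertions are 200–2,000 bp with masked
fraction 0.2–0.5 (below the 0.5399 null mean — novel sequence that
should survive the repeat filter), placed away from telomere margins and
gap flanks; rule-violating spikes are engineered via explicit placement.
Callsets carry QUAL ~ N(60, 10²) and DP ~ N(50, 8²) per sample (clipped
positive), genotype-consistent allele depths, flat false-negative
dropping, and false positives at a per-true-call rate, flagged in a
truth table. Optical-map records per OM sample jitter breakpoints with
the given sd; emitted confidence bounds always span the jittered and
the true breakpoint, so zero jitter reproduces the truth exactly. All
generators are pure functions of (specs, seed); numpy's PCG64 streams
derive from the single seed, plus a CRC-based per-variant stream so the
same truth SV spells the same alleles in every sample.

What the generator does **not** model: read-level error structure,
caller-specific breakpoint wobble, repeat-mediated mis-assembly,
segmental duplication, and optical-map label-site physics. Passing
tests therefore demonstrate the correctness of the computations on
their defined inputs, not the field performance of any variant caller.

## Problem sizes

The unit and acceptance suites run on desk-scale fixtures chosen as the
smallest sizes that exercise every rule: a 1 Mb reference with four
alternates and 40 spiked insertions for end-to-end recovery; 100
randomized ≤ 100 kb fixtures for the interval-algebra oracles; 200
experiments × 1,000 replicates × 100 queries for the permutation
calibration; 300–2,000-replicate permutation runs inside pipeline tests.
The published genome-scale totals (which depend on a five-genome
whole-genome alignment) are out of reach of any desk-scale rerun and are
used only as arithmetic inputs to the report engine.

## Known limitations

- GFA support covers the S/L/P dialect with 0M overlaps; W-lines, nested
  subpaths and cyclic paths are rejected.
- The redundancy stage consumes alignments (PAF) or exact duplicates; it
  does not run an aligner.
- The breed-restriction key is exact; two callers representing one
  event with different breakpoints will not cancel across groups unless
  clustered first.
- Symbolic alleles other than INV/DUP/TRA/INS/DEL are rejected rather
  than guessed.
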