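"""Merging, classification and filtering of non-reference segments.

The raw projected segments are merged when nearly adjacent (≤5 bp apart),
classified by length (short <10 bp, intermediate 10–60 bp, large >60 bp),
position (telomeric when within 10 kb of the end of a chromosome-scale
sequence, gap-flanking when within 1 kb of an N-run), and sequence class
(novel when ≥95% of bases come from non-reference nodes, haplotype
otherwise).  Retention requires: large, novel, non-telomeric,
non-gap-flanking, and not significantly repeat-enriched relative to the
genome-wide soft-masked fraction (Bonferroni-corrected one-sided binomial
z-test).  Retained segments become contigs; near-identical contigs are
collapsed to their longest representative, and the survivors are appended
to the reference to form the expanded linear genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .graph import NonRefSegment

#: Genome-wide mean soft-masked (repetitive) fraction of the autosomes,
#: the null rate of the repeat-enrichment test.
GENOME_MEAN_MASKED = 0.5399

LENGTH_SHORT_LT = 10  # short: length < 10 bp
LENGTH_LARGE_GT = 60  # large: length > 60 bp (minimum retained length 61)
TELOMERE_MARGIN = 10_000
TELOMERE_MIN_SEQ = 5_000_000  # telomere rule applies to sequences > 5 Mb only
GAP_FLANK = 1_000
NOVEL_FRACTION = 0.95


@dataclass
class ClassifiedSegment:
    """A merged segment with its classification flags and filter decision."""

    segment: NonRefSegment
    length_class: str  # short | intermediate | large
    telomeric: bool
    gap_flank: bool
    category: str  # novel | haplotype
    masked_fraction: float
    repeat_p: float
    decision: str = "pending"  # retained | dropped:<reason> | pending

    @property
    def length(self) -> int:
        return self.segment.length


@dataclass(frozen=True)
class NovelContig:
    """A retained non-reference contig with its provenance."""

    contig_id: str
    sequence: str
    assembly: str
    seq_id: str
    start: int
    end: int
    sources: frozenset[str]

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.contig_id}: sequence length {len(self.sequence)} != span "
                f"{self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ContigStats:
    count: int
    total_bp: int
    min_bp: int
    max_bp: int
    mean_bp: float
    sd_bp: float


def merge_segments(
    segments: Sequence[NonRefSegment], max_gap: int = 5
) -> list[NonRefSegment]:
    """Merge consecutive segments ≤ ``max_gap`` bp apart on one sequence.

    Sources are unioned; the merged non-reference fraction counts bridged
    gap bases as reference bases.  Input must be sorted by (sequence,
    start) within a single assembly.
    """
    segs = list(segments)
    for prev, cur in zip(segs, segs[1:]):
        if (cur.seq_id, cur.start) < (prev.seq_id, prev.start):
            raise ValueError("segments must be sorted by (sequence, start)")
        if len({prev.assembly, cur.assembly}) > 1:
            raise ValueError("merge_segments operates within one assembly")
    out: list[NonRefSegment] = []
    for seg in segs:
        if (
            out
            and out[-1].seq_id == seg.seq_id
            and seg.start - out[-1].end <= max_gap
        ):
            prev = out[-1]
            nonref = (
                prev.nonref_fraction * prev.length
                + seg.nonref_fraction * seg.length
            )
            merged = NonRefSegment(
                assembly=prev.assembly,
                seq_id=prev.seq_id,
                start=prev.start,
                end=seg.end,
                sources=prev.sources | seg.sources,
                nonref_fraction=nonref / (seg.end - prev.start),
                nodes=prev.nodes + seg.nodes,
            )
            out[-1] = merged
        else:
            out.append(seg)
    return out


def repeat_enrichment_p(
    masked_bases: int,
    length: int,
    genome_mean: float = GENOME_MEAN_MASKED,
    exact: bool = False,
) -> float:
    """One-sided upper-tail p-value for repeat enrichment.

    Null model: each base soft-masked independently with probability
    ``genome_mean``.  Default is the z-score normal approximation
    ``z = (masked − Lμ) / sqrt(Lμ(1−μ))``; ``exact=True`` computes the
    exact binomial tail P(X ≥ masked), preferable for short segments.
    """
    if length < 1:
        raise ValueError("length must be ≥ 1")
    if not 0 <= masked_bases <= length:
        raise ValueError("masked_bases outside [0, length]")
    if exact:
        return float(sps.binom.sf(masked_bases - 1, length, genome_mean))
    mu = length * genome_mean
    sd = math.sqrt(length * genome_mean * (1.0 - genome_mean))
    z = (masked_bases - mu) / sd
    return float(sps.norm.sf(z))


def masked_fraction_of(sequence: str) -> float:
    """Fraction of soft-masked (lower-case) bases in a sequence slice."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(c.islower() for c in sequence) / len(sequence)


def classify_segment(
    segment: NonRefSegment,
    sequence_length: int,
    gap_intervals: Sequence[tuple[int, int]] = (),
    *,
    sequence: str | None = None,
    masked_bases: int | None = None,
    telomere_margin: int = TELOMERE_MARGIN,
    telomere_min_seq: int = TELOMERE_MIN_SEQ,
    gap_flank: int = GAP_FLANK,
    novel_fraction: float = NOVEL_FRACTION,
    genome_mean: float = GENOME_MEAN_MASKED,
    exact_repeat_test: bool = False,
) -> ClassifiedSegment:
    """Attach length/position/sequence-class flags and the repeat p-value.

    ``sequence`` is the owning assembly sequence (soft-masked); the
    segment's masked bases are counted from its slice unless
    ``masked_bases`` is given directly.
    """
    if not (0 <= segment.start and segment.end <= sequence_length):
        raise ValueError("segment outside owning sequence bounds")
    n = segment.length
    if n < LENGTH_SHORT_LT:
        length_class = "short"
    elif n <= LENGTH_LARGE_GT:
        length_class = "intermediate"
    else:
        length_class = "large"
    telomeric = sequence_length > telomere_min_seq and (
        segment.start < telomere_margin
        or sequence_length - segment.end < telomere_margin
    )
    near_gap = any(
        segment.start < ge + gap_flank and gs - gap_flank < segment.end
        for gs, ge in gap_intervals
    )
    category = "novel" if segment.nonref_fraction >= novel_fraction else "haplotype"
    if masked_bases is None:
        if sequence is not None:
            masked_bases = sum(
                c.islower() for c in sequence[segment.start : segment.end]
            )
        else:
            masked_bases = 0
    masked_fraction = masked_bases / n
    repeat_p = repeat_enrichment_p(
        masked_bases, n, genome_mean=genome_mean, exact=exact_repeat_test
    )
    return ClassifiedSegment(
        segment=segment,
        length_class=length_class,
        telomeric=telomeric,
        gap_flank=near_gap,
        category=category,
        masked_fraction=masked_fraction,
        repeat_p=repeat_p,
    )


def filter_segments(
    classified: Iterable[ClassifiedSegment],
    n_tests: int,
    alpha: float = 0.05,
) -> list[ClassifiedSegment]:
    """Apply the retention filter chain; return retained segments.

    Retained iff large AND novel AND not telomeric AND not gap-flanking
    AND repeat_p strictly above the Bonferroni per-test cutoff
    ``alpha / n_tests``.  Each dropped segment's ``decision`` carries its
    first failing rule, in that order.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    cutoff = alpha / n_tests
    retained = []
    for cs in classified:
        if cs.length_class != "large":
            cs.decision = "dropped:length"
        elif cs.category != "novel":
            cs.decision = "dropped:haplotype"
        elif cs.telomeric:
            cs.decision = "dropped:telomeric"
        elif cs.gap_flank:
            cs.decision = "dropped:gap_flank"
        elif not cs.repeat_p > cutoff:
            cs.decision = "dropped:repetitive"
        else:
            cs.decision = "retained"
            retained.append(cs)
    return retained


def bonferroni_cutoff(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test p-value cutoff ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    return alpha / n_tests


@dataclass(frozen=True)
class AlignmentRecord:
    """A pairwise contig alignment (PAF-derived)."""

    query: str
    target: str
    block_length: int
    identity: float  # matches / block length, in [0, 1]


def collapse_redundant(
    contigs: Sequence[NovelContig],
    alignments: Iterable[AlignmentRecord],
    min_identity: float = 0.99,
    min_short_coverage: float = 0.95,
) -> list[NovelContig]:
    """Collapse near-identical contigs, keeping the longest per group.

    Two contigs are the same sequence when an alignment links them with
    identity > ``min_identity`` and a block spanning ≥
    ``min_short_coverage`` of the shorter contig.  Groups are the
    transitive closure of qualifying links; ties on length break by
    lexicographic contig id.
    """
    by_id = {c.contig_id: c for c in contigs}
    parent = {cid: cid for cid in by_id}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for aln in alignments:
        if aln.query not in by_id or aln.target not in by_id:
            raise KeyError(f"alignment references unknown contig {aln.query!r}/{aln.target!r}")
        if aln.query == aln.target:
            continue
        shorter = min(by_id[aln.query].length, by_id[aln.target].length)
        if aln.identity > min_identity and aln.block_length >= min_short_coverage * shorter:
            ra, rb = find(aln.query), find(aln.target)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, list[NovelContig]] = {}
    for cid in by_id:
        groups.setdefault(find(cid), []).append(by_id[cid])
    kept = [
        max(members, key=lambda c: (c.length, _neg_lex(c.contig_id)))
        for members in groups.values()
    ]
    kept.sort(key=lambda c: c.contig_id)
    return kept


class _neg_lex(str):
    """Inverted lexicographic order, so max() prefers the smaller id on ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def contig_stats(contigs: Sequence[NovelContig], sample_sd: bool = True) -> ContigStats:
    """Count/total/min/max plus mean and sd rounded to 2 decimals.

    ``sample_sd`` selects the n−1 denominator (default); a single contig
    reports sd 0 under either convention.
    """
    if not contigs:
        raise ValueError("empty contig list")
    lengths = np.array([c.length for c in contigs], dtype=np.int64)
    sd = 0.0 if len(lengths) < 2 else float(np.std(lengths, ddof=1 if sample_sd else 0))
    return ContigStats(
        count=int(len(lengths)),
        total_bp=int(lengths.sum()),
        min_bp=int(lengths.min()),
        max_bp=int(lengths.max()),
        mean_bp=_round2(float(lengths.mean())),
        sd_bp=_round2(sd),
    )


def _round2(x: float) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def shared_partition(
    items: Iterable[NovelContig | NonRefSegment],
) -> dict[frozenset[str], float]:
    """Partition retained bases by their exact source-assembly combination.

    Returns kilobases per combination; every base is assigned to exactly
    one combination (its sources set), so the totals sum to the retained
    total.
    """
    out: dict[frozenset[str], float] = {}
    for item in items:
        key = frozenset(item.sources)
        out[key] = out.get(key, 0.0) + item.length / 1000.0
    return out


def build_expanded_genome(
    reference: Mapping[str, str],
    novel_contigs: Sequence[NovelContig],
) -> tuple[dict[str, str], list[dict]]:
    """Append the NOVEL contigs to the reference sequences.

    Returns (expanded sequence mapping in order, provenance table).  The
    reference sequences pass through byte-identical; each contig id must
    not collide with a reference sequence id.
    """
    expanded = dict(reference)
    provenance = []
    for contig in novel_contigs:
        if contig.contig_id in expanded:
            raise ValueError(f"contig id {contig.contig_id!r} collides with an existing sequence")
        expanded[contig.contig_id] = contig.sequence
        provenance.append(
            {
                "contig_id": contig.contig_id,
                "assembly": contig.assembly,
                "seq_id": contig.seq_id,
                "start": contig.start,
                "end": contig.end,
                "sources": ",".join(sorted(contig.sources)),
            }
        )
    return expanded, provenance


def consensus_genes(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str]
) -> set[str]:
    """Three-way intersection of gene identifiers, case-folded."""
    fold = lambda ids: {str(g).casefold() for g in ids}
    return fold(set_a) & fold(set_b) & fold(set_c)


def contigs_from_segments(
    retained: Sequence[ClassifiedSegment],
    assembly_sequences: Mapping[str, Mapping[str, str]],
    prefix: str = "contig",
) -> list[NovelContig]:
    """Materialise retained segments as contigs with provenance.

    ``assembly_sequences`` maps assembly name -> {sequence id -> sequence}.
    Ids are assigned in (assembly, sequence, start) order.
    """
    ordered = sorted(
        retained, key=lambda cs: (cs.segment.assembly, cs.segment.seq_id, cs.segment.start)
    )
    contigs = []
    for i, cs in enumerate(ordered, 1):
        seg = cs.segment
        seq = assembly_sequences[seg.assembly][seg.seq_id][seg.start : seg.end]
        contigs.append(
            NovelContig(
                contig_id=f"{prefix}_{i:06d}",
                sequence=seq,
                assembly=seg.assembly,
                seq_id=seg.seq_id,
                start=seg.start,
                end=seg.end,
                sources=seg.sources,
            )
        )
    return contigs
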