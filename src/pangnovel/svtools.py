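"""Structural-variant normalisation, typing, clustering and intersection.

Calls are first broken into single-allele records and typed: symbolic
alleles keep their declared type; otherwise an alt longer than the ref is
an insertion, shorter a deletion, equal-length non-SNP a complex variant,
and 1-bp substitutions are SNPs (excluded from SV sets).  The size of a
structural variant defaults to the size of the reference allele; since
that makes explicit-allele insertions 1 bp, a ``max_allele`` mode is also
provided and the choice is a configuration, not a constant.

Optical-map records carry breakpoint confidence intervals; they convert
to genomic intervals by taking the outermost CI bounds and padding by
1 kb to absorb the resolution limit of optical mapping.  Intersections
between callsets and optical-map intervals are type-aware (INS↔INS,
DEL↔DEL, ...); an untyped any-overlap mode serves the pooled-region
comparison used for group-restricted variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import IntervalSet

SV_TYPES = {"INS", "DEL", "INV", "DUP", "CPX", "TRA"}
_SNP_BASES = set("ACGT")


@dataclass
class SampleCall:
    """Per-sample genotype evidence."""

    gt: str  # e.g. "0/1", "1/1", "./."
    dp: int | None = None
    ad: tuple[int, int] | None = None  # (ref depth, alt depth)

    @property
    def missing(self) -> bool:
        return "." in self.gt

    @property
    def alt_count(self) -> int:
        if self.missing:
            return 0
        return sum(1 for a in self.gt.replace("|", "/").split("/") if a == "1")


@dataclass
class SVRecord:
    """A single-allele variant call (possibly a SNP before SV filtering)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    svtype: str
    qual: float | None = None
    end: int | None = None  # 1-based inclusive END for symbolic alleles
    samples: dict[str, SampleCall] = field(default_factory=dict)
    sample_order: tuple[str, ...] = ()

    @property
    def start0(self) -> int:
        """0-based start of the affected reference span."""
        return self.pos - 1

    def interval(self, size_mode: str = "reference_allele") -> tuple[int, int]:
        """0-based half-open genomic footprint [pos−1, pos−1+size)."""
        size = max(1, sv_size(self, size_mode))
        return self.start0, self.start0 + size


def _type_from_alleles(ref: str, alt: str) -> str:
    if alt.startswith("<"):
        tag = alt.strip("<>").split(":")[0].upper()
        if tag in SV_TYPES:
            return tag
        raise ValueError(f"unrecognised symbolic allele {alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        if ref.upper() in _SNP_BASES and alt.upper() in _SNP_BASES:
            return "SNP"
        raise ValueError(f"malformed alleles {ref!r}>{alt!r}")
    if len(alt) > len(ref):
        return "INS"
    if len(alt) < len(ref):
        return "DEL"
    return "CPX"


def normalize_svs(
    records: Iterable,
    keep_snps: bool = False,
) -> list[SVRecord]:
    """Break multi-allelic records into typed single-allele SVRecords.

    ``records`` may be SVRecord-like objects with an ``alts`` sequence or
    plain tuples/dicts with fields (chrom, pos, ref, alts, qual, end,
    samples).  1-bp substitutions are excluded unless ``keep_snps``.
    Per-sample fields are carried through; for multi-allelic genotypes
    the allele index is collapsed onto the emitted alt (other alt alleles
    read as reference).
    """
    out: list[SVRecord] = []
    for rec in records:
        chrom, pos, ref, alts, qual, end, samples, order = _coerce_record(rec)
        if not ref or any(not a for a in alts):
            raise ValueError(f"malformed alleles in record {chrom}:{pos}")
        for ai, alt in enumerate(alts, start=1):
            try:
                svtype = _type_from_alleles(ref, alt)
            except ValueError as exc:
                raise ValueError(f"record {chrom}:{pos}: {exc}") from exc
            if svtype == "SNP" and not keep_snps:
                continue
            new_samples = {}
            for name, call in samples.items():
                gt = call.gt.replace("|", "/")
                if "." in gt:
                    new_gt = gt
                else:
                    new_gt = "/".join(
                        "1" if a == str(ai) else "0" for a in gt.split("/")
                    )
                new_samples[name] = SampleCall(gt=new_gt, dp=call.dp, ad=call.ad)
            out.append(
                SVRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    svtype=svtype,
                    qual=qual,
                    end=end,
                    samples=new_samples,
                    sample_order=order,
                )
            )
    return out


def _coerce_record(rec):
    if isinstance(rec, SVRecord):
        return (
            rec.chrom,
            rec.pos,
            rec.ref,
            [rec.alt],
            rec.qual,
            rec.end,
            rec.samples,
            rec.sample_order,
        )
    if isinstance(rec, Mapping):
        samples = {
            k: v if isinstance(v, SampleCall) else SampleCall(**v)
            for k, v in rec.get("samples", {}).items()
        }
        return (
            str(rec["chrom"]),
            int(rec["pos"]),
            rec["ref"],
            list(rec["alts"]),
            rec.get("qual"),
            rec.get("end"),
            samples,
            tuple(rec.get("samples", {})),
        )
    chrom, pos, ref, alts = rec[:4]
    qual = rec[4] if len(rec) > 4 else None
    end = rec[5] if len(rec) > 5 else None
    samples = rec[6] if len(rec) > 6 else {}
    return str(chrom), int(pos), ref, list(alts), qual, end, dict(samples), tuple(samples)


def sv_size(record: SVRecord, mode: str = "reference_allele") -> int:
    """Size of a structural variant.

    ``reference_allele`` returns the reference-allele length (the
    convention used for the size filter here); ``max_allele`` the longer
    of the two alleles.  Symbolic records use their declared END − POS
    span in either mode.
    """
    if record.alt.startswith("<"):
        if record.end is None:
            raise ValueError(f"symbolic record {record.chrom}:{record.pos} lacks END")
        return record.end - record.pos
    if mode == "reference_allele":
        return len(record.ref)
    if mode == "max_allele":
        return max(len(record.ref), len(record.alt))
    raise ValueError(f"unknown size mode {mode!r}")


@dataclass(frozen=True)
class OMRecord:
    """One optical-map SV with breakpoint confidence intervals."""

    chrom: str
    start: int  # 0-based
    end: int
    svtype: str
    ci_start_lo: int
    ci_start_hi: int
    ci_end_lo: int
    ci_end_hi: int
    sample: str = ""


def om_to_intervals(
    records: Iterable[OMRecord], pad: int = 1000
) -> IntervalSet:
    """Convert optical-map records to padded typed genomic intervals.

    Each interval spans the outermost confidence bounds ±``pad`` bp,
    clamped at zero; translocations are excluded (no meaningful single
    interval).
    """
    if pad < 0:
        raise ValueError("pad must be ≥ 0")
    out = IntervalSet()
    for r in records:
        if r.svtype == "TRA":
            continue
        if r.end < r.start:
            raise ValueError(f"OM record on {r.chrom}: end {r.end} < start {r.start}")
        lo = max(0, min(r.start, r.ci_start_lo) - pad)
        hi = max(r.end, r.ci_end_hi) + pad
        out.add(r.chrom, lo, hi, r.svtype)
    return out


def merge_interval_sets(
    sets: Sequence[IntervalSet], keep_sequences: Iterable[str] | None = None
) -> IntervalSet:
    """Concatenate, sort, coalesce, and restrict to allowed sequences.

    Mirrors concatenating per-sample BED files, ``bedtools merge``, and
    keeping autosomal sequences only.  Merging ignores type labels (the
    pooled region set); use per-type subsets upstream for typed targets.
    """
    pooled = IntervalSet()
    for s in sets:
        for chrom, a, b, _t in s:
            pooled.add(chrom, a, b, None)
    merged = pooled.merged()
    if keep_sequences is not None:
        merged = merged.restrict(keep_sequences)
    return merged


@dataclass
class SVCluster:
    """A cluster of same-type calls with a representative record."""

    representative: SVRecord
    members: list[tuple[str, SVRecord]]  # (sample, record)

    @property
    def support(self) -> int:
        return len({s for s, _ in self.members})


def cluster_svs(
    callsets: Sequence[tuple[str, Sequence[SVRecord]]],
    max_dist: int = 100,
    min_size: int = 500,
    size_mode: str = "reference_allele",
    exclude: frozenset[str] = frozenset({"TRA"}),
) -> list[SVCluster]:
    """Cluster calls across samples by type and breakpoint proximity.

    Same-type records whose start positions lie within ``max_dist`` bp
    chain into one cluster (single linkage; on a line this is chaining of
    consecutive gaps).  Each cluster's representative is the earliest
    start, ties broken by the order samples were supplied.  The size
    (> ``min_size``) and type-exclusion filters apply to representatives
    after clustering.
    """
    tagged: list[tuple[str, int, SVRecord]] = []
    for si, (sample, records) in enumerate(callsets):
        for rec in records:
            tagged.append((sample, si, rec))
    by_key: dict[tuple[str, str], list[tuple[str, int, SVRecord]]] = {}
    for sample, si, rec in tagged:
        by_key.setdefault((rec.chrom, rec.svtype), []).append((sample, si, rec))
    clusters: list[SVCluster] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda t: (t[2].pos, t[1]))
        current: list[tuple[str, int, SVRecord]] = []
        for item in group:
            if current and item[2].pos - current[-1][2].pos > max_dist:
                clusters.append(_emit_cluster(current))
                current = []
            current.append(item)
        if current:
            clusters.append(_emit_cluster(current))
    kept = [
        c
        for c in clusters
        if c.representative.svtype not in exclude
        and sv_size(c.representative, size_mode) > min_size
    ]
    return kept


def _emit_cluster(members: list[tuple[str, int, SVRecord]]) -> SVCluster:
    rep = min(members, key=lambda t: (t[2].pos, t[1]))[2]
    return SVCluster(representative=rep, members=[(s, r) for s, _si, r in members])


def intersect_by_type(
    svs: Sequence[SVRecord],
    targets: IntervalSet,
    size_mode: str = "reference_allele",
    typed: bool = True,
) -> tuple[list[tuple[SVRecord, bool]], dict[str, int]]:
    """Flag each call supported by a ≥1 bp same-type overlap with targets.

    With ``typed=False`` any-overlap against the pooled target set
    counts.  Returns (per-record flags, summary counts).
    """
    flags = []
    supported = 0
    for rec in svs:
        s, e = rec.interval(size_mode)
        hit = targets.overlaps(rec.chrom, s, e, rec.svtype if typed else None)
        flags.append((rec, hit))
        supported += hit
    summary = {
        "total": len(flags),
        "supported": supported,
        "unsupported": len(flags) - supported,
    }
    return flags, summary


def records_to_intervalset(
    svs: Iterable[SVRecord], size_mode: str = "reference_allele", typed: bool = True
) -> IntervalSet:
    out = IntervalSet()
    for rec in svs:
        s, e = rec.interval(size_mode)
        out.add(rec.chrom, s, e, rec.svtype if typed else None)
    return out


def three_way_support(
    svs_a: Sequence[SVRecord],
    svs_b: Sequence[SVRecord],
    om: IntervalSet,
    size_mode: str = "reference_allele",
) -> dict[str, int]:
    """Per-record support pattern counts for two callsets against OM.

    Every query record is counted exactly once in its pattern category
    (a record may overlap several records of the other method; counting
    stays per query record).  Keys: ``a_only``, ``a_b``, ``a_om``,
    ``a_b_om`` and the b-side equivalents; per-method categories sum to
    that method's record count.
    """
    set_b = records_to_intervalset(svs_b, size_mode)
    set_a = records_to_intervalset(svs_a, size_mode)
    counts = {
        k: 0
        for k in ("a_only", "a_b", "a_om", "a_b_om", "b_only", "b_a", "b_om", "b_a_om")
    }
    for rec in svs_a:
        s, e = rec.interval(size_mode)
        in_b = set_b.overlaps(rec.chrom, s, e, rec.svtype)
        in_om = om.overlaps(rec.chrom, s, e, rec.svtype)
        key = "a" + ("_b" if in_b else "") + ("_om" if in_om else "")
        counts[key if key != "a" else "a_only"] += 1
    for rec in svs_b:
        s, e = rec.interval(size_mode)
        in_a = set_a.overlaps(rec.chrom, s, e, rec.svtype)
        in_om = om.overlaps(rec.chrom, s, e, rec.svtype)
        key = "b" + ("_a" if in_a else "") + ("_om" if in_om else "")
        counts[key if key != "b" else "b_only"] += 1
    return counts
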