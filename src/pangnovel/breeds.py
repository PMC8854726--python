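"""Group-restricted structural variants and the QC filter chain.

A variant is group-restricted when it is present in at least one sample
of the target group and in no sample of any other group (iterative
cross-group exclusion; identity is exact on (chrom, pos, ref, alt) —
fuzzy breakpoint matching belongs to clustering, applied upstream if
desired).  Candidates then pass a quality chain: QUAL > 30, per-sample
depth strictly inside (20, 90), no missing genotype across the group's
samples, total non-reference allele count ≥ 5, and size > 500 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .svtools import SampleCall, SVRecord, sv_size

VariantKey = tuple[str, int, str, str]


@dataclass
class GroupCallset:
    """Per-sample call lists for one group (breed)."""

    group: str
    samples: dict[str, list[SVRecord]] = field(default_factory=dict)


def _key(rec: SVRecord) -> VariantKey:
    return (rec.chrom, rec.pos, rec.ref, rec.alt)


def group_restricted(
    callsets: Sequence[GroupCallset], target_group: str
) -> list[SVRecord]:
    """Variants present only in the target group, aggregated across its samples.

    The aggregated record carries a genotype slot for *every* sample of
    the target group (missing where the sample lacks the call), so the
    downstream no-missingness rule can act on it.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two groups")
    targets = [c for c in callsets if c.group == target_group]
    if not targets:
        raise ValueError(f"target group {target_group!r} not found")
    target = targets[0]
    all_names = [n for c in callsets for n in c.samples]
    if len(all_names) != len(set(all_names)):
        raise ValueError("sample names must be unique across groups")
    other_keys: set[VariantKey] = {
        _key(rec)
        for c in callsets
        if c.group != target_group
        for recs in c.samples.values()
        for rec in recs
    }
    by_key: dict[VariantKey, dict[str, SVRecord]] = {}
    for sample, recs in target.samples.items():
        for rec in recs:
            if _key(rec) in other_keys:
                continue
            by_key.setdefault(_key(rec), {})[sample] = rec
    out: list[SVRecord] = []
    sample_order = tuple(target.samples)
    for key in sorted(by_key, key=lambda k: (k[0], k[1], k[2], k[3])):
        carriers = by_key[key]
        chrom, pos, ref, alt = key
        any_rec = next(iter(carriers.values()))
        samples: dict[str, SampleCall] = {}
        for name in sample_order:
            if name in carriers:
                rec = carriers[name]
                samples[name] = rec.samples.get(name, SampleCall(gt="./."))
            else:
                samples[name] = SampleCall(gt="./.")
        out.append(
            SVRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                svtype=any_rec.svtype,
                qual=max(
                    (r.qual for r in carriers.values() if r.qual is not None),
                    default=None,
                ),
                end=any_rec.end,
                samples=samples,
                sample_order=sample_order,
            )
        )
    return out


def allele_count(record: SVRecord) -> int:
    """Total non-reference allele count across the record's samples."""
    return sum(call.alt_count for call in record.samples.values())


def qc_filter(
    record: SVRecord,
    qual_min: float = 30,
    dp_lo: int = 20,
    dp_hi: int = 90,
    min_ac: int = 5,
    min_size: int = 500,
    size_mode: str = "reference_allele",
    dp_per_sample: bool = True,
) -> tuple[bool, str]:
    """Apply the high-quality chain; returns (pass, reason).

    All bounds are strict except the allele-count ≥.  ``dp_per_sample``
    requires every sample's DP inside the bounds (the stricter reading);
    with False, the mean DP across samples is tested instead.
    """
    if record.qual is None or not record.qual > qual_min:
        return False, "qual"
    dps = [c.dp for c in record.samples.values()]
    if any(d is None for d in dps):
        return False, "dp_missing"
    if dp_per_sample:
        if not all(dp_lo < d < dp_hi for d in dps):
            return False, "dp"
    else:
        mean_dp = sum(dps) / len(dps)
        if not dp_lo < mean_dp < dp_hi:
            return False, "dp"
    if any(c.missing for c in record.samples.values()):
        return False, "missing_genotype"
    if allele_count(record) < min_ac:
        return False, "allele_count"
    if not sv_size(record, size_mode) > min_size:
        return False, "size"
    return True, "pass"


def restricted_high_quality(
    callsets: Sequence[GroupCallset],
    target_group: str,
    **qc_kwargs,
) -> list[SVRecord]:
    """group_restricted followed by the QC chain."""
    return [
        rec
        for rec in group_restricted(callsets, target_group)
        if qc_filter(rec, **qc_kwargs)[0]
    ]
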