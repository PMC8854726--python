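"""Permutation overlap testing and variant-quality summaries.

The permutation test asks whether the observed number of query regions
overlapping a target interval set (e.g. SV calls vs optical-map regions)
exceeds what random placement would produce: each replicate re-places all
query regions uniformly at random across the allowed placement space
(autosomes minus N-gaps by default, sequences chosen proportional to the
number of placeable start positions) and counts how many land on a
target.  The null mean/sd give a Z-score; an add-one empirical p-value
``(r+1)/(n+1)`` avoids zeroes.

Also here: allelic-balance summaries (alt-supporting read fraction at
heterozygous sites; 0.5 is the unbiased expectation, reference bias pulls
it below), Ti/Tv, the in-frame indel fraction, Benjamini–Hochberg
q-values with an overridable number of tests (the genome-size convention,
m = 2.7e9, for peak q-scores), and the input-peak subtraction rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .intervals import IntervalSet, merge_intervals, overlap_length, subtract_intervals


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    n_reps: int
    null_mean: float
    null_sd: float
    z: float  # nan when degenerate
    p_normal: float
    p_empirical: float
    seed: int | None
    degenerate: bool = False


class PlacementSpace:
    """Allowed placement intervals per sequence (lengths minus exclusions)."""

    def __init__(
        self,
        sequence_lengths: Mapping[str, int],
        excluded: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    ):
        self.allowed: dict[str, list[tuple[int, int]]] = {}
        excluded = excluded or {}
        for chrom, length in sequence_lengths.items():
            self.allowed[chrom] = subtract_intervals(
                [(0, int(length))], excluded.get(chrom, [])
            )

    def slots(self, length: int) -> tuple[list[tuple[str, int]], np.ndarray]:
        """(chrom, interval start) slots and valid-start counts for a region length."""
        keys: list[tuple[str, int]] = []
        counts: list[int] = []
        for chrom in sorted(self.allowed):
            for a, b in self.allowed[chrom]:
                c = (b - a) - length + 1
                if c > 0:
                    keys.append((chrom, a))
                    counts.append(c)
        return keys, np.array(counts, dtype=np.int64)


def place_regions(
    lengths: Sequence[int],
    space: PlacementSpace,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Place regions of the given lengths uniformly at random.

    Each region is placed independently (overlaps between placed regions
    allowed); the sequence is chosen proportional to its number of
    placeable start positions for that region length.
    """
    out = []
    for ln in lengths:
        keys, counts = space.slots(int(ln))
        total = int(counts.sum())
        if total <= 0:
            raise ValueError(f"no placement possible for a region of {ln} bp")
        u = int(rng.integers(total))
        idx = int(np.searchsorted(np.cumsum(counts), u, side="right"))
        offset = u - (int(np.cumsum(counts)[idx - 1]) if idx > 0 else 0)
        chrom, a = keys[idx]
        out.append((chrom, a + offset, a + offset + int(ln)))
    return out


def permutation_overlap(
    queries: Sequence[tuple[str, int, int]],
    space: PlacementSpace,
    targets: IntervalSet,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test of query-region overlap with a target interval set.

    ``queries`` are the observed regions (chrom, start, end).  Each
    replicate re-places regions of the same sizes at random and counts
    how many overlap ≥1 target interval (any type).  Returns the observed
    count, null moments, Z-score and both p-values; a zero null sd flags
    the result degenerate with an undefined z.
    """
    if not queries:
        raise ValueError("no query regions")
    rng = np.random.default_rng(seed)
    merged = targets.untyped().merged()
    observed = sum(
        merged.overlaps(chrom, s, e) for chrom, s, e in queries
    )
    lengths = [e - s for _, s, e in queries]
    # Precompute per-length slot tables and target arrays per chrom.
    slot_cache: dict[int, tuple[list[tuple[str, int]], np.ndarray, np.ndarray]] = {}
    for ln in set(lengths):
        keys, counts = space.slots(ln)
        if counts.sum() <= 0:
            raise ValueError(f"no placement possible for a region of {ln} bp")
        slot_cache[ln] = (keys, counts, np.cumsum(counts))
    counts_per_rep = np.zeros(n_reps, dtype=np.int64)
    for ln in lengths:
        keys, counts, cum = slot_cache[ln]
        total = int(cum[-1])
        u = rng.integers(total, size=n_reps)
        idx = np.searchsorted(cum, u, side="right")
        offsets = u - np.where(idx > 0, cum[idx - 1], 0)
        # group draws by slot's chromosome for vectorised overlap checks
        chrom_of = np.array([k[0] for k in keys])
        base_of = np.array([k[1] for k in keys], dtype=np.int64)
        starts = base_of[idx] + offsets
        ends = starts + ln
        for chrom in np.unique(chrom_of[idx]):
            sel = chrom_of[idx] == chrom
            hits = merged.overlaps_many(str(chrom), starts[sel], ends[sel])
            counts_per_rep[np.flatnonzero(sel)[hits]] += 1
    null_mean = float(counts_per_rep.mean())
    null_sd = float(counts_per_rep.std(ddof=1)) if n_reps > 1 else 0.0
    degenerate = null_sd == 0.0
    z = float("nan") if degenerate else (observed - null_mean) / null_sd
    p_normal = float("nan") if degenerate else float(sps.norm.sf(z))
    r = int((counts_per_rep >= observed).sum())
    p_empirical = (r + 1) / (n_reps + 1)
    return PermutationResult(
        observed=int(observed),
        n_reps=int(n_reps),
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_normal=p_normal,
        p_empirical=p_empirical,
        seed=seed,
        degenerate=degenerate,
    )


def zscore(observed: float, mean: float, sd: float) -> float:
    """(observed − mean) / sd; sd must be positive."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return (observed - mean) / sd


def allelic_balance(
    records: Iterable,
    bin_edges: Sequence[int] = (1, 15, 50),
    het_only: bool = True,
) -> dict:
    """Summarise allelic balance per variant class and size bin.

    AB = alt depth / (ref depth + alt depth) from the AD field, computed
    at heterozygous genotypes by default.  Records lacking AD are skipped
    and counted.  Returns ``{"bins": {(class, bin): {n, mean_ab,
    mean_abs_dev}}, "skipped": int}``; classes are SNP/INS/DEL (others
    under their own type), size bins are defined by ``bin_edges``
    (strictly increasing): ≤e1, (e1, e2], ..., >ek.
    """
    edges = list(bin_edges)
    if edges != sorted(set(edges)):
        raise ValueError("bin edges must be strictly increasing")
    acc: dict[tuple[str, str], list[float]] = {}
    skipped = 0
    for rec in records:
        if rec.svtype == "SNP":
            size = 1
        else:
            # indel size: bases gained or lost relative to the reference
            size = max(len(rec.ref), len(rec.alt)) - 1
        label = _bin_label(size, edges)
        for call in rec.samples.values():
            if call.ad is None:
                skipped += 1
                continue
            if het_only and call.alt_count != 1:
                continue
            ref_d, alt_d = call.ad
            if ref_d + alt_d == 0:
                skipped += 1
                continue
            ab = alt_d / (ref_d + alt_d)
            acc.setdefault((rec.svtype, label), []).append(ab)
    bins = {
        key: {
            "n": len(vals),
            "mean_ab": float(np.mean(vals)),
            "mean_abs_dev": float(np.mean(np.abs(np.array(vals) - 0.5))),
        }
        for key, vals in acc.items()
    }
    return {"bins": bins, "skipped": skipped}


def _bin_label(size: int, edges: Sequence[int]) -> str:
    prev = None
    for e in edges:
        if size <= e:
            return f"<={e}" if prev is None else f"({prev},{e}]"
        prev = e
    return f">{edges[-1]}"


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def titv(records: Iterable) -> tuple[float | None, bool]:
    """Transition/transversion ratio over SNP records.

    Accepts records with ``ref``/``alt`` attributes or (ref, alt) pairs;
    indels are ignored.  Returns (ratio, defined); zero transversions
    yield (None, False).
    """
    ti = tv = 0
    for rec in records:
        ref, alt = (
            (rec.ref, rec.alt) if hasattr(rec, "ref") else (rec[0], rec[1])
        )
        if len(ref) != 1 or len(alt) != 1:
            continue
        pair = (ref.upper(), alt.upper())
        if pair[0] == pair[1] or not set(pair) <= set("ACGT"):
            continue
        if pair in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None, False
    return ti / tv, True


def inframe_fraction(indel_sizes: Sequence[int]) -> float:
    """Fraction of indel sizes that are multiples of 3 (in-frame)."""
    sizes = list(indel_sizes)
    if not sizes:
        raise ValueError("empty size list")
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    return sum(1 for s in sizes if s % 3 == 0) / len(sizes)


def bh_qvalues(p_list: Sequence[float], m_override: int = 2_700_000_000) -> list[float]:
    """Benjamini–Hochberg step-up q-values with a fixed number of tests.

    ``q_(i) = min_{j ≥ rank(i)} (m · p_(j) / j)`` capped at 1, input
    order preserved.  ``m_override`` defaults to the theoretical genome
    size convention (2.7 Gb) used for peak q-scores; with
    ``m_override=len(p_list)`` this is standard BH.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m_override < p.size:
        raise ValueError("m_override must be ≥ the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_override / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q.tolist()


def subtract_input_peaks(
    peaks: Sequence[tuple],
    input_peaks: Sequence[tuple],
    min_frac: float = 0.5,
) -> list[tuple]:
    """Drop peaks mostly shared with the input (control) sample.

    A peak (chrom, start, end, *extra) is removed whole iff its total
    overlap with the union of input peaks on that chromosome is strictly
    greater than ``min_frac`` of its own length; all others pass through
    unchanged (the behaviour of ``bedtools subtract -A -f``).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in input_peaks:
        by_chrom.setdefault(str(iv[0]), []).append((int(iv[1]), int(iv[2])))
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    out = []
    for peak in peaks:
        chrom, s, e = str(peak[0]), int(peak[1]), int(peak[2])
        cov = overlap_length((s, e), merged.get(chrom, []))
        if not cov > min_frac * (e - s):
            out.append(peak)
    return out


def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100·n/d, half-up rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
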