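"""Synthetic assemblies, graphs, SV callsets and optical-map intervals.

The generator emulates the shape of a multi-assembly pan-genome study:
one reference assembly, several alternates carrying spiked insertions of
controlled length, sharing pattern and soft-masked (repeat-like)
fraction, with N-gaps and telomeric margins; per-sample SV callsets with
flat false-positive/negative rates and QUAL/DP/genotype fields; and
optical-map intervals with confidence-interval noise.  Every generated
feature is recorded in a :class:`TruthManifest` so downstream stages can
be scored against known ground truth.

Insertions are the only spiked divergence in the assemblies themselves
(non-reference sequence is by definition inserted/divergent sequence);
deletions and inversions exist only as SV-callset truth.  All generators
are pure functions of (specs, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import GenomeGraph
from .svtools import OMRecord, SampleCall, SVRecord

_BASES = np.array(list("ACGT"))

DEFAULT_GAP_LENGTH_RANGE = (100, 300)
DEFAULT_TELOMERE_MARGIN = 10_000
#: minimum reference distance between spiked insertions, so that distinct
#: spikes never fall within the 5 bp merge distance of one another
MIN_SPIKE_SEPARATION = 100


@dataclass(frozen=True)
class SpikeRecord:
    """One spiked insertion as it appears in one carrying assembly."""

    assembly: str
    seq_id: str
    start: int  # 0-based, in the carrying assembly's coordinates
    end: int
    sequence: str
    sharing: frozenset[str]
    masked_fraction: float
    ref_pos: int  # insertion point on the reference sequence


@dataclass(frozen=True)
class TruthSV:
    svtype: str
    chrom: str
    pos: int  # 0-based breakpoint on the reference
    size: int
    breeds: frozenset[str]
    genotype: str  # genotype carried by every sample of those breeds


@dataclass
class TruthManifest:
    """Ground truth for one generated dataset."""

    reference_name: str
    alt_names: tuple[str, ...]
    spiked_insertions: list[SpikeRecord]
    gap_positions: dict[str, dict[str, list[tuple[int, int]]]]  # assembly -> seq -> runs
    telomere_margin: int
    true_svs: list[TruthSV]
    om_truth: list[tuple[str, int, int, str]]

    def validate(self, assemblies: Mapping[str, Mapping[str, str]] | None = None) -> None:
        alt_set = set(self.alt_names)
        for spike in self.spiked_insertions:
            if not spike.sharing or not spike.sharing <= alt_set:
                raise ValueError(f"spike sharing set {set(spike.sharing)} invalid")
            if not 0.0 <= spike.masked_fraction <= 1.0:
                raise ValueError("masked fraction outside [0, 1]")
            if assemblies is not None:
                seq = assemblies[spike.assembly][spike.seq_id]
                if not 0 <= spike.start < spike.end <= len(seq):
                    raise ValueError(f"spike outside sequence bounds: {spike}")

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, frozenset):
                return sorted(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=enc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(
            reference_name=d["reference_name"],
            alt_names=tuple(d["alt_names"]),
            spiked_insertions=[
                SpikeRecord(
                    assembly=s["assembly"],
                    seq_id=s["seq_id"],
                    start=s["start"],
                    end=s["end"],
                    sequence=s["sequence"],
                    sharing=frozenset(s["sharing"]),
                    masked_fraction=s["masked_fraction"],
                    ref_pos=s["ref_pos"],
                )
                for s in d["spiked_insertions"]
            ],
            gap_positions={
                a: {sid: [tuple(iv) for iv in ivs] for sid, ivs in seqs.items()}
                for a, seqs in d["gap_positions"].items()
            },
            telomere_margin=d["telomere_margin"],
            true_svs=[
                TruthSV(
                    svtype=t["svtype"],
                    chrom=t["chrom"],
                    pos=t["pos"],
                    size=t["size"],
                    breeds=frozenset(t["breeds"]),
                    genotype=t["genotype"],
                )
                for t in d["true_svs"]
            ],
            om_truth=[tuple(x) for x in d["om_truth"]],
        )


@dataclass(frozen=True)
class InsertionEvent:
    """A requested insertion on the reference coordinate system."""

    seq_id: str
    position: int  # 0-based point on the reference sequence
    length: int
    masked_fraction: float
    sharing: frozenset[str]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mask_sequence(rng: np.random.Generator, seq: str, fraction: float) -> str:
    """Lower-case a contiguous block of ``fraction`` of the bases."""
    n = int(round(fraction * len(seq)))
    if n <= 0:
        return seq
    start = int(rng.integers(0, len(seq) - n + 1))
    return seq[:start] + seq[start : start + n].lower() + seq[start + n :]


def _normalise_ref_spec(reference_spec: Mapping) -> list[int]:
    if "lengths" in reference_spec:
        lengths = [int(x) for x in reference_spec["lengths"]]
    else:
        lengths = [int(reference_spec["length"])] * int(
            reference_spec.get("n_sequences", 1)
        )
    if any(l < 10_000 for l in lengths):
        raise ValueError("reference sequence lengths must be ≥ 10 kb")
    return lengths


def generate_assembly_set(
    seed: int,
    reference_spec: Mapping,
    alt_specs: Sequence[Mapping],
    gap_rate: float = 2e-6,
    reference_name: str = "ref",
    telomere_margin: int = DEFAULT_TELOMERE_MARGIN,
    extra_sv_spec: Mapping | None = None,
) -> tuple[dict[str, dict[str, str]], GenomeGraph, TruthManifest]:
    """Generate a reference, alternates with spiked insertions, and their graph.

    ``reference_spec``: ``{"n_sequences": k, "length": L}`` or
    ``{"lengths": [...]}`` (each ≥ 10 kb).  Each alt spec is a mapping
    with ``name`` plus either explicit ``insertions`` (dicts with
    ``position``, ``length``, ``masked_fraction``, optional ``seq_id``
    and ``sharing``) or random generation controls ``n_insertions``,
    ``length_range``, ``masked_fraction_range`` and an optional
    ``sharing`` list of name-lists cycled across that entry's insertions.
    Randomly placed insertions avoid telomeric margins and N-gap flanks,
    so default spikes satisfy the positional retention rules; explicit
    placement is how rule-violating spikes are engineered.

    ``gap_rate`` is the per-bp probability that an N-run starts at a
    reference base.  ``extra_sv_spec`` controls deletion/inversion truth
    entries present only in SV callsets (defaults: 6 deletions, 3
    inversions of 600–5,000 bp).

    Returns ``(assemblies, graph, manifest)`` where ``assemblies`` maps
    assembly name -> {sequence id -> sequence}; each assembly's graph
    path reconstructs its sequence exactly.
    """
    rng = np.random.default_rng(seed)
    alt_names = [str(spec["name"]) for spec in alt_specs]
    if len(set(alt_names)) != len(alt_names) or reference_name in alt_names:
        raise ValueError("alt names must be unique and distinct from the reference")
    lengths = _normalise_ref_spec(reference_spec)
    seq_ids = [f"chr{i+1}" for i in range(len(lengths))]

    # reference sequences with N-gaps
    ref_seqs: dict[str, str] = {}
    ref_gaps: dict[str, list[tuple[int, int]]] = {}
    explicit_gaps = reference_spec.get("gaps")  # per-sequence interval lists
    for i, (sid, L) in enumerate(zip(seq_ids, lengths)):
        seq = _random_sequence(rng, L)
        gaps: list[tuple[int, int]] = []
        if explicit_gaps is not None:
            gaps = [(int(s), int(e)) for s, e in explicit_gaps[i]]
            if any(not 0 <= s < e <= L for s, e in gaps):
                raise ValueError(f"explicit gap outside sequence {sid}")
        else:
            n_gaps = int(rng.binomial(L, gap_rate))
            for _ in range(n_gaps):
                glen = int(rng.integers(*DEFAULT_GAP_LENGTH_RANGE))
                hi = L - telomere_margin - glen
                if hi <= telomere_margin:
                    continue  # no interior room on a short sequence
                gs = int(rng.integers(telomere_margin, hi))
                gaps.append((gs, gs + glen))
        gaps = _merge_sorted(gaps)
        chars = list(seq)
        for gs, ge in gaps:
            chars[gs:ge] = "N" * (ge - gs)
        ref_seqs[sid] = "".join(chars)
        ref_gaps[sid] = gaps

    events = _collect_insertion_events(
        rng, alt_specs, alt_names, seq_ids, lengths, ref_gaps, telomere_margin
    )

    assemblies, graph, spikes = _build_graph(
        reference_name, alt_names, ref_seqs, events, rng
    )

    # gap coordinates per assembly (lifted through insertions)
    gap_positions: dict[str, dict[str, list[tuple[int, int]]]] = {
        reference_name: {sid: list(ref_gaps[sid]) for sid in seq_ids}
    }
    for alt in alt_names:
        gap_positions[alt] = {}
        for sid in seq_ids:
            ins_here = sorted(
                (ev.position, ev.length)
                for ev in events
                if ev.seq_id == sid and alt in ev.sharing
            )
            lifted = []
            for gs, ge in ref_gaps[sid]:
                shift = sum(ln for p, ln in ins_here if p <= gs)
                lifted.append((gs + shift, ge + shift))
            gap_positions[alt][sid] = lifted

    true_svs = _truth_svs(rng, events, seq_ids, lengths, ref_gaps, alt_names,
                          telomere_margin, extra_sv_spec)
    om_truth = []
    for sv in true_svs:
        if sv.svtype == "INS":
            om_truth.append((sv.chrom, sv.pos, sv.pos + 1, "INS"))
        else:
            om_truth.append((sv.chrom, sv.pos, sv.pos + sv.size, sv.svtype))

    manifest = TruthManifest(
        reference_name=reference_name,
        alt_names=tuple(alt_names),
        spiked_insertions=spikes,
        gap_positions=gap_positions,
        telomere_margin=telomere_margin,
        true_svs=true_svs,
        om_truth=sorted(om_truth),
    )
    manifest.validate(assemblies)
    return assemblies, graph, manifest


def _merge_sorted(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _collect_insertion_events(
    rng, alt_specs, alt_names, seq_ids, lengths, ref_gaps, telomere_margin
) -> list[InsertionEvent]:
    events: list[InsertionEvent] = []
    taken: dict[str, list[int]] = {sid: [] for sid in seq_ids}

    def position_ok(sid: str, pos: int, L: int) -> bool:
        if not telomere_margin < pos < L - telomere_margin:
            return False
        for gs, ge in ref_gaps[sid]:
            if gs - 2_000 < pos < ge + 2_000:
                return False
        return all(abs(pos - p) >= MIN_SPIKE_SEPARATION for p in taken[sid])

    for spec in alt_specs:
        name = str(spec["name"])
        sharing_cycle = spec.get("sharing")
        if sharing_cycle is not None:
            for group in sharing_cycle:
                bad = set(group) - set(alt_names)
                if bad:
                    raise ValueError(f"sharing pattern names unknown: {sorted(bad)}")
        explicit = spec.get("insertions")
        if explicit is not None:
            for ins in explicit:
                sid = ins.get("seq_id", seq_ids[0])
                pos = int(ins["position"])
                L = lengths[seq_ids.index(sid)]
                if not 0 < pos < L:
                    raise ValueError(f"insertion position {pos} outside (0, {L})")
                if any(abs(pos - p) < 1 for p in taken[sid]):
                    raise ValueError(
                        f"overlapping requested insertions at {sid}:{pos}"
                    )
                sharing = frozenset(ins.get("sharing", [name]))
                if not sharing <= set(alt_names):
                    raise ValueError(
                        f"sharing names {sorted(sharing - set(alt_names))} not in alt specs"
                    )
                taken[sid].append(pos)
                events.append(
                    InsertionEvent(
                        seq_id=sid,
                        position=pos,
                        length=int(ins["length"]),
                        masked_fraction=float(ins.get("masked_fraction", 0.0)),
                        sharing=sharing,
                    )
                )
            continue
        n_ins = int(spec.get("n_insertions", 0))
        lo, hi = spec.get("length_range", (200, 2000))
        # default range models non-repetitive novel sequence (below the
        # 0.5399 genome-wide masked mean)
        mlo, mhi = spec.get("masked_fraction_range", (0.2, 0.5))
        for i in range(n_ins):
            sid = seq_ids[int(rng.integers(len(seq_ids)))]
            L = lengths[seq_ids.index(sid)]
            for _ in range(1000):
                pos = int(rng.integers(telomere_margin + 1, L - telomere_margin))
                if position_ok(sid, pos, L):
                    break
            else:
                raise ValueError("could not place insertion away from gaps/telomeres")
            if sharing_cycle:
                sharing = frozenset(sharing_cycle[i % len(sharing_cycle)])
            else:
                sharing = frozenset([name])
            taken[sid].append(pos)
            events.append(
                InsertionEvent(
                    seq_id=sid,
                    position=pos,
                    length=int(rng.integers(lo, hi + 1)),
                    masked_fraction=float(rng.uniform(mlo, mhi)),
                    sharing=sharing,
                )
            )
    return events


def _build_graph(
    reference_name: str,
    alt_names: list[str],
    ref_seqs: dict[str, str],
    events: list[InsertionEvent],
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, str]], GenomeGraph, list[SpikeRecord]]:
    graph = GenomeGraph()
    assemblies: dict[str, dict[str, str]] = {reference_name: {}}
    for alt in alt_names:
        assemblies[alt] = {}
    spikes: list[SpikeRecord] = []
    node_counter = 0

    def new_node(seq: str) -> str:
        nonlocal node_counter
        node_counter += 1
        nid = f"s{node_counter}"
        graph.nodes[nid] = seq
        return nid

    for sid, ref_seq in ref_seqs.items():
        here = sorted(
            (ev for ev in events if ev.seq_id == sid), key=lambda ev: ev.position
        )
        cuts = [ev.position for ev in here]
        bounds = [0] + cuts + [len(ref_seq)]
        ref_nodes = []
        for a, b in zip(bounds, bounds[1:]):
            if a == b:
                continue
            ref_nodes.append((a, new_node(ref_seq[a:b])))
        ins_nodes: dict[int, tuple[str, InsertionEvent, str]] = {}
        for ev in here:
            seq = _mask_sequence(
                rng, _random_sequence(rng, ev.length), ev.masked_fraction
            )
            ins_nodes[ev.position] = (new_node(seq), ev, seq)
        # reference path
        ref_path = [(nid, "+") for _a, nid in ref_nodes]
        graph.paths[f"{reference_name}#{sid}"] = ref_path
        assemblies[reference_name][sid] = ref_seq
        # alternate paths
        for alt in alt_names:
            steps: list[tuple[str, str]] = []
            parts: list[str] = []
            offset = 0
            for (a, nid), nxt in zip(ref_nodes, ref_nodes[1:] + [(len(ref_seq), None)]):
                steps.append((nid, "+"))
                node_seq = graph.nodes[nid]
                parts.append(node_seq)
                offset += len(node_seq)
                cut = nxt[0]
                if cut in ins_nodes:
                    ins_id, ev, ins_seq = ins_nodes[cut]
                    if alt in ev.sharing:
                        steps.append((ins_id, "+"))
                        parts.append(ins_seq)
                        spikes.append(
                            SpikeRecord(
                                assembly=alt,
                                seq_id=sid,
                                start=offset,
                                end=offset + len(ins_seq),
                                sequence=ins_seq,
                                sharing=ev.sharing,
                                masked_fraction=ev.masked_fraction,
                                ref_pos=ev.position,
                            )
                        )
                        offset += len(ins_seq)
            graph.paths[f"{alt}#{sid}"] = steps
            assemblies[alt][sid] = "".join(parts)
        for path_name in (f"{reference_name}#{sid}", *(f"{alt}#{sid}" for alt in alt_names)):
            steps = graph.paths[path_name]
            for (a, ao), (b, bo) in zip(steps, steps[1:]):
                graph.edges.add((a, ao, b, bo))
    spikes.sort(key=lambda s: (s.assembly, s.seq_id, s.start))
    return assemblies, graph, spikes


def _truth_svs(
    rng, events, seq_ids, lengths, ref_gaps, alt_names, telomere_margin, extra_sv_spec
) -> list[TruthSV]:
    spec = {"n_del": 6, "n_inv": 3, "size_range": (600, 5000)}
    if extra_sv_spec:
        spec.update(extra_sv_spec)
    svs: list[TruthSV] = []
    for ev in events:
        gt = "1/1" if rng.random() < 0.5 else "0/1"
        svs.append(
            TruthSV(
                svtype="INS",
                chrom=ev.seq_id,
                pos=ev.position,
                size=ev.length,
                breeds=ev.sharing,
                genotype=gt,
            )
        )
    taken = {sid: [ev.position for ev in events if ev.seq_id == sid] for sid in seq_ids}
    for svtype, n in (("DEL", spec["n_del"]), ("INV", spec["n_inv"])):
        for _ in range(int(n)):
            sid = seq_ids[int(rng.integers(len(seq_ids)))]
            L = lengths[seq_ids.index(sid)]
            size = int(rng.integers(*spec["size_range"]))
            placed = False
            for _ in range(1000):
                pos = int(rng.integers(telomere_margin, L - telomere_margin - size))
                # keep a clear margin around the affected interval so truth
                # records stay unambiguous
                lo, hi = pos - MIN_SPIKE_SEPARATION, pos + size + MIN_SPIKE_SEPARATION
                if all(not lo <= p < hi for p in taken[sid]):
                    placed = True
                    break
            if not placed:
                continue  # crowded fixture: emit fewer extra SVs
            taken[sid].append(pos)
            k = int(rng.integers(1, len(alt_names) + 1))
            breeds = frozenset(
                np.array(alt_names)[rng.choice(len(alt_names), size=k, replace=False)].tolist()
            )
            gt = "1/1" if rng.random() < 0.5 else "0/1"
            svs.append(
                TruthSV(svtype=svtype, chrom=sid, pos=pos, size=size, breeds=breeds, genotype=gt)
            )
    svs.sort(key=lambda s: (s.chrom, s.pos, s.svtype))
    return svs


@dataclass(frozen=True)
class SampleSpec:
    name: str
    breed: str


def generate_sv_callsets(
    manifest: TruthManifest,
    reference: Mapping[str, str],
    samples: Sequence[SampleSpec | Mapping],
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    qual_model: Mapping[str, float] = {"mean": 60.0, "sd": 10.0},
    dp_model: Mapping[str, float] = {"mean": 50.0, "sd": 8.0},
    seed: int = 0,
) -> tuple[dict[str, list[SVRecord]], list[dict]]:
    """Emit per-sample callsets from the truth manifest.

    A sample carries every true SV whose breed set contains its breed;
    each such call is dropped with probability ``fn_rate``, and false
    positives are added at rate ``fp_rate`` per true call, at random
    reference positions.  With both rates zero the emitted calls equal
    the truth for each sample's breed.  Returns (callsets, truth table)
    where the truth table rows flag false positives.
    """
    if not samples:
        raise ValueError("empty sample list")
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    specs = [
        s if isinstance(s, SampleSpec) else SampleSpec(s["name"], s["breed"])
        for s in samples
    ]
    rng = np.random.default_rng(seed)
    callsets: dict[str, list[SVRecord]] = {}
    truth_rows: list[dict] = []
    for spec in specs:
        records: list[SVRecord] = []
        true_here = [sv for sv in manifest.true_svs if spec.breed in sv.breeds]
        for sv in true_here:
            if fn_rate > 0 and rng.random() < fn_rate:
                continue
            rec = _truth_to_record(sv, reference, spec.name, rng, qual_model, dp_model)
            records.append(rec)
            truth_rows.append(
                {"sample": spec.name, "chrom": rec.chrom, "pos": rec.pos,
                 "svtype": rec.svtype, "size": sv.size, "is_fp": False}
            )
        n_fp = int(rng.binomial(len(true_here), fp_rate)) if true_here else 0
        for _ in range(n_fp):
            rec = _random_fp_record(reference, spec.name, rng, qual_model, dp_model)
            records.append(rec)
            truth_rows.append(
                {"sample": spec.name, "chrom": rec.chrom, "pos": rec.pos,
                 "svtype": rec.svtype, "size": len(rec.ref) if not rec.alt.startswith("<")
                 else (rec.end - rec.pos), "is_fp": True}
            )
        records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
        callsets[spec.name] = records
    return callsets, truth_rows


def _genotype_fields(gt: str, rng, qual_model, dp_model) -> tuple[float, SampleCall]:
    qual = float(max(1.0, rng.normal(qual_model["mean"], qual_model["sd"])))
    dp = int(max(1, round(rng.normal(dp_model["mean"], dp_model["sd"]))))
    if gt in ("0/1", "1/0"):
        alt_d = int(rng.binomial(dp, 0.5))
    else:
        alt_d = dp - int(rng.binomial(dp, 0.02))
    return qual, SampleCall(gt=gt, dp=dp, ad=(dp - alt_d, alt_d))


def _truth_to_record(sv: TruthSV, reference, sample, rng, qual_model, dp_model) -> SVRecord:
    seq = reference[sv.chrom]
    qual, call = _genotype_fields(sv.genotype, rng, qual_model, dp_model)
    # deterministic allele sequences: derive from a per-variant generator so
    # the same truth SV spells the same alleles in every sample's callset
    vkey = zlib.crc32(f"{sv.chrom}:{sv.pos}:{sv.svtype}:{sv.size}".encode())
    vrng = np.random.default_rng(vkey % 2**31)
    if sv.svtype == "INS":
        anchor = seq[sv.pos - 1].upper()
        inserted = _random_sequence(vrng, sv.size)
        return SVRecord(
            chrom=sv.chrom, pos=sv.pos, ref=anchor, alt=anchor + inserted,
            svtype="INS", qual=qual, samples={sample: call}, sample_order=(sample,),
        )
    if sv.svtype == "DEL":
        ref = seq[sv.pos - 1 : sv.pos + sv.size].upper()
        return SVRecord(
            chrom=sv.chrom, pos=sv.pos, ref=ref, alt=ref[0],
            svtype="DEL", qual=qual, samples={sample: call}, sample_order=(sample,),
        )
    # inversions stay symbolic
    return SVRecord(
        chrom=sv.chrom, pos=sv.pos, ref=seq[sv.pos - 1].upper(), alt="<INV>",
        svtype="INV", qual=qual, end=sv.pos + sv.size,
        samples={sample: call}, sample_order=(sample,),
    )


def _random_fp_record(reference, sample, rng, qual_model, dp_model) -> SVRecord:
    chrom = sorted(reference)[int(rng.integers(len(reference)))]
    seq = reference[chrom]
    size = int(rng.integers(600, 3000))
    pos = int(rng.integers(10_000, len(seq) - 10_000 - size))
    qual, call = _genotype_fields("0/1", rng, qual_model, dp_model)
    if rng.random() < 0.5:
        anchor = seq[pos - 1].upper()
        return SVRecord(
            chrom=chrom, pos=pos, ref=anchor,
            alt=anchor + _random_sequence(rng, size), svtype="INS", qual=qual,
            samples={sample: call}, sample_order=(sample,),
        )
    ref = seq[pos - 1 : pos + size].upper()
    return SVRecord(
        chrom=chrom, pos=pos, ref=ref, alt=ref[0], svtype="DEL", qual=qual,
        samples={sample: call}, sample_order=(sample,),
    )


def generate_om_intervals(
    manifest: TruthManifest,
    ci_sd: float = 0.0,
    detection_rate: float = 1.0,
    seed: int = 0,
    om_samples: Sequence[str] = ("om1", "om2"),
) -> list[OMRecord]:
    """Emit optical-map records derived from the manifest's OM truth.

    Each truth interval is detected per OM sample with probability
    ``detection_rate``; breakpoints are jittered with sd ``ci_sd`` bp and
    the emitted confidence bounds always cover the jitter (hence the true
    breakpoint).  ``detection_rate=1, ci_sd=0`` reproduces the truth
    exactly.
    """
    if ci_sd < 0:
        raise ValueError("ci_sd must be ≥ 0")
    if not 0 <= detection_rate <= 1:
        raise ValueError("detection_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[OMRecord] = []
    for sample in om_samples:
        for chrom, start, end, svtype in manifest.om_truth:
            if rng.random() >= detection_rate:
                continue
            js = int(round(rng.normal(0, ci_sd))) if ci_sd > 0 else 0
            je = int(round(rng.normal(0, ci_sd))) if ci_sd > 0 else 0
            s = max(0, start + js)
            e = max(s, end + je)
            # CI spans the jittered and the true breakpoint, so the true
            # position always lies inside the reported bounds
            out.append(
                OMRecord(
                    chrom=chrom,
                    start=s,
                    end=e,
                    svtype=svtype,
                    ci_start_lo=min(s, start),
                    ci_start_hi=max(s, start),
                    ci_end_lo=min(e, end),
                    ci_end_hi=max(e, end),
                    sample=sample,
                )
            )
    return out
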