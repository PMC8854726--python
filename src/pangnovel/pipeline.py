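"""End-to-end orchestration: extract → filter → expand → SV bench → report.

`run_pipeline` wires the stages together over files on disk and emits a
report bundle (JSON/TSV) whose every proportion is recomputed from its
own printed counts.  Each stage is also callable on its own through the
library API or the ``pangnovel`` command-line subcommands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import io as pio
from .breeds import GroupCallset, group_restricted, qc_filter
from .graph import (
    GenomeGraph,
    exclude_regions,
    node_source_map,
    nonreference_nodes,
    project_segments,
    read_graph,
    screen_n_nodes,
)
from .intervals import IntervalSet
from .segments import (
    AlignmentRecord,
    ClassifiedSegment,
    NovelContig,
    build_expanded_genome,
    classify_segment,
    collapse_redundant,
    contig_stats,
    contigs_from_segments,
    filter_segments,
    merge_segments,
    shared_partition,
)
from .stats import PlacementSpace, permutation_overlap, proportion
from .svtools import (
    cluster_svs,
    intersect_by_type,
    merge_interval_sets,
    normalize_svs,
    om_to_intervals,
)

log = logging.getLogger("pangnovel")


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, with its default."""

    reference_name: str = "ref"
    merge_gap: int = 5
    length_short_lt: int = 10
    length_large_gt: int = 60
    telomere_margin: int = 10_000
    telomere_min_seq: int = 5_000_000
    gap_flank: int = 1_000
    novel_fraction: float = 0.95
    repeat_mean: float = 0.5399
    alpha: float = 0.05
    redundancy_identity: float = 0.99
    redundancy_coverage: float = 0.95
    sv_min_size: int = 500
    sv_cluster_dist: int = 100
    om_pad: int = 1_000
    # size of an explicit-allele insertion is its inserted length under
    # max_allele; under reference_allele it is 1 bp and the >500 bp filter
    # would exclude every insertion, so the pipeline defaults to max_allele
    sv_size_mode: str = "max_allele"
    qc_qual: float = 30
    qc_dp_lo: int = 20
    qc_dp_hi: int = 90
    qc_min_ac: int = 5
    perm_reps: int = 10_000
    seed: int = 0
    bh_m: int = 2_700_000_000
    peak_frac: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def log_thresholds(self) -> None:
        for f in dataclasses.fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))


def exact_duplicate_alignments(contigs: Sequence[NovelContig]) -> list[AlignmentRecord]:
    """Qualifying alignments between byte-identical contig sequences.

    Shared insertions project onto several assemblies as identical
    contigs; these links feed the redundancy collapse even when no
    aligner output is supplied.
    """
    by_seq: dict[str, list[NovelContig]] = {}
    for c in contigs:
        by_seq.setdefault(c.sequence.upper(), []).append(c)
    out = []
    for members in by_seq.values():
        for a, b in zip(members, members[1:]):
            out.append(
                AlignmentRecord(
                    query=a.contig_id,
                    target=b.contig_id,
                    block_length=a.length,
                    identity=1.0,
                )
            )
    return out


def extract_and_filter(
    graph: GenomeGraph,
    assemblies: Mapping[str, Mapping[str, str]],
    config: PipelineConfig,
    exclusions: Mapping[str, Mapping[str, list[tuple[int, int]]]] | None = None,
    alignments: Sequence[AlignmentRecord] | None = None,
) -> dict:
    """Run extraction through redundancy collapse; return stage artifacts.

    ``exclusions`` maps assembly -> sequence -> misassembly intervals (in
    that assembly's coordinates).  Returns a dict with per-genome
    segments, classified segments, retained segments, contigs, and the
    final collapsed contig list.
    """
    ref = config.reference_name
    nonref = nonreference_nodes(graph, ref)
    clean = screen_n_nodes(nonref, graph)
    alt_names = sorted(assemblies.keys() - {ref})
    per_genome_segments: dict[str, list] = {}
    classified: list[ClassifiedSegment] = []
    for alt in alt_names:
        segs = project_segments(graph, clean, alt)
        if exclusions and alt in exclusions:
            segs = exclude_regions(segs, exclusions[alt])
        merged = merge_segments(segs, max_gap=config.merge_gap)
        per_genome_segments[alt] = merged
        for seg in merged:
            seq = assemblies[alt][seg.seq_id]
            gaps = pio.gaps_of_sequence(seq)
            classified.append(
                classify_segment(
                    seg,
                    sequence_length=len(seq),
                    gap_intervals=gaps,
                    sequence=seq,
                    telomere_margin=config.telomere_margin,
                    telomere_min_seq=config.telomere_min_seq,
                    gap_flank=config.gap_flank,
                    novel_fraction=config.novel_fraction,
                    genome_mean=config.repeat_mean,
                )
            )
    # segments surviving the length/class/position rules enter the repeat
    # test; their count sets the Bonferroni correction
    pre_repeat = [
        cs
        for cs in classified
        if cs.length_class == "large"
        and cs.category == "novel"
        and not cs.telomeric
        and not cs.gap_flank
    ]
    n_tests = max(1, len(pre_repeat))
    retained = filter_segments(classified, n_tests=n_tests, alpha=config.alpha)
    contigs = contigs_from_segments(retained, assemblies)
    links = list(alignments or [])
    links.extend(exact_duplicate_alignments(contigs))
    final = collapse_redundant(
        contigs,
        links,
        min_identity=config.redundancy_identity,
        min_short_coverage=config.redundancy_coverage,
    )
    return {
        "nonref_nodes": nonref,
        "screened_nodes": clean,
        "per_genome_segments": per_genome_segments,
        "classified": classified,
        "n_tests": n_tests,
        "retained": retained,
        "contigs": contigs,
        "final_contigs": final,
    }


def table1_report(
    graph: GenomeGraph,
    screened_nodes: set[str],
    per_genome_retained: Mapping[str, Sequence[ClassifiedSegment]],
    final_contigs: Sequence[NovelContig],
    reference_name: str,
) -> dict:
    """Per-genome node/segment counts and the final contig statistics.

    Combined totals count shared nodes (and shared retained node-runs)
    once, so the combined column is ≤ the sum of the per-genome columns.
    """
    src = node_source_map(graph)
    genomes = sorted(
        {a for s in src.values() for a in s if a != reference_name}
    )
    rows: dict = {"genomes": genomes, "nonref_nodes": {}, "filtered": {}}
    for g in genomes:
        ids = [n for n in screened_nodes if g in src[n]]
        rows["nonref_nodes"][g] = {
            "n_nodes": len(ids),
            "bp": sum(len(graph.nodes[n]) for n in ids),
        }
    rows["nonref_nodes"]["total"] = {
        "n_nodes": len(screened_nodes),
        "bp": sum(len(graph.nodes[n]) for n in screened_nodes),
    }
    seen_runs: set[tuple[str, ...]] = set()
    combined_n = 0
    combined_bp = 0
    for g in genomes:
        segs = per_genome_retained.get(g, [])
        rows["filtered"][g] = {
            "n_segments": len(segs),
            "bp": sum(cs.length for cs in segs),
        }
        for cs in segs:
            key = cs.segment.nodes
            if key not in seen_runs:
                seen_runs.add(key)
                combined_n += 1
                combined_bp += cs.length
    rows["filtered"]["total"] = {"n_segments": combined_n, "bp": combined_bp}
    if final_contigs:
        stats = contig_stats(list(final_contigs))
        rows["final_contigs"] = dataclasses.asdict(stats)
    else:
        rows["final_contigs"] = None
    return rows


def sv_benchmark(
    callsets: Sequence[tuple[str, Sequence]],
    om_intervals: IntervalSet,
    config: PipelineConfig,
) -> dict:
    """Cluster calls across samples and count optical-map-supported SVs."""
    clusters = cluster_svs(
        callsets,
        max_dist=config.sv_cluster_dist,
        min_size=config.sv_min_size,
        size_mode=config.sv_size_mode,
    )
    reps = [c.representative for c in clusters]
    flags, summary = intersect_by_type(
        reps, om_intervals, size_mode=config.sv_size_mode, typed=False
    )
    pct = (
        proportion(summary["supported"], summary["total"])
        if summary["total"]
        else None
    )
    return {
        "clusters": clusters,
        "flags": flags,
        "n_svs": summary["total"],
        "n_supported": summary["supported"],
        "pct_supported": pct,
    }


def run_pipeline(
    config: PipelineConfig,
    inputs: Mapping,
    out_dir: str | Path,
) -> dict:
    """Execute all stages over files and write the report bundle.

    ``inputs`` keys: ``gfa`` (graph path); ``assemblies`` (mapping name
    -> FASTA path); optional ``exclusions`` (mapping assembly -> BED
    path); ``svs`` (list of {sample, breed, vcf}); ``om`` (TSV path);
    optional ``paf`` (alignments for redundancy collapse).  Writes NOVEL
    contigs, the expanded genome, classified segments, and report.json /
    report.tsv under ``out_dir``.  Deterministic given config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.log_thresholds()
    stage = "parse-inputs"
    try:
        with open(inputs["gfa"]) as fh:
            graph = read_graph(fh)
        assemblies = {
            name: pio.read_fasta(path) for name, path in inputs["assemblies"].items()
        }
        exclusions = None
        if inputs.get("exclusions"):
            exclusions = {}
            for asm, bed in inputs["exclusions"].items():
                per_seq: dict[str, list[tuple[int, int]]] = {}
                for chrom, s, e, *_ in pio.read_bed(bed):
                    per_seq.setdefault(chrom, []).append((s, e))
                exclusions[asm] = per_seq
        alignments = pio.read_paf(inputs["paf"]) if inputs.get("paf") else None

        stage = "extract-filter"
        ext = extract_and_filter(graph, assemblies, config, exclusions, alignments)
        per_genome_retained: dict[str, list[ClassifiedSegment]] = {}
        for cs in ext["retained"]:
            per_genome_retained.setdefault(cs.segment.assembly, []).append(cs)

        stage = "expand"
        expanded, provenance = build_expanded_genome(
            assemblies[config.reference_name], ext["final_contigs"]
        )
        pio.write_fasta(
            {c.contig_id: c.sequence for c in ext["final_contigs"]},
            out / "novel_contigs.fasta",
        )
        pio.write_fasta(expanded, out / "expanded_genome.fasta")
        with open(out / "provenance.tsv", "w") as fh:
            fh.write("contig_id\tassembly\tseq_id\tstart\tend\tsources\n")
            for row in provenance:
                fh.write(
                    "\t".join(str(row[k]) for k in
                              ("contig_id", "assembly", "seq_id", "start", "end", "sources"))
                    + "\n"
                )
        _write_classified(ext["classified"], out / "classified_segments.tsv")

        stage = "sv-bench"
        sample_callsets = []
        breed_of: dict[str, str] = {}
        for svc in inputs.get("svs", []):
            raw = pio.read_vcf(svc["vcf"])
            recs = normalize_svs(raw)
            sample_callsets.append((svc["sample"], recs))
            breed_of[svc["sample"]] = svc["breed"]
        om_records = pio.read_om_tsv(inputs["om"]) if inputs.get("om") else []
        padded = om_to_intervals(om_records, pad=config.om_pad)
        om_pooled = merge_interval_sets(
            [padded], keep_sequences=assemblies[config.reference_name].keys()
        )
        bench = (
            sv_benchmark(sample_callsets, om_pooled, config)
            if sample_callsets
            else None
        )

        stage = "permutation"
        perm = None
        if bench and bench["n_svs"] and len(om_pooled):
            ref_seqs = assemblies[config.reference_name]
            gaps = {sid: pio.gaps_of_sequence(seq) for sid, seq in ref_seqs.items()}
            space = PlacementSpace(
                {sid: len(seq) for sid, seq in ref_seqs.items()}, gaps
            )
            queries = [
                (r.chrom, *r.interval(config.sv_size_mode))
                for r in (c.representative for c in bench["clusters"])
            ]
            perm = permutation_overlap(
                queries, space, om_pooled, n_reps=config.perm_reps, seed=config.seed
            )

        stage = "breed-restricted"
        groups: dict[str, GroupCallset] = {}
        for sample, recs in sample_callsets:
            b = breed_of[sample]
            groups.setdefault(b, GroupCallset(group=b)).samples[sample] = list(recs)
        breed_report = {}
        if len(groups) >= 2:
            for b in sorted(groups):
                restricted = group_restricted(list(groups.values()), b)
                hq = [
                    rec
                    for rec in restricted
                    if qc_filter(
                        rec,
                        qual_min=config.qc_qual,
                        dp_lo=config.qc_dp_lo,
                        dp_hi=config.qc_dp_hi,
                        min_ac=config.qc_min_ac,
                        min_size=config.sv_min_size,
                        size_mode=config.sv_size_mode,
                    )[0]
                ]
                _, summary = intersect_by_type(
                    hq, om_pooled, size_mode=config.sv_size_mode, typed=False
                )
                breed_report[b] = {
                    "n_candidates": len(restricted),
                    "n_high_quality": len(hq),
                    "n_om_supported": summary["supported"],
                    "pct_om_supported": (
                        proportion(summary["supported"], len(hq)) if hq else None
                    ),
                }

        stage = "report"
        table1 = table1_report(
            graph,
            ext["screened_nodes"],
            per_genome_retained,
            ext["final_contigs"],
            config.reference_name,
        )
        partition = {
            "+".join(sorted(k)): round(v, 3)
            for k, v in shared_partition(ext["final_contigs"]).items()
        }
        report = {
            "config": dataclasses.asdict(config),
            "table1": table1,
            "n_tests": ext["n_tests"],
            "bonferroni_cutoff": config.alpha / ext["n_tests"],
            "shared_partition_kb": partition,
            "sv_benchmark": (
                {
                    "n_svs": bench["n_svs"],
                    "n_supported": bench["n_supported"],
                    "pct_supported": bench["pct_supported"],
                }
                if bench
                else None
            ),
            "permutation": (
                {
                    "observed": perm.observed,
                    "null_mean": perm.null_mean,
                    "null_sd": perm.null_sd,
                    "z": None if perm.degenerate else perm.z,
                    "p_empirical": perm.p_empirical,
                    "n_reps": perm.n_reps,
                }
                if perm
                else None
            ),
            "breed_restricted": breed_report,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_classified(classified: Sequence[ClassifiedSegment], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "assembly\tseq_id\tstart\tend\tsources\tnonref_fraction\tlength_class\t"
            "telomeric\tgap_flank\tcategory\tmasked_fraction\trepeat_p\tdecision\n"
        )
        for cs in classified:
            seg = cs.segment
            fh.write(
                f"{seg.assembly}\t{seg.seq_id}\t{seg.start}\t{seg.end}\t"
                f"{','.join(sorted(seg.sources))}\t{seg.nonref_fraction:.4f}\t"
                f"{cs.length_class}\t{int(cs.telomeric)}\t{int(cs.gap_flank)}\t"
                f"{cs.category}\t{cs.masked_fraction:.4f}\t{cs.repeat_p:.3e}\t{cs.decision}\n"
            )
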