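"""Segment merging, classification, filtering, redundancy and contigs."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from pangnovel.graph import NonRefSegment
from pangnovel.segments import (
    AlignmentRecord,
    NovelContig,
    bonferroni_cutoff,
    build_expanded_genome,
    classify_segment,
    collapse_redundant,
    consensus_genes,
    contig_stats,
    filter_segments,
    merge_segments,
    repeat_enrichment_p,
    shared_partition,
)


def seg(start, end, frac=1.0, sources=("alt1",), seq="chr1", assembly="alt1"):
    return NonRefSegment(
        assembly=assembly, seq_id=seq, start=start, end=end,
        sources=frozenset(sources), nonref_fraction=frac,
    )


class TestMerge:
    def test_gap_at_threshold_merges(self):
        merged = merge_segments([seg(10, 20), seg(24, 30)], max_gap=5)
        assert [(s.start, s.end) for s in merged] == [(10, 30)]

    def test_gap_above_threshold_stays_split(self):
        merged = merge_segments([seg(10, 20), seg(26, 30)], max_gap=5)
        assert [(s.start, s.end) for s in merged] == [(10, 20), (26, 30)]

    def test_bridged_gap_counts_as_reference(self):
        merged = merge_segments([seg(10, 20), seg(24, 30)], max_gap=5)
        assert merged[0].nonref_fraction == pytest.approx(16 / 20)

    def test_sources_unioned(self):
        merged = merge_segments(
            [seg(10, 20, sources=("alt1",)), seg(22, 30, sources=("alt2",))]
        )
        assert merged[0].sources == frozenset({"alt1", "alt2"})

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            merge_segments([seg(24, 30), seg(10, 20)])

    def test_output_gaps_all_exceed_threshold(self):
        rng = np.random.default_rng(7)
        starts = np.cumsum(rng.integers(1, 20, size=50))
        segs = [seg(int(s), int(s + rng.integers(1, 8))) for s in starts]
        segs = [s for s in segs if s.start < s.end]
        segs.sort(key=lambda s: s.start)
        # drop overlaps to satisfy the sortedness/disjointness premise
        clean = []
        for s in segs:
            if not clean or s.start > clean[-1].end:
                clean.append(s)
        merged = merge_segments(clean, max_gap=5)
        gaps = [b.start - a.end for a, b in zip(merged, merged[1:])]
        assert all(g > 5 for g in gaps)
        assert sum(s.length * s.nonref_fraction for s in merged) == pytest.approx(
            sum(s.length for s in clean)
        )


class TestClassify:
    @pytest.mark.parametrize(
        "length, expected",
        [(9, "short"), (10, "intermediate"), (59, "intermediate"),
         (60, "intermediate"), (61, "large")],
    )
    def test_length_class_boundaries(self, length, expected):
        cs = classify_segment(seg(1000, 1000 + length), 20_000_000)
        assert cs.length_class == expected

    def test_telomeric_needs_chromosome_scale_sequence(self):
        near_end = seg(19_990_000, 19_995_000)
        assert classify_segment(near_end, 20_000_000).telomeric
        # same relative position on a 1 Mb scaffold: never telomeric
        assert not classify_segment(seg(990_000, 995_000), 1_000_000).telomeric
        assert not classify_segment(seg(50_000, 51_000), 20_000_000).telomeric

    def test_gap_flank_within_1kb(self):
        gaps = [(100_000, 100_500)]
        assert classify_segment(seg(101_000, 101_100), 20_000_000, gaps).gap_flank
        assert not classify_segment(seg(102_000, 102_100), 20_000_000, gaps).gap_flank

    @pytest.mark.parametrize("frac, category", [(0.96, "novel"), (0.95, "novel"), (0.94, "haplotype")])
    def test_novel_fraction_boundary(self, frac, category):
        cs = classify_segment(seg(1000, 2000, frac=frac), 20_000_000)
        assert cs.category == category

    def test_masked_fraction_counted_from_sequence(self):
        sequence = "A" * 1000 + "acgt" * 25 + "A" * 1000
        cs = classify_segment(seg(1000, 1100), 20_000_000, sequence=sequence)
        assert cs.masked_fraction == 1.0


class TestRepeatEnrichment:
    def test_mean_masked_fraction_gives_half(self):
        p = repeat_enrichment_p(int(round(0.5399 * 10_000)), 10_000)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_fully_masked_is_enriched(self):
        z = (100 - 53.99) / math.sqrt(100 * 0.5399 * 0.4601)
        assert repeat_enrichment_p(100, 100) == pytest.approx(float(sps.norm.sf(z)))
        assert repeat_enrichment_p(100, 100) < 8e-7

    def test_short_segment_against_exact_binomial(self):
        # 6/10 masked: unremarkable under a 0.54 null
        exact = float(sps.binom.sf(5, 10, 0.5399))
        assert repeat_enrichment_p(6, 10, exact=True) == pytest.approx(exact)
        assert repeat_enrichment_p(6, 10, exact=True) > 0.05

    def test_normal_approximation_tracks_exact_tail(self):
        for length, masked in [(500, 300), (1000, 600), (2000, 1150)]:
            approx = repeat_enrichment_p(masked, length)
            exact = repeat_enrichment_p(masked, length, exact=True)
            assert math.log10(approx) == pytest.approx(math.log10(exact), abs=0.5)


class TestFilter:
    def make(self, **over):
        base = dict(length=100, frac=1.0, telomeric=False, gap=False, masked=30)
        base.update(over)
        s = seg(100_000, 100_000 + base["length"], frac=base["frac"])
        gaps = [(100_000 - 500, 100_000 - 400)] if base["gap"] else []
        seq_len = 20_000_000
        if base["telomeric"]:
            s = seg(5_000, 5_000 + base["length"], frac=base["frac"])
        return classify_segment(s, seq_len, gaps, masked_bases=base["masked"])

    def test_clean_large_novel_retained(self):
        cs = self.make()
        assert filter_segments([cs], n_tests=100) == [cs]
        assert cs.decision == "retained"

    @pytest.mark.parametrize(
        "over, reason",
        [
            (dict(length=50), "dropped:length"),
            (dict(frac=0.90), "dropped:haplotype"),
            (dict(telomeric=True), "dropped:telomeric"),
            (dict(gap=True), "dropped:gap_flank"),
            (dict(masked=100, length=100), "dropped:repetitive"),
        ],
    )
    def test_first_failing_reason_recorded(self, over, reason):
        cs = self.make(**over)
        assert filter_segments([cs], n_tests=100) == []
        assert cs.decision == reason

    def test_boundary_p_equal_to_cutoff_drops(self):
        cs = self.make()
        cs.repeat_p = 0.05 / 100
        assert filter_segments([cs], n_tests=100) == []
        assert cs.decision == "dropped:repetitive"

    def test_bonferroni_cutoff_value(self):
        assert bonferroni_cutoff(62_337) == pytest.approx(0.05 / 62_337)
        assert round(bonferroni_cutoff(62_337), 7) == 8e-7

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(5)
        batch = []
        for _ in range(40):
            length = int(rng.integers(61, 3000))
            batch.append(self.make(length=length, masked=int(rng.integers(0, length + 1))))
        n_loose = len(filter_segments(batch, n_tests=10, alpha=0.05))
        n_tight = len(filter_segments(batch, n_tests=10, alpha=0.005))
        assert n_tight <= n_loose


def contig(cid, length, assembly="alt1", start=0, sources=("alt1",)):
    return NovelContig(
        contig_id=cid, sequence="A" * length, assembly=assembly,
        seq_id="chr1", start=start, end=start + length,
        sources=frozenset(sources),
    )


class TestCollapse:
    def test_worked_pair_keeps_longer(self):
        c1, c2 = contig("contig1", 1000), contig("contig2", 300, start=5000)
        aln = AlignmentRecord("contig1", "contig2", block_length=296, identity=0.995)
        kept = collapse_redundant([c1, c2], [aln])
        assert [c.contig_id for c in kept] == ["contig1"]

    def test_low_identity_keeps_both(self):
        c1, c2 = contig("contig1", 1000), contig("contig2", 300, start=5000)
        aln = AlignmentRecord("contig1", "contig2", block_length=296, identity=0.98)
        assert len(collapse_redundant([c1, c2], [aln])) == 2

    def test_short_coverage_below_threshold_keeps_both(self):
        c1, c2 = contig("contig1", 1000), contig("contig2", 300, start=5000)
        aln = AlignmentRecord("contig1", "contig2", block_length=280, identity=0.995)
        assert len(collapse_redundant([c1, c2], [aln])) == 2

    def test_transitive_chain_collapses_to_longest(self):
        a, b, c = contig("a", 500), contig("b", 800, start=1000), contig("c", 600, start=3000)
        alns = [
            AlignmentRecord("a", "b", 495, 0.999),
            AlignmentRecord("b", "c", 590, 0.999),
        ]
        kept = collapse_redundant([a, b, c], alns)
        assert [k.contig_id for k in kept] == ["b"]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_connected_components_oracle(self, trial):
        rng = np.random.default_rng(4000 + trial)
        n = 12
        contigs = [contig(f"c{i:02d}", int(rng.integers(100, 2000)), start=i * 3000)
                   for i in range(n)]
        by_id = {c.contig_id: c for c in contigs}
        alns = []
        for _ in range(10):
            i, j = rng.choice(n, 2, replace=False)
            q, t = contigs[i], contigs[j]
            ident = float(rng.uniform(0.97, 1.0))
            block = int(rng.uniform(0.8, 1.0) * min(q.length, t.length))
            alns.append(AlignmentRecord(q.contig_id, t.contig_id, block, ident))
        g = nx.Graph()
        g.add_nodes_from(by_id)
        for a in alns:
            shorter = min(by_id[a.query].length, by_id[a.target].length)
            if a.identity > 0.99 and a.block_length >= 0.95 * shorter:
                g.add_edge(a.query, a.target)
        expected = sorted(
            max(comp, key=lambda cid: (by_id[cid].length, _inv(cid)))
            for comp in nx.connected_components(g)
        )
        kept = collapse_redundant(contigs, alns)
        assert [c.contig_id for c in kept] == expected
        # no qualifying pair survives among the kept set
        kept_ids = {c.contig_id for c in kept}
        for a in alns:
            shorter = min(by_id[a.query].length, by_id[a.target].length)
            if a.identity > 0.99 and a.block_length >= 0.95 * shorter:
                assert not {a.query, a.target} <= kept_ids
        assert sum(c.length for c in kept) <= sum(c.length for c in contigs)


class _inv(str):
    def __lt__(self, other):
        return str.__gt__(self, other)


class TestStatsAndPartition:
    def test_single_contig_stats(self):
        st = contig_stats([contig("c1", 61)])
        assert (st.min_bp, st.max_bp, st.mean_bp, st.sd_bp) == (61, 61, 61.0, 0.0)

    def test_two_lengths_mean(self):
        st = contig_stats([contig("a", 61), contig("b", 103_683, start=5_000)])
        assert st.mean_bp == 51_872.00
        assert st.total_bp == 61 + 103_683

    def test_mean_times_count_matches_total(self):
        rng = np.random.default_rng(9)
        contigs = [contig(f"c{i}", int(rng.integers(61, 5000)), start=i * 6000)
                   for i in range(200)]
        st = contig_stats(contigs)
        assert abs(st.mean_bp * st.count - st.total_bp) <= 0.005 * st.count

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contig_stats([])

    def test_partition_assigns_each_base_once(self):
        items = [
            contig("a", 2000, sources=("alt1", "alt2")),
            contig("b", 500, start=3000, sources=("alt1",)),
        ]
        part = shared_partition(items)
        assert part[frozenset({"alt1", "alt2"})] == pytest.approx(2.0)
        assert part[frozenset({"alt1"})] == pytest.approx(0.5)
        assert sum(part.values()) == pytest.approx(sum(c.length for c in items) / 1000)


class TestExpandedGenome:
    def test_zero_contigs_identity(self):
        ref = {"chr1": "ACGT" * 100}
        expanded, prov = build_expanded_genome(ref, [])
        assert expanded == ref and prov == []

    def test_additivity_and_provenance(self):
        ref = {"chr1": "A" * 1000}
        contigs = [contig("nc1", 200, start=100), contig("nc2", 300, start=900)]
        expanded, prov = build_expanded_genome(ref, contigs)
        assert sum(map(len, expanded.values())) == 1000 + 500
        assert list(expanded)[0] == "chr1"
        assert [p["contig_id"] for p in prov] == ["nc1", "nc2"]

    def test_id_collision_rejected(self):
        ref = {"chr1": "A" * 1000}
        with pytest.raises(ValueError, match="chr1"):
            build_expanded_genome(ref, [contig("chr1", 100)])

    def test_provenance_round_trip(self, engineered_dataset):
        assemblies, graph, manifest, config, _ = engineered_dataset
        from pangnovel.pipeline import extract_and_filter

        ext = extract_and_filter(graph, assemblies, config)
        for c in ext["final_contigs"]:
            assert assemblies[c.assembly][c.seq_id][c.start : c.end] == c.sequence


def test_consensus_genes_case_folded_intersection():
    assert consensus_genes({"A", "b"}, {"B", "c"}, {"b", "d"}) == {"b"}
    assert consensus_genes({"x"}, {"y"}, {"z"}) == set()
    assert consensus_genes({"G1", "g2"}, {"g1", "G2"}, {"g1", "g2"}) == {"g1", "g2"}
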