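"""SV normalisation, sizing, OM conversion, clustering, intersection."""

import networkx as nx
import numpy as np
import pytest

from pangnovel.intervals import IntervalSet, merge_intervals, overlap_length
from pangnovel.svtools import (
    OMRecord,
    SampleCall,
    SVRecord,
    cluster_svs,
    intersect_by_type,
    merge_interval_sets,
    normalize_svs,
    om_to_intervals,
    sv_size,
    three_way_support,
)


def rec(chrom="chr1", pos=100, ref="A", alt=None, svtype=None, end=None, **kw):
    if alt is None:
        alt = "A" + "C" * 600
    if svtype is None:
        svtype = "INS" if len(alt) > len(ref) else "DEL"
    return SVRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, svtype=svtype, end=end, **kw)


class TestNormalize:
    def test_insertion_typed_from_allele_lengths(self):
        out = normalize_svs([{"chrom": "chr1", "pos": 10, "ref": "A",
                              "alts": ["A" + "G" * 600]}])
        assert [r.svtype for r in out] == ["INS"]

    def test_deletion_typed_from_allele_lengths(self):
        out = normalize_svs([{"chrom": "chr1", "pos": 10, "ref": "G" * 800,
                              "alts": ["G"]}])
        assert [r.svtype for r in out] == ["DEL"]

    def test_multiallelic_split_into_two_records(self):
        out = normalize_svs(
            [{"chrom": "chr1", "pos": 10, "ref": "A",
              "alts": ["A" + "C" * 600, "A" + "T" * 700],
              "samples": {"s1": SampleCall(gt="1/2", dp=40, ad=(0, 20))}}]
        )
        assert len(out) == 2
        # allele-index collapse: sample is het for each emitted allele
        assert out[0].samples["s1"].gt == "1/0"
        assert out[1].samples["s1"].gt == "0/1"

    def test_snp_excluded_and_symbolic_honoured(self):
        out = normalize_svs(
            [
                {"chrom": "chr1", "pos": 10, "ref": "A", "alts": ["G"]},
                {"chrom": "chr1", "pos": 50, "ref": "A", "alts": ["<INV>"], "end": 650},
                {"chrom": "chr1", "pos": 80, "ref": "ACGTA", "alts": ["TGCAT"]},
            ]
        )
        assert [r.svtype for r in out] == ["INV", "CPX"]

    def test_malformed_allele_names_record(self):
        with pytest.raises(ValueError, match="chr1:10"):
            normalize_svs([{"chrom": "chr1", "pos": 10, "ref": "A", "alts": ["<WEIRD>"]}])


class TestSize:
    def test_deletion_same_in_both_modes(self):
        r = rec(ref="G" * 1530, alt="G", svtype="DEL")
        assert sv_size(r, "reference_allele") == 1530
        assert sv_size(r, "max_allele") == 1530

    def test_insertion_modes_differ(self):
        r = rec(ref="A", alt="A" + "C" * 600, svtype="INS")
        assert sv_size(r, "reference_allele") == 1
        assert sv_size(r, "max_allele") == 601

    def test_symbolic_uses_end_minus_pos(self):
        r = rec(pos=100, ref="A", alt="<INV>", svtype="INV", end=700)
        assert sv_size(r) == 600


class TestOMConversion:
    def om(self, **kw):
        base = dict(chrom="chr1", start=10_000, end=12_000, svtype="DEL",
                    ci_start_lo=9_500, ci_start_hi=10_200,
                    ci_end_lo=11_900, ci_end_hi=12_500, sample="om1")
        base.update(kw)
        return OMRecord(**base)

    def test_outermost_ci_plus_pad(self):
        iset = om_to_intervals([self.om()], pad=1000)
        assert iset.records == [("chr1", 8_500, 13_500, "DEL")]

    def test_zero_width_ci(self):
        r = self.om(ci_start_lo=10_000, ci_start_hi=10_000,
                    ci_end_lo=12_000, ci_end_hi=12_000)
        iset = om_to_intervals([r], pad=1000)
        assert iset.records == [("chr1", 9_000, 13_000, "DEL")]

    def test_clamped_at_zero_and_translocations_dropped(self):
        near0 = self.om(start=200, end=900, ci_start_lo=100, ci_end_hi=1_000)
        tra = self.om(svtype="TRA")
        iset = om_to_intervals([near0, tra], pad=1000)
        assert iset.records == [("chr1", 0, 2_000, "DEL")]


class TestMergeSets:
    def test_overlap_coalesced_and_chrom_filtered(self):
        a = IntervalSet.from_intervals([("chr1", 0, 10), ("chrX", 5, 15)])
        b = IntervalSet.from_intervals([("chr1", 5, 20)])
        merged = merge_interval_sets([a, b], keep_sequences=["chr1"])
        assert merged.records == [("chr1", 0, 20, None)]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_per_base_union_oracle(self, trial):
        rng = np.random.default_rng(5000 + trial)
        sets = []
        raw = []
        for _ in range(3):
            ivs = []
            for _ in range(int(rng.integers(1, 20))):
                s = int(rng.integers(0, 95_000))
                e = s + int(rng.integers(1, 5_000))
                ivs.append(("chr1", s, e))
                raw.append((s, e))
            sets.append(IntervalSet.from_intervals(ivs))
        merged = merge_interval_sets(sets)
        assert [(s, e) for _c, s, e, _t in merged.records] == merge_intervals(raw)


def make_callsets(*positions_by_sample, svtype="DEL", size=800):
    out = []
    for i, positions in enumerate(positions_by_sample):
        sample = f"s{i+1}"
        recs = [
            rec(pos=p, ref="G" * (size + 1), alt="G", svtype=svtype)
            for p in positions
        ]
        out.append((sample, recs))
    return out


class TestCluster:
    def test_nearby_same_type_merge_with_support(self):
        clusters = cluster_svs(make_callsets([1000], [1050]))
        assert len(clusters) == 1
        assert clusters[0].support == 2
        assert clusters[0].representative.pos == 1000

    def test_different_types_never_merge(self):
        a = [("s1", [rec(pos=1000, ref="G" * 801, alt="G", svtype="DEL")])]
        b = [("s2", [rec(pos=1010, ref="A", alt="<DUP>", svtype="DUP", end=1810)])]
        clusters = cluster_svs(a + b)
        assert len(clusters) == 2

    def test_single_linkage_chains_consecutive_gaps(self):
        clusters = cluster_svs(make_callsets([1000], [1080], [1160]))
        assert len(clusters) == 1 and clusters[0].support == 3

    def test_size_filter_after_clustering(self):
        clusters = cluster_svs(make_callsets([1000], [1050], size=400))
        assert clusters == []

    def test_translocations_excluded(self):
        tra = [("s1", [rec(pos=1000, ref="A", alt="<TRA>", svtype="TRA", end=5000)])]
        assert cluster_svs(tra) == []

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_single_linkage_oracle(self, trial):
        rng = np.random.default_rng(6000 + trial)
        callsets = make_callsets(
            *[sorted(int(p) for p in rng.integers(0, 20_000, size=rng.integers(1, 15)))
              for _ in range(3)]
        )
        clusters = cluster_svs(callsets, max_dist=100, min_size=500)
        # oracle: graph on records, edge when same type and |Δstart| ≤ 100
        g = nx.Graph()
        items = [(s, r) for s, recs in callsets for r in recs]
        g.add_nodes_from(range(len(items)))
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if (items[i][1].svtype == items[j][1].svtype
                        and abs(items[i][1].pos - items[j][1].pos) <= 100):
                    g.add_edge(i, j)
        expected = sorted(
            min(items[i][1].pos for i in comp) for comp in nx.connected_components(g)
        )
        got = sorted(c.representative.pos for c in clusters)
        assert got == expected

    def test_sample_order_invariance_of_membership(self):
        callsets = make_callsets([1000, 5000], [1050])
        flipped = list(reversed(callsets))
        a = cluster_svs(callsets)
        b = cluster_svs(flipped)
        assert sorted(c.representative.pos for c in a) == sorted(
            c.representative.pos for c in b
        )
        assert sorted(c.support for c in a) == sorted(c.support for c in b)


class TestIntersect:
    def om_targets(self):
        return IntervalSet.from_intervals(
            [("chr1", 5_000, 9_000, "DEL"), ("chr1", 20_000, 22_000, "INS")],
            typed=True,
        )

    def test_typed_matches(self):
        del_in = rec(pos=6_001, ref="G" * 801, alt="G", svtype="DEL")
        ins_in = rec(pos=21_000, ref="A", alt="A" + "C" * 900, svtype="INS")
        del_on_ins = rec(pos=21_000, ref="G" * 801, alt="G", svtype="DEL")
        flags, summary = intersect_by_type(
            [del_in, ins_in, del_on_ins], self.om_targets()
        )
        assert [hit for _r, hit in flags] == [True, True, False]
        assert summary == {"total": 3, "supported": 2, "unsupported": 1}

    def test_untyped_mode_any_overlap(self):
        del_on_ins = rec(pos=21_000, ref="G" * 801, alt="G", svtype="DEL")
        _f, summary = intersect_by_type([del_on_ins], self.om_targets(), typed=False)
        assert summary["supported"] == 1

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_per_base_overlap_oracle(self, trial):
        rng = np.random.default_rng(7000 + trial)
        targets = []
        for _ in range(15):
            s = int(rng.integers(0, 990_000))
            targets.append(("chr1", s, s + int(rng.integers(1, 5_000)), "DEL"))
        iset = IntervalSet.from_intervals(targets, typed=True)
        merged = merge_intervals([(s, e) for _c, s, e, _t in targets])
        svs = [
            rec(pos=int(rng.integers(1, 990_000)), ref="G" * 801, alt="G", svtype="DEL")
            for _ in range(100)
        ]
        flags, _ = intersect_by_type(svs, iset)
        for r, hit in flags:
            s, e = r.interval()
            assert hit == (overlap_length((s, e), merged) > 0)


class TestThreeWay:
    def test_triple_overlap_counted_once_in_triple_category(self):
        a = [rec(pos=1_000, ref="G" * 801, alt="G", svtype="DEL")]
        b = [rec(pos=1_050, ref="G" * 801, alt="G", svtype="DEL")]
        om = IntervalSet.from_intervals([("chr1", 900, 2_000, "DEL")], typed=True)
        counts = three_way_support(a, b, om)
        assert counts["a_b_om"] == 1 and counts["a_only"] == 0
        assert counts["b_a_om"] == 1

    def test_isolated_record_in_exclusive_category(self):
        a = [rec(pos=500_000, ref="G" * 801, alt="G", svtype="DEL")]
        counts = three_way_support(a, [], IntervalSet())
        assert counts["a_only"] == 1

    def test_per_method_categories_sum_to_record_count(self):
        rng = np.random.default_rng(8)
        om = IntervalSet.from_intervals(
            [("chr1", int(s), int(s) + 2_000, "DEL")
             for s in rng.integers(0, 900_000, size=10)],
            typed=True,
        )
        a = [rec(pos=int(p), ref="G" * 801, alt="G", svtype="DEL")
             for p in rng.integers(1, 900_000, size=30)]
        b = [rec(pos=int(p), ref="G" * 801, alt="G", svtype="DEL")
             for p in rng.integers(1, 900_000, size=20)]
        counts = three_way_support(a, b, om)
        assert counts["a_only"] + counts["a_b"] + counts["a_om"] + counts["a_b_om"] == 30
        assert counts["b_only"] + counts["b_a"] + counts["b_om"] + counts["b_a_om"] == 20
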