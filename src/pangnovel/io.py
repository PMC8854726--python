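"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython (soft-masked, 60-column wrap), VCF reading
through cyvcf2; VCF 4.2 writing, BED (0-based half-open), PAF and the
tab-separated optical-map records are small fixed dialects written
directly.  All in-memory coordinates are 0-based half-open; VCF's
1-based positions are converted here and nowhere else.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .segments import AlignmentRecord
from .svtools import OMRecord, SampleCall, SVRecord


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(
    intervals: Iterable[tuple], path: str | Path, extra_cols: bool = True
) -> None:
    """Write (chrom, start, end, *extra) rows as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            cols = list(row) if extra_cols else list(row[:3])
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return out


def gaps_of_sequence(seq: str) -> list[tuple[int, int]]:
    """N-run intervals (0-based half-open) in a sequence."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c in "Nn":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


# ---------------------------------------------------------------- VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_vcf(
    records: Sequence[SVRecord],
    path: str | Path,
    sample_names: Sequence[str] | None = None,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write single-allele records as VCF 4.2 with GT/DP/AD."""
    if sample_names is None:
        names: list[str] = []
        for rec in records:
            for n in rec.sample_order or rec.samples:
                if n not in names:
                    names.append(n)
        sample_names = names
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(sample_names)) + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            info = f"SVTYPE={rec.svtype}"
            if rec.end is not None:
                info += f";END={rec.end}"
            qual = "." if rec.qual is None else f"{rec.qual:.2f}"
            fields = [
                rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, qual, "PASS", info, "GT:DP:AD",
            ]
            for name in sample_names:
                call = rec.samples.get(name)
                if call is None:
                    fields.append("./.:.:.")
                else:
                    dp = "." if call.dp is None else str(call.dp)
                    ad = "." if call.ad is None else f"{call.ad[0]},{call.ad[1]}"
                    fields.append(f"{call.gt}:{dp}:{ad}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> list[dict]:
    """Read a VCF into raw multi-allelic dicts for ``normalize_svs``."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    out = []
    for var in vcf:
        samples = {}
        for i, name in enumerate(sample_names):
            gt = var.genotypes[i] if var.genotypes else [-1, -1, False]
            alleles = gt[:-1]
            gt_str = "/".join("." if a < 0 else str(a) for a in alleles)
            dp = None
            ad = None
            try:
                dp_arr = var.format("DP")
                if dp_arr is not None and dp_arr[i][0] >= 0:
                    dp = int(dp_arr[i][0])
            except KeyError:
                pass
            try:
                ad_arr = var.format("AD")
                if ad_arr is not None and len(ad_arr[i]) >= 2 and ad_arr[i][0] >= 0:
                    ad = (int(ad_arr[i][0]), int(ad_arr[i][1]))
            except KeyError:
                pass
            samples[name] = SampleCall(gt=gt_str, dp=dp, ad=ad)
        out.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alts": list(var.ALT),
                "qual": var.QUAL,
                "end": var.INFO.get("END"),
                "samples": samples,
            }
        )
    return out


# ---------------------------------------------------------------- OM TSV

_OM_COLS = [
    "chrom", "start", "end", "type",
    "ci_start_lo", "ci_start_hi", "ci_end_lo", "ci_end_hi", "sample",
]


def write_om_tsv(records: Iterable[OMRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_OM_COLS)
        for r in records:
            w.writerow(
                [r.chrom, r.start, r.end, r.svtype,
                 r.ci_start_lo, r.ci_start_hi, r.ci_end_lo, r.ci_end_hi, r.sample]
            )


def read_om_tsv(path: str | Path) -> list[OMRecord]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                OMRecord(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    svtype=row["type"],
                    ci_start_lo=int(row["ci_start_lo"]),
                    ci_start_hi=int(row["ci_start_hi"]),
                    ci_end_lo=int(row["ci_end_lo"]),
                    ci_end_hi=int(row["ci_end_hi"]),
                    sample=row.get("sample", ""),
                )
            )
    return out


# ---------------------------------------------------------------- PAF

def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Read pairwise alignments; identity = matches / alignment block length."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                continue
            matches = int(f[9])
            block = int(f[10])
            out.append(
                AlignmentRecord(
                    query=f[0],
                    target=f[5],
                    block_length=block,
                    identity=matches / block if block else 0.0,
                )
            )
    return out
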