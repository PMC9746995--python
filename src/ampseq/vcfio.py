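"""Minimal multi-sample VCF 4.2 writer/reader.

Records carry raw column strings so that write -> parse -> write is
byte-stable; helper functions build canonical FORMAT strings (GT:DP:AD:AR)
from genotype calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

GT_STRINGS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
              "missing": "./."}
FORMAT = "GT:DP:AD:AR"


@dataclass
class VcfRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    info: str  # raw INFO column
    sample_fields: list[str]  # raw per-sample columns, sheet order
    id_: str = "."
    qual: str = "."
    filter_: str = "PASS"

    def line(self) -> str:
        cols = [self.chrom, str(self.pos), self.id_, self.ref, self.alt,
                self.qual, self.filter_, self.info, FORMAT]
        cols.extend(self.sample_fields)
        return "\t".join(cols)


def format_sample_field(genotype: str, depth: int, ad_ref: int, ad_alt: int,
                        allele_ratio: float) -> str:
    gt = GT_STRINGS[genotype]
    ar = "." if genotype == "missing" else f"{allele_ratio:.4f}"
    return f"{gt}:{depth}:{ad_ref},{ad_alt}:{ar}"


def parse_sample_field(field: str) -> tuple[str, int, int, int, Optional[float]]:
    """Inverse of :func:`format_sample_field`; returns
    (genotype, depth, ad_ref, ad_alt, allele_ratio)."""
    gt_s, dp, ad, ar = field.split(":")
    rev = {v: k for k, v in GT_STRINGS.items()}
    ad_ref, ad_alt = (int(x) for x in ad.split(","))
    return (rev[gt_s], int(dp), ad_ref, ad_alt,
            None if ar == "." else float(ar))


def _header(samples: Iterable[str], contigs: Iterable[str]) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=ampseq"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines += [
        '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation: effect|gene|codon_change|aa_change">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">',
        '##FORMAT=<ID=AR,Number=1,Type=Float,Description="Major-allele ratio over the top two alleles">',
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    return lines


def write_vcf(path: Union[str, Path], samples: list[str],
              contigs: list[str], records: list[VcfRecord]) -> None:
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        for line in _header(samples, contigs):
            fh.write(line + "\n")
        for rec in records:
            fh.write(rec.line() + "\n")


def read_vcf(path: Union[str, Path]) -> tuple[list[str], list[str], list[VcfRecord]]:
    """Parse a VCF written by :func:`write_vcf`.

    Returns (samples, contigs, records)."""
    samples: list[str] = []
    contigs: list[str] = []
    records: list[VcfRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##contig=<ID="):
                contigs.append(line[len("##contig=<ID="):-1])
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            cols = line.split("\t")
            records.append(VcfRecord(
                chrom=cols[0], pos=int(cols[1]), id_=cols[2], ref=cols[3],
                alt=cols[4], qual=cols[5], filter_=cols[6], info=cols[7],
                sample_fields=cols[9:],
            ))
    return samples, contigs, records
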