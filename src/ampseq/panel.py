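"""Panel data model and I/O.

An amplicon panel is described by three plain-text files:

* a tab-separated panel table with header
  ``locus_id  gene  chrom  start  end  fwd_primer  rev_primer  length  multiplex_group``
  (coordinates 1-based inclusive, VCF convention);
* a companion FASTA of reference insert sequences, one record per locus,
  spanning the full amplicon primer-to-primer;
* an optional tab-separated CDS segment table
  ``locus_id  cds_start  cds_end  strand  frame  [codon_start]`` where
  ``frame`` is the number of bases to skip before the first complete codon
  and ``codon_start`` anchors literature amino-acid numbering for partial
  genes (defaults to 1).

Known resistance sites ride along in an optional sites table
``locus_id  pos  ref_aa  alt_aa  label``.

Internally offsets are 0-based: insert offset ``o`` of a locus maps to
genomic position ``ref_start + o`` (inserts are stored on the forward
genome strand).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import PLAIN_BASES, is_iupac, match_primer, revcomp


class PanelError(ValueError):
    """Raised when a panel file violates a structural invariant."""


@dataclass(frozen=True)
class CdsSegment:
    start: int  # genomic, 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    frame: int  # bases to skip before the first complete codon
    codon_start: int = 1  # codon number of the first complete codon

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise PanelError(f"bad strand {self.strand!r}")
        if not 0 <= self.frame <= 2:
            raise PanelError(f"frame must be 0-2, got {self.frame}")
        if self.end < self.start:
            raise PanelError("cds segment end < start")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class KnownSite:
    pos: int  # genomic, 1-based
    ref_aa: str
    alt_aa: str
    label: str  # e.g. "A296S"


@dataclass
class AmpliconDef:
    locus_id: str
    gene: str
    chrom: str
    ref_start: int  # 1-based inclusive
    ref_end: int
    fwd_primer: str
    rev_primer: str  # stored 5'->3' in primer orientation (opposite strand)
    declared_length: int
    insert_seq: str
    multiplex_group: int = 1
    cds_segments: list[CdsSegment] = field(default_factory=list)
    known_sites: list[KnownSite] = field(default_factory=list)

    def validate(self, length_range: Optional[tuple[int, int]] = (440, 500)) -> None:
        if self.declared_length != len(self.insert_seq):
            raise PanelError(
                f"{self.locus_id}: declared length {self.declared_length} != "
                f"insert length {len(self.insert_seq)}"
            )
        if self.ref_end - self.ref_start + 1 != self.declared_length:
            raise PanelError(
                f"{self.locus_id}: genomic span "
                f"{self.ref_end - self.ref_start + 1} != declared length"
            )
        if length_range is not None and not (
            length_range[0] <= self.declared_length <= length_range[1]
        ):
            raise PanelError(
                f"{self.locus_id}: amplicon length {self.declared_length} "
                f"outside expected range {length_range}"
            )
        for name, primer in (("fwd", self.fwd_primer), ("rev", self.rev_primer)):
            if not primer or not is_iupac(primer):
                raise PanelError(f"{self.locus_id}: malformed {name} primer {primer!r}")
        if set(self.insert_seq.upper()) - PLAIN_BASES:
            raise PanelError(
                f"{self.locus_id}: insert contains non-A/C/G/T characters"
            )
        ok, n = match_primer(
            self.fwd_primer, self.insert_seq[: len(self.fwd_primer)], 0
        )
        if not ok:
            raise PanelError(
                f"{self.locus_id}: fwd primer does not match insert 5' end "
                f"({n} mismatches)"
            )
        ok, n = match_primer(
            revcomp(self.rev_primer), self.insert_seq[-len(self.rev_primer):], 0
        )
        if not ok:
            raise PanelError(
                f"{self.locus_id}: rev primer (reverse complement) does not "
                f"match insert 3' end ({n} mismatches)"
            )
        prev_end = None
        for seg in self.cds_segments:
            if prev_end is not None and seg.start <= prev_end:
                raise PanelError(
                    f"{self.locus_id}: cds segments overlap or are unsorted"
                )
            prev_end = seg.end

    # -- coordinate helpers -------------------------------------------------

    def offset_to_pos(self, offset: int) -> int:
        return self.ref_start + offset

    def pos_to_offset(self, pos: int) -> int:
        return pos - self.ref_start

    def contains_pos(self, pos: int) -> bool:
        return self.ref_start <= pos <= self.ref_end

    def ref_base(self, pos: int) -> str:
        return self.insert_seq[self.pos_to_offset(pos)]

    @property
    def insert_region(self) -> tuple[int, int]:
        """0-based half-open insert interval between the primers."""
        return len(self.fwd_primer), len(self.insert_seq) - len(self.rev_primer)


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    fwd_barcode: str
    rev_barcode: str
    pool_id: str


class SampleSheet:
    """Sample -> dual 6bp barcode assignment, grouped by pool."""

    BARCODE_LEN = 6

    def __init__(self, entries: Iterable[SampleEntry]):
        self.entries: list[SampleEntry] = list(entries)
        if not self.entries:
            raise PanelError("sample sheet is empty")
        seen_samples: set[str] = set()
        combos: set[tuple[str, str, str]] = set()
        for e in self.entries:
            for bc in (e.fwd_barcode, e.rev_barcode):
                if len(bc) != self.BARCODE_LEN:
                    raise PanelError(
                        f"{e.sample_id}: barcode {bc!r} is not "
                        f"{self.BARCODE_LEN}bp"
                    )
                if set(bc) - PLAIN_BASES:
                    raise PanelError(
                        f"{e.sample_id}: barcode {bc!r} not over A/C/G/T"
                    )
            if e.sample_id in seen_samples:
                raise PanelError(f"duplicate sample id {e.sample_id}")
            seen_samples.add(e.sample_id)
            key = (e.pool_id, e.fwd_barcode, e.rev_barcode)
            if key in combos:
                raise PanelError(
                    f"barcode combination {e.fwd_barcode}/{e.rev_barcode} "
                    f"reused within pool {e.pool_id}"
                )
            combos.add(key)
        self.by_combo: dict[tuple[str, str], SampleEntry] = {}
        for e in self.entries:
            self.by_combo.setdefault((e.fwd_barcode, e.rev_barcode), e)
        self.fwd_barcodes = sorted({e.fwd_barcode for e in self.entries})
        self.rev_barcodes = sorted({e.rev_barcode for e in self.entries})

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def pool_ids(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.pool_id not in out:
                out.append(e.pool_id)
        return out

    def pool_map(self) -> dict[str, str]:
        return {e.sample_id: e.pool_id for e in self.entries}

    def subset(self, pool_id: str) -> "SampleSheet":
        sub = [e for e in self.entries if e.pool_id == pool_id]
        if not sub:
            raise PanelError(f"no samples in pool {pool_id!r}")
        return SampleSheet(sub)


@dataclass
class FilterConfig:
    """Quality and genotyping thresholds used throughout the pipeline."""

    min_base_quality: int = 30
    min_depth: int = 50
    min_allele_depth: int = 10
    hom_ratio_threshold: float = 0.8
    min_mosquitoes: int = 2
    min_pools: int = 2
    barcode_max_mismatch: int = 0
    primer_max_mismatch: int = 2

    def __post_init__(self):
        for name in (
            "min_base_quality",
            "min_depth",
            "min_allele_depth",
            "min_mosquitoes",
            "min_pools",
            "barcode_max_mismatch",
            "primer_max_mismatch",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.5 < self.hom_ratio_threshold <= 1.0:
            raise ValueError("hom_ratio_threshold must lie in (0.5, 1.0]")

    def replace(self, **kw) -> "FilterConfig":
        return dataclasses.replace(self, **kw)


class Panel:
    def __init__(self, amplicons: Iterable[AmpliconDef],
                 length_range: Optional[tuple[int, int]] = (440, 500)):
        self.amplicons: dict[str, AmpliconDef] = {}
        for a in amplicons:
            if a.locus_id in self.amplicons:
                raise PanelError(f"duplicate locus {a.locus_id}")
            a.validate(length_range=length_range)
            self.amplicons[a.locus_id] = a
        if not self.amplicons:
            raise PanelError("no amplicons defined")
        self.length_range = length_range

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons.values())

    def __getitem__(self, locus_id: str) -> AmpliconDef:
        try:
            return self.amplicons[locus_id]
        except KeyError:
            raise PanelError(f"unknown locus {locus_id!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, Panel) and list(self) == list(other)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.amplicons)

    def loci_covering(self, chrom: str, pos: int) -> list[AmpliconDef]:
        return [
            a for a in self if a.chrom == chrom and a.contains_pos(pos)
        ]

    def chroms(self) -> list[str]:
        out: list[str] = []
        for a in self:
            if a.chrom not in out:
                out.append(a.chrom)
        return out


# ---------------------------------------------------------------------------
# file I/O

PANEL_COLUMNS = [
    "locus_id", "gene", "chrom", "start", "end",
    "fwd_primer", "rev_primer", "length", "multiplex_group",
]
CDS_COLUMNS = ["locus_id", "cds_start", "cds_end", "strand", "frame", "codon_start"]
SITES_COLUMNS = ["locus_id", "pos", "ref_aa", "alt_aa", "label"]
SHEET_COLUMNS = ["sample_id", "fwd_barcode", "rev_barcode", "pool_id"]

PathLike = Union[str, Path]


def _read_tsv(path: PathLike, required: list[str]) -> list[dict[str, str]]:
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            return []
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in required if c not in header]
        if missing:
            raise PanelError(f"{path}: missing columns {missing}")
        rows = []
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.rstrip("\n").split("\t")
            rows.append(dict(zip(header, fields)))
        return rows


def parse_panel(panel_file: PathLike, insert_fasta: PathLike,
                cds_file: Optional[PathLike] = None,
                sites_file: Optional[PathLike] = None,
                length_range: Optional[tuple[int, int]] = (440, 500)) -> Panel:
    """Parse and validate a panel from its plain-text description.

    Raises :class:`PanelError` on any invariant violation (missing insert,
    declared-length mismatch, primer not matching insert ends, malformed
    IUPAC characters, ...).
    """
    inserts = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(insert_fasta), "fasta")}
    rows = _read_tsv(panel_file, PANEL_COLUMNS[:-1])  # multiplex_group optional
    if not rows:
        raise PanelError("no amplicons defined")

    cds_by_locus: dict[str, list[CdsSegment]] = {}
    if cds_file is not None:
        for r in _read_tsv(cds_file, CDS_COLUMNS[:-1]):
            cds_by_locus.setdefault(r["locus_id"], []).append(
                CdsSegment(
                    start=int(r["cds_start"]), end=int(r["cds_end"]),
                    strand=r["strand"], frame=int(r["frame"]),
                    codon_start=int(r.get("codon_start", 1) or 1),
                )
            )
    sites_by_locus: dict[str, list[KnownSite]] = {}
    if sites_file is not None:
        for r in _read_tsv(sites_file, SITES_COLUMNS):
            sites_by_locus.setdefault(r["locus_id"], []).append(
                KnownSite(pos=int(r["pos"]), ref_aa=r["ref_aa"],
                          alt_aa=r["alt_aa"], label=r["label"])
            )

    amplicons = []
    for r in rows:
        locus = r["locus_id"]
        if locus not in inserts:
            raise PanelError(f"missing insert sequence for locus {locus}")
        amplicons.append(AmpliconDef(
            locus_id=locus,
            gene=r["gene"],
            chrom=r["chrom"],
            ref_start=int(r["start"]),
            ref_end=int(r["end"]),
            fwd_primer=r["fwd_primer"].upper(),
            rev_primer=r["rev_primer"].upper(),
            declared_length=int(r["length"]),
            insert_seq=inserts[locus],
            multiplex_group=int(r.get("multiplex_group", 1) or 1),
            cds_segments=sorted(cds_by_locus.get(locus, []),
                                key=lambda s: s.start),
            known_sites=sites_by_locus.get(locus, []),
        ))
    return Panel(amplicons, length_range=length_range)


def write_panel(panel: Panel, panel_file: PathLike, insert_fasta: PathLike,
                cds_file: Optional[PathLike] = None,
                sites_file: Optional[PathLike] = None) -> None:
    """Write a panel back to its plain-text representation (round-trips
    through :func:`parse_panel`)."""
    with open(panel_file, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for a in panel:
            fh.write("\t".join(map(str, [
                a.locus_id, a.gene, a.chrom, a.ref_start, a.ref_end,
                a.fwd_primer, a.rev_primer, a.declared_length,
                a.multiplex_group,
            ])) + "\n")
    records = [SeqRecord(Seq(a.insert_seq), id=a.locus_id, description="")
               for a in panel]
    SeqIO.write(records, str(insert_fasta), "fasta")
    if cds_file is not None:
        with open(cds_file, "w") as fh:
            fh.write("\t".join(CDS_COLUMNS) + "\n")
            for a in panel:
                for s in a.cds_segments:
                    fh.write("\t".join(map(str, [
                        a.locus_id, s.start, s.end, s.strand, s.frame,
                        s.codon_start,
                    ])) + "\n")
    if sites_file is not None:
        with open(sites_file, "w") as fh:
            fh.write("\t".join(SITES_COLUMNS) + "\n")
            for a in panel:
                for k in a.known_sites:
                    fh.write("\t".join(map(str, [
                        a.locus_id, k.pos, k.ref_aa, k.alt_aa, k.label,
                    ])) + "\n")


def parse_sample_sheet(path: PathLike) -> SampleSheet:
    rows = _read_tsv(path, SHEET_COLUMNS)
    return SampleSheet(
        SampleEntry(r["sample_id"], r["fwd_barcode"].upper(),
                    r["rev_barcode"].upper(), r["pool_id"])
        for r in rows
    )


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SHEET_COLUMNS) + "\n")
        for e in sheet:
            fh.write(f"{e.sample_id}\t{e.fwd_barcode}\t{e.rev_barcode}"
                     f"\t{e.pool_id}\n")
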