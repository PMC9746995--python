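"""Synthetic pool simulator.

Generates barcoded, multiplexed paired-end amplicon pools with known
per-sample diploid genotypes, substitution sequencing error and barcode
mistagging, so every downstream stage is testable without real data.

Read structure on both mates is ``5'-[6bp barcode][primer][insert...]-3'``
(mate 2 reads from the reverse end of the amplicon).  The fragment is the
full amplicon — no shearing — so 250bp mates overlap in the middle of
~470bp amplicons.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .iupac import concretize, revcomp
from .panel import (AmpliconDef, CdsSegment, FilterConfig, KnownSite, Panel,
                    PanelError, SampleEntry, SampleSheet)

GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class GenotypeEntry:
    sample_id: str
    locus_id: str
    insert_offset: int  # 0-based within insert
    ref_allele: str
    alt_allele: str
    genotype: str  # hom_ref | het | hom_alt


@dataclass
class GenotypeSpec:
    entries: list[GenotypeEntry] = field(default_factory=list)

    def validate(self, panel: Panel, sheet: SampleSheet) -> None:
        samples = set(sheet.sample_ids)
        for e in self.entries:
            if e.sample_id not in samples:
                raise ValueError(f"unknown sample {e.sample_id!r}")
            amp = panel[e.locus_id]
            lo, hi = amp.insert_region
            if not lo <= e.insert_offset < hi:
                raise ValueError(
                    f"{e.locus_id}:{e.insert_offset}: site inside a primer "
                    f"region or outside the insert"
                )
            if amp.insert_seq[e.insert_offset] != e.ref_allele:
                raise ValueError(
                    f"{e.locus_id}:{e.insert_offset}: ref allele "
                    f"{e.ref_allele!r} does not match insert"
                )
            if e.genotype not in GENOTYPES:
                raise ValueError(f"bad genotype {e.genotype!r}")

    def for_sample_locus(self, sample_id: str,
                         locus_id: str) -> list[GenotypeEntry]:
        return [e for e in self.entries
                if e.sample_id == sample_id and e.locus_id == locus_id]


@dataclass
class SimConfig:
    coverage: int = 100  # read pairs per (sample, amplicon)
    read_length: int = 250
    base_error_rate: float = 0.0
    mistag_rate: float = 0.0
    quality_model: str = "constant"  # "constant" (Q37) or "two_level"
    seed: int = 0
    total_pairs: Optional[int] = None  # overrides coverage; pairs drawn
    # multinomially over all (sample, amplicon) products
    efficiency: Optional[dict[str, float]] = None  # per-locus weight

    HIGH_Q = 37
    LOW_Q = 20

    def __post_init__(self):
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be in [0,1]")
        if not 0.0 <= self.mistag_rate <= 1.0:
            raise ValueError("mistag_rate must be in [0,1]")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.quality_model not in ("constant", "two_level"):
            raise ValueError("quality_model must be 'constant' or 'two_level'")


@dataclass(frozen=True)
class SimReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    sample_id: str
    locus_id: str
    haplotype: str  # comma-joined emitted alleles at spec sites, "*" if none
    mistag: bool


@dataclass
class SimResult:
    reads: list[SimReadPair]
    truth: list[TruthRow]
    pool_id: str

    def write(self, prefix: Union[str, Path]) -> tuple[Path, Path, Path]:
        """Write R1/R2 gzip FASTQ plus the tab-separated truth table."""
        prefix = Path(prefix)
        r1_path = prefix.with_name(prefix.name + ".R1.fastq.gz")
        r2_path = prefix.with_name(prefix.name + ".R2.fastq.gz")
        truth_path = prefix.with_name(prefix.name + ".truth.tsv")
        with gzip.open(r1_path, "wt") as r1, gzip.open(r2_path, "wt") as r2:
            for rp in self.reads:
                r1.write(f"@{rp.read_id}/1\n{rp.seq1}\n+\n{rp.qual1}\n")
                r2.write(f"@{rp.read_id}/2\n{rp.seq2}\n+\n{rp.qual2}\n")
        with open(truth_path, "w") as fh:
            fh.write("read_id\tsample_id\tlocus_id\thaplotype\tmistag\n")
            for t in self.truth:
                fh.write(f"{t.read_id}\t{t.sample_id}\t{t.locus_id}"
                         f"\t{t.haplotype}\t{int(t.mistag)}\n")
        return r1_path, r2_path, truth_path

    def pairs(self) -> Iterable[tuple[tuple[str, str, str], tuple[str, str, str]]]:
        """Yield mate-synchronized (id, seq, qual) tuples for demultiplexing."""
        for rp in self.reads:
            yield ((rp.read_id + "/1", rp.seq1, rp.qual1),
                   (rp.read_id + "/2", rp.seq2, rp.qual2))


def _phred_string(n: int, q: int) -> str:
    return chr(q + 33) * n


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator,
                  cfg: SimConfig) -> tuple[str, str]:
    """Return (mutated sequence, quality string)."""
    n = len(seq)
    if rate <= 0.0:
        return seq, _phred_string(n, cfg.HIGH_Q)
    hits = np.nonzero(rng.random(n) < rate)[0]
    if hits.size == 0:
        return seq, _phred_string(n, cfg.HIGH_Q)
    chars = list(seq)
    quals = [chr(cfg.HIGH_Q + 33)] * n
    low = chr(cfg.LOW_Q + 33)
    for i in hits:
        original = chars[i]
        choices = [b for b in "ACGT" if b != original]
        chars[i] = choices[rng.integers(0, len(choices))]
        if cfg.quality_model == "two_level":
            quals[i] = low
    return "".join(chars), "".join(quals)


def simulate_pool(panel: Panel, sheet: SampleSheet, spec: GenotypeSpec,
                  cfg: SimConfig, pool_id: Optional[str] = None) -> SimResult:
    """Simulate one sequencing pool.

    ``sheet`` may contain several pools; ``pool_id`` selects one (required in
    that case).  Identical seeds give byte-identical output.
    """
    if pool_id is None:
        pools = sheet.pool_ids
        if len(pools) != 1:
            raise ValueError("sheet spans several pools; pass pool_id")
        pool_id = pools[0]
    pool_sheet = sheet.subset(pool_id)
    spec.validate(panel, sheet)

    rng = np.random.default_rng(cfg.seed)

    combos = set(pool_sheet.by_combo)
    invalid_combos = [(f, r) for f in pool_sheet.fwd_barcodes
                      for r in pool_sheet.rev_barcodes if (f, r) not in combos]
    if cfg.mistag_rate > 0 and not invalid_combos:
        raise ValueError(
            "mistag_rate > 0 but every barcode combination is assigned; "
            "no mistag is representable"
        )

    products = [(entry, amp) for entry in pool_sheet for amp in panel]
    if cfg.total_pairs is not None:
        weights = np.array([
            (cfg.efficiency or {}).get(amp.locus_id, 1.0)
            for _, amp in products
        ], dtype=float)
        counts = rng.multinomial(cfg.total_pairs, weights / weights.sum())
    else:
        counts = np.full(len(products), cfg.coverage, dtype=int)
        if cfg.efficiency:
            counts = np.array([
                int(round(cfg.coverage
                          * (cfg.efficiency or {}).get(amp.locus_id, 1.0)))
                for _, amp in products
            ])

    site_cache: dict[tuple[str, str], list[GenotypeEntry]] = {}
    reads: list[SimReadPair] = []
    truth: list[TruthRow] = []
    ins_len = cfg.read_length - SampleSheet.BARCODE_LEN

    for (entry, amp), n_pairs in zip(products, counts):
        key = (entry.sample_id, amp.locus_id)
        if key not in site_cache:
            site_cache[key] = spec.for_sample_locus(*key)
        sites = site_cache[key]
        insert = amp.insert_seq
        for i in range(int(n_pairs)):
            if sites:
                hap = list(insert)
                emitted = []
                for s in sites:
                    if s.genotype == "hom_ref":
                        allele = s.ref_allele
                    elif s.genotype == "hom_alt":
                        allele = s.alt_allele
                    else:
                        allele = (s.alt_allele if rng.random() < 0.5
                                  else s.ref_allele)
                    hap[s.insert_offset] = allele
                    emitted.append(allele)
                hap_seq = "".join(hap)
                hap_label = ",".join(emitted)
            else:
                hap_seq = insert
                hap_label = "*"

            mistag = cfg.mistag_rate > 0 and rng.random() < cfg.mistag_rate
            if mistag:
                fb, rb = invalid_combos[rng.integers(0, len(invalid_combos))]
            else:
                fb, rb = entry.fwd_barcode, entry.rev_barcode

            seq1 = fb + hap_seq[:ins_len]
            seq2 = rb + revcomp(hap_seq)[:ins_len]
            seq1, qual1 = _apply_errors(seq1, cfg.base_error_rate, rng, cfg)
            seq2, qual2 = _apply_errors(seq2, cfg.base_error_rate, rng, cfg)

            read_id = f"{pool_id}:{entry.sample_id}:{amp.locus_id}:{i:05d}"
            reads.append(SimReadPair(read_id, seq1, qual1, seq2, qual2))
            truth.append(TruthRow(read_id, entry.sample_id, amp.locus_id,
                                  hap_label, mistag))
    return SimResult(reads=reads, truth=truth, pool_id=pool_id)


def pool_depth_summary(truth: Sequence[TruthRow]) -> dict[tuple[str, str], int]:
    """Per-amplicon (sample, locus) read-pair counts; values sum to the total
    number of simulated pairs.  Empty truth (coverage 0) gives no entries."""
    counts: dict[tuple[str, str], int] = {}
    for row in truth:
        key = (row.sample_id, row.locus_id)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Built-in demo panel: synthetic 444-498bp inserts with the published
# 11-locus primer set grafted at the ends, plausible coordinates, CDS
# segments anchored so that the known resistance codons carry their
# literature numbering.  All tests run from this without any download.

_TABLE1 = [
    # locus_id, gene, chrom, start, fwd, rev, length, multiplex
    ("DomainI", "vgsc", "3", 315900000,
     "TTTCGTCTAATGACCCAAGA", "ARAGAWTTCGCTCACCCG", 464, 1),
    ("DomainIIIExon35", "vgsc", "3", 315939000,
     "GGATCCAGATCATGAACGAY", "GATGATCATGTCGAACTTCT", 480, 1),
    ("Rdl_Aeg", "rdl", "2", 41847560,
     "CCAACCGATGTATCTTCTTC", "CTGGTTATTTGTACAAGTAGCA", 498, 1),
    ("Ace1", "ace-1", "3", 161500000,
     "TCGCYTRGCCGAAGCCGT", "CASGTGAARTGATAATCTCCSAC", 468, 1),
    ("DomainIIS4", "vgsc", "3", 315915000,
     "TCTAGATTTAGYGACTCCAR", "TACCGATGTAGTTCTTGCC", 444, 2),
    ("DomainII", "vgsc", "3", 315905000,
     "ACTCRTTCATGATCGTGTTC", "GACTTGATCCAGTTGGAGA", 498, 2),
    ("DomainIIIExon36", "vgsc", "3", 315925000,
     "GTGTCATCATCGACAACTTC", "CACACCTAAAATGGACAGGA", 489, 2),
    ("DomainIV", "vgsc", "3", 315945000,
     "GCGATCTSATCGAGAAGTA", "ATGCTAGCAARTACGTGATG", 495, 2),
    ("DomainIIExon26", "vgsc", "3", 315910000,
     "TCACCTTATGCTAAGACTTCA", "GGGAAACAATTTGTCGGTTA", 494, 3),
    ("DomainIIIExon33_34", "vgsc", "3", 315939400,
     "AACTCTCTATTCCCGCTTG", "GCAGATCATTCGTAACAAGT", 469, 3),
    ("DomainIVS6", "vgsc", "3", 315950000,
     "TGTTGGACGGTATCATCAA", "CCTCGATCGGRTTACCTTT", 456, 3),
]

# Known-site positions sit at insert offsets covered by both 250bp mates
# (the centre ~10bp of a 498bp amplicon is unreadable at 2x250 with 6bp
# barcodes, so sites must avoid it).
RDL_SITE_POS = 41847790  # codon 296 first base; GCA (Ala) -> TCA (Ser)
ACE1_SITE_POS = 161500240  # codon 119 first base; GGC (Gly) -> AGC (Ser)


def _random_insert(rng: np.random.Generator, length: int,
                   fwd: str, rev: str) -> list[str]:
    body = _BASES[rng.integers(0, 4, size=length)].astype("U1")
    chars = list("".join(body))
    f = concretize(fwd)
    r = revcomp(concretize(rev))
    chars[: len(f)] = list(f)
    chars[length - len(r):] = list(r)
    return chars


def demo_panel(seed: int = 7) -> Panel:
    """The 11-locus demonstration panel on synthetic reference inserts."""
    rng = np.random.default_rng(seed)
    inserts: dict[str, list[str]] = {}
    defs = {row[0]: row for row in _TABLE1}
    for locus_id, gene, chrom, start, fwd, rev, length, mp in _TABLE1:
        inserts[locus_id] = _random_insert(rng, length, fwd, rev)

    # Force the known-site codons.
    rdl = inserts["Rdl_Aeg"]
    off = RDL_SITE_POS - defs["Rdl_Aeg"][3]
    rdl[off:off + 3] = list("GCA")
    ace = inserts["Ace1"]
    off = ACE1_SITE_POS - defs["Ace1"][3]
    ace[off:off + 3] = list("GGC")

    # DomainIIIExon33_34 genuinely overlaps DomainIIIExon35: copy the shared
    # genomic window so both amplicons agree outside their grafted primers.
    e35_start = defs["DomainIIIExon35"][3]
    e33_start = defs["DomainIIIExon33_34"][3]
    e35 = inserts["DomainIIIExon35"]
    e33 = inserts["DomainIIIExon33_34"]
    e35_end = e35_start + len(e35) - 1
    fwd_len = len(defs["DomainIIIExon33_34"][4])
    for o in range(fwd_len, e35_end - e33_start + 1):
        e33[o] = e35[e33_start + o - e35_start]

    cds: dict[str, list[CdsSegment]] = {}
    sites: dict[str, list[KnownSite]] = {}
    cds["Rdl_Aeg"] = [CdsSegment(RDL_SITE_POS - 99, RDL_SITE_POS + 98,
                                 "+", 0, codon_start=263)]
    sites["Rdl_Aeg"] = [KnownSite(RDL_SITE_POS, "A", "S", "A296S")]
    cds["Ace1"] = [CdsSegment(ACE1_SITE_POS - 90, ACE1_SITE_POS + 89,
                              "+", 0, codon_start=89)]
    sites["Ace1"] = [KnownSite(ACE1_SITE_POS, "G", "S", "G119S")]
    for locus_id, gene, chrom, start, fwd, rev, length, mp in _TABLE1:
        if locus_id in ("Rdl_Aeg", "Ace1"):
            continue
        cds[locus_id] = [CdsSegment(start + 100, start + 300, "+", 0,
                                    codon_start=900)]

    amplicons = []
    for locus_id, gene, chrom, start, fwd, rev, length, mp in _TABLE1:
        amplicons.append(AmpliconDef(
            locus_id=locus_id, gene=gene, chrom=chrom,
            ref_start=start, ref_end=start + length - 1,
            fwd_primer=fwd, rev_primer=rev,
            declared_length=length,
            insert_seq="".join(inserts[locus_id]),
            multiplex_group=mp,
            cds_segments=cds.get(locus_id, []),
            known_sites=sites.get(locus_id, []),
        ))
    return Panel(amplicons)


def _distant_barcodes(n: int, rng: np.random.Generator,
                      min_dist: int = 3) -> list[str]:
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not generate barcode set")
        cand = "".join(_BASES[rng.integers(0, 4, size=6)].astype("U1"))
        if all(sum(a != b for a, b in zip(cand, prev)) >= min_dist
               for prev in out):
            out.append(cand)
    return out


def demo_sheet(samples_per_pool: int = 20, n_pools: int = 1,
               seed: int = 11) -> SampleSheet:
    """Sample sheet with one unique (fwd, rev) barcode pair per mosquito.

    Forward and reverse barcode sets have pairwise Hamming distance >= 3 so
    single-mismatch barcode matching stays unambiguous; the same barcode
    scheme is reused in every pool.
    """
    rng = np.random.default_rng(seed)
    codes = _distant_barcodes(2 * samples_per_pool, rng)
    fwd, rev = codes[:samples_per_pool], codes[samples_per_pool:]
    entries = []
    k = 0
    for p in range(1, n_pools + 1):
        for i in range(samples_per_pool):
            k += 1
            entries.append(SampleEntry(
                sample_id=f"S{k:03d}",
                fwd_barcode=fwd[i], rev_barcode=rev[i],
                pool_id=f"P{p}",
            ))
    return SampleSheet(entries)


SPEC_COLUMNS = ["sample_id", "locus_id", "insert_offset", "ref_allele",
                "alt_allele", "genotype"]


def read_genotype_spec(path: Union[str, Path]) -> GenotypeSpec:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            r = dict(zip(header, line.rstrip("\n").split("\t")))
            entries.append(GenotypeEntry(
                r["sample_id"], r["locus_id"], int(r["insert_offset"]),
                r["ref_allele"], r["alt_allele"], r["genotype"]))
    return GenotypeSpec(entries)


def write_genotype_spec(spec: GenotypeSpec, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SPEC_COLUMNS) + "\n")
        for e in spec.entries:
            fh.write(f"{e.sample_id}\t{e.locus_id}\t{e.insert_offset}"
                     f"\t{e.ref_allele}\t{e.alt_allele}\t{e.genotype}\n")


def random_genotype_spec(panel: Panel, sheet: SampleSheet,
                         site_freqs: dict[tuple[str, int], float],
                         seed: int = 0,
                         alt_of: Optional[dict[tuple[str, int], str]] = None,
                         ) -> GenotypeSpec:
    """Draw Hardy-Weinberg genotypes for every sample at the given sites.

    ``site_freqs`` maps (locus_id, insert_offset) to the alternate allele
    frequency; genotypes are drawn hom_ref/het/hom_alt with probabilities
    (1-p)^2, 2p(1-p), p^2 per sample.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for (locus_id, offset), p in site_freqs.items():
        amp = panel[locus_id]
        ref = amp.insert_seq[offset]
        if alt_of and (locus_id, offset) in alt_of:
            alt = alt_of[(locus_id, offset)]
        else:
            alt = {"A": "T", "C": "A", "G": "T", "T": "C"}[ref]
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
        for e in sheet:
            gt = GENOTYPES[rng.choice(3, p=probs)]
            entries.append(GenotypeEntry(e.sample_id, locus_id, offset,
                                         ref, alt, gt))
    return GenotypeSpec(entries)
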