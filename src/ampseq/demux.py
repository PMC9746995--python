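"""Demultiplexing of pooled read pairs to (sample, amplicon) read groups.

A pair is assigned iff (i) the first 6 bases of each mate match a known
barcode within ``barcode_max_mismatch``, (ii) the (forward, reverse)
combination exists in the sample sheet, and (iii) the bases after the
barcode match exactly one amplicon's primer within ``primer_max_mismatch``
(IUPAC-aware) on both mates.  Pairs with valid individual barcodes whose
combination is absent from the sheet are mistags and are discarded; all
other failures are counted unmatched.  Both read orientations are tried.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .iupac import match_primer
from .panel import AmpliconDef, FilterConfig, Panel, PanelError, SampleSheet

Read = tuple[str, str, str]  # (id, sequence, quality)
BARCODE_LEN = SampleSheet.BARCODE_LEN


@dataclass(frozen=True)
class TrimmedPair:
    """A read pair assigned to one (sample, locus), technical sequence
    removed and orientation normalized (mate 1 is the forward read)."""
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class DemuxStats:
    total_pairs: int = 0
    assigned: int = 0
    mistag: int = 0
    unmatched: int = 0
    per_sample_per_locus: dict[tuple[str, str], int] = field(default_factory=dict)

    def check(self) -> None:
        if self.assigned + self.mistag + self.unmatched != self.total_pairs:
            raise AssertionError("demux counts do not conserve total pairs")
        if min(self.total_pairs, self.assigned, self.mistag,
               self.unmatched, 0) < 0:
            raise AssertionError("negative demux count")

    def to_tsv(self) -> str:
        lines = ["metric\tvalue",
                 f"total_pairs\t{self.total_pairs}",
                 f"assigned\t{self.assigned}",
                 f"mistag\t{self.mistag}",
                 f"unmatched\t{self.unmatched}",
                 "", "sample_id\tlocus_id\tpairs"]
        for (s, l), n in sorted(self.per_sample_per_locus.items()):
            lines.append(f"{s}\t{l}\t{n}")
        return "\n".join(lines) + "\n"


def _barcode_lookup(prefix: str, barcodes: Sequence[str],
                    max_mismatch: int) -> Optional[str]:
    """Best-matching barcode within max_mismatch; None if absent or tied."""
    if max_mismatch == 0:
        return prefix if prefix in barcodes else None
    best, best_d, ties = None, max_mismatch + 1, 0
    for bc in barcodes:
        d = sum(a != b for a, b in zip(prefix, bc))
        if d < best_d:
            best, best_d, ties = bc, d, 1
        elif d == best_d:
            ties += 1
    if best is not None and ties == 1:
        return best
    return None


def _primer_candidates(seq: str, panel: Panel, which: str,
                       max_mismatch: int) -> set[str]:
    """Locus ids whose fwd/rev primer matches ``seq`` just after the
    barcode."""
    out = set()
    for amp in panel:
        primer = amp.fwd_primer if which == "fwd" else amp.rev_primer
        window = seq[BARCODE_LEN:BARCODE_LEN + len(primer)]
        if len(window) < len(primer):
            continue
        ok, _ = match_primer(primer, window, max_mismatch)
        if ok:
            out.add(amp.locus_id)
    return out


def trim_technical(read: tuple[str, str], amplicon: AmpliconDef,
                   which: str) -> tuple[str, str]:
    """Remove the 6bp barcode and the matched primer from the 5' end of one
    mate.  ``which`` selects the forward or reverse primer."""
    seq, qual = read
    primer = amplicon.fwd_primer if which == "fwd" else amplicon.rev_primer
    n = BARCODE_LEN + len(primer)
    if n > len(seq):
        raise ValueError("trim longer than read")
    return seq[n:], qual[n:]


def _classify(seq_f: str, seq_r: str, panel: Panel, sheet: SampleSheet,
              cfg: FilterConfig):
    """Classify one orientation.  Returns ("assigned", sample, locus),
    ("mistag",) or ("unmatched",)."""
    fb = _barcode_lookup(seq_f[:BARCODE_LEN], sheet.fwd_barcodes,
                         cfg.barcode_max_mismatch)
    rb = _barcode_lookup(seq_r[:BARCODE_LEN], sheet.rev_barcodes,
                         cfg.barcode_max_mismatch)
    if fb is None or rb is None:
        return ("unmatched",)
    entry = sheet.by_combo.get((fb, rb))
    if entry is None:
        return ("mistag",)
    fwd_hits = _primer_candidates(seq_f, panel, "fwd", cfg.primer_max_mismatch)
    rev_hits = _primer_candidates(seq_r, panel, "rev", cfg.primer_max_mismatch)
    common = fwd_hits & rev_hits
    if len(common) != 1:
        # no primer, ambiguous, or mates supporting different amplicons
        return ("unmatched",)
    return ("assigned", entry.sample_id, next(iter(common)))


def demultiplex(
    pairs: Iterable[tuple[Read, Read]],
    panel: Panel,
    sheet: SampleSheet,
    cfg: Optional[FilterConfig] = None,
) -> tuple[dict[tuple[str, str], list[TrimmedPair]], DemuxStats]:
    """Partition mate-synchronized read pairs into per-(sample, locus)
    trimmed read groups.

    The partition is exhaustive and exclusive:
    ``assigned + mistag + unmatched == total_pairs``.
    """
    if cfg is None:
        cfg = FilterConfig()
    if len(sheet) == 0:
        raise PanelError("empty sample sheet")
    groups: dict[tuple[str, str], list[TrimmedPair]] = {}
    stats = DemuxStats()
    for (id1, seq1, qual1), (id2, seq2, qual2) in pairs:
        if id1.split("/")[0].split()[0] != id2.split("/")[0].split()[0]:
            raise ValueError(f"desynchronized mates: {id1!r} vs {id2!r}")
        stats.total_pairs += 1
        seq1, seq2 = seq1.upper(), seq2.upper()
        verdict = _classify(seq1, seq2, panel, sheet, cfg)
        swapped = False
        if verdict[0] != "assigned":
            alt = _classify(seq2, seq1, panel, sheet, cfg)
            if alt[0] == "assigned":
                verdict, swapped = alt, True
            elif verdict[0] != "mistag" and alt[0] == "mistag":
                verdict = alt
        if verdict[0] == "assigned":
            _, sample_id, locus_id = verdict
            amp = panel[locus_id]
            if swapped:
                f_read, r_read = (seq2, qual2), (seq1, qual1)
            else:
                f_read, r_read = (seq1, qual1), (seq2, qual2)
            try:
                t1, q1 = trim_technical(f_read, amp, "fwd")
                t2, q2 = trim_technical(r_read, amp, "rev")
            except ValueError:
                stats.unmatched += 1
                continue
            stats.assigned += 1
            key = (sample_id, locus_id)
            groups.setdefault(key, []).append(
                TrimmedPair(id1.split("/")[0].split()[0], t1, q1, t2, q2))
            stats.per_sample_per_locus[key] = (
                stats.per_sample_per_locus.get(key, 0) + 1)
        elif verdict[0] == "mistag":
            stats.mistag += 1
        else:
            stats.unmatched += 1
    stats.check()
    return groups, stats


# -- file plumbing ----------------------------------------------------------

def _open_maybe_gz(path: Union[str, Path]):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def fastq_pairs(r1_path: Union[str, Path],
                r2_path: Union[str, Path]) -> Iterator[tuple[Read, Read]]:
    """Stream mate-synchronized (id, seq, qual) tuples from two FASTQ files
    (gzip-aware)."""
    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            yield (t1, s1, q1), (t2, s2, q2)


def demultiplex_files(r1_path, r2_path, panel, sheet, cfg=None):
    return demultiplex(fastq_pairs(r1_path, r2_path), panel, sheet, cfg)


def write_groups(groups: dict[tuple[str, str], list[TrimmedPair]],
                 out_dir: Union[str, Path]) -> list[Path]:
    """Write per-(sample, locus) FASTQ files named
    ``<sample>.<locus>.R{1,2}.fastq.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (sample, locus), pairs in sorted(groups.items()):
        for mate in (1, 2):
            path = out_dir / f"{sample}.{locus}.R{mate}.fastq.gz"
            with gzip.open(path, "wt") as fh:
                for p in pairs:
                    seq = p.seq1 if mate == 1 else p.seq2
                    qual = p.qual1 if mate == 1 else p.qual2
                    fh.write(f"@{p.read_id}/{mate}\n{seq}\n+\n{qual}\n")
            written.append(path)
    return written
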