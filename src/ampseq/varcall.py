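"""Per-sample alignment, quality-filtered pileup and allele-ratio diploid
genotyping.

Alignment is glocal: global in the read, free end-gaps on the reference
insert.  Scoring is match +1, mismatch -1, and a gap of length k costs
4 + k (open 4, extend 1 per gapped base).  Because trimmed amplicon reads
have a known expected placement (mate 1 starts right after the forward
primer, mate 2 ends right before the reverse primer), the pipeline first
evaluates that ungapped placement and only falls back to the full dynamic
program when it looks wrong.

Overlapping mate bases at the same insert position are counted once per
fragment, keeping the higher-quality base, so depth is not double-counted
on ~470bp amplicons sequenced with 250bp pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

from .demux import TrimmedPair
from .iupac import revcomp
from .panel import AmpliconDef, FilterConfig, Panel

NEG_INF = float("-inf")

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, 4, 1

# Pileup allele keys: a plain base string for substitutions, ("D", k) for a
# k-base deletion anchored at the column, ("I", seq) for an insertion of
# ``seq`` after the column.  Indels are left-aligned.
Allele = Union[str, tuple[str, object]]


@dataclass
class Alignment:
    read_id: str
    locus_id: str
    insert_start: int  # 0-based offset on the insert
    ops: list[tuple[str, int]]  # runs of M (match/mismatch), I, D
    seq: str  # read in insert orientation
    quals: Sequence[int]  # per-base phred scores, same orientation
    score: int = 0

    def __post_init__(self):
        consumed = sum(n for op, n in self.ops if op in ("M", "I"))
        if consumed != len(self.seq):
            raise ValueError("operations do not consume the read exactly")

    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in ("M", "D"))

    def aligned_bases(self) -> Iterator[tuple[int, str, int]]:
        """Yield (insert_offset, base, phred) for every M-aligned base."""
        o, r = self.insert_start, 0
        for op, n in self.ops:
            if op == "M":
                for k in range(n):
                    yield o + k, self.seq[r + k], self.quals[r + k]
                o += n
                r += n
            elif op == "D":
                o += n
            else:
                r += n

    def indels(self, insert: str) -> Iterator[tuple[int, Allele, int]]:
        """Yield (anchor_offset, allele_key, phred) for every indel,
        left-aligned with a VCF-style anchor base before the event."""
        o, r = self.insert_start, 0
        for op, n in self.ops:
            if op == "M":
                o += n
                r += n
            elif op == "D":
                start = o
                while start > 0 and insert[start - 1] == insert[start + n - 1]:
                    start -= 1
                q = self.quals[r - 1] if r > 0 else (
                    self.quals[r] if r < len(self.quals) else 0)
                yield start - 1, ("D", n), q
                o += n
            else:  # I
                ins = self.seq[r:r + n]
                start = o
                while start > 0 and insert[start - 1] == ins[-1]:
                    ins = insert[start - 1] + ins[:-1]
                    start -= 1
                q = min(self.quals[r:r + n]) if n else 0
                yield start - 1, ("I", ins), q
                r += n


def glocal_align(read: str, insert: str, quals: Optional[Sequence[int]] = None,
                 read_id: str = "", locus_id: str = "") -> Alignment:
    """Optimal glocal alignment of ``read`` against ``insert``.

    The read is aligned end to end; leading/trailing unaligned reference is
    free.  Ties break to the leftmost placement, then fewest gaps (via a
    deterministic traceback preference M > D > I).
    """
    if not read:
        raise ValueError("empty read")
    if len(read) > len(insert):
        raise ValueError("read longer than insert")
    m, n = len(read), len(insert)
    if quals is None:
        quals = [40] * m

    # M/X/Y: alignment ends in match, insertion (read gap), deletion.
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    X = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0
    open_cost = GAP_OPEN + GAP_EXTEND
    for i in range(1, m + 1):
        ri = read[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Xi[0] = max(Mp[0] - open_cost, Xp[0] - GAP_EXTEND)
        for j in range(1, n + 1):
            s = MATCH if ri == insert[j - 1] else MISMATCH
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] - open_cost, Xp[j] - GAP_EXTEND,
                        Yp[j] - open_cost)
            Yi[j] = max(Mi[j - 1] - open_cost, Yi[j - 1] - GAP_EXTEND,
                        Xi[j - 1] - open_cost)

    best_j, best_state, best = 1, "M", NEG_INF
    for j in range(n + 1):  # smallest j wins ties -> leftmost end
        for state, row in (("M", M[m]), ("X", X[m])):
            if row[j] > best:
                best, best_j, best_state = row[j], j, state

    # traceback
    ops: list[str] = []
    i, j, state = m, best_j, best_state
    eps = 1e-9
    while i > 0:
        if state == "M":
            s = MATCH if read[i - 1] == insert[j - 1] else MISMATCH
            prev = M[i][j] - s
            ops.append("M")
            if abs(M[i - 1][j - 1] - prev) < eps:
                state = "M"
            elif abs(Y[i - 1][j - 1] - prev) < eps:
                state = "Y"
            else:
                state = "X"
            i, j = i - 1, j - 1
        elif state == "X":
            ops.append("I")
            if abs(X[i - 1][j] - GAP_EXTEND - X[i][j]) < eps:
                state = "X"
            elif abs(M[i - 1][j] - open_cost - X[i][j]) < eps:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            ops.append("D")
            if abs(Y[i][j - 1] - GAP_EXTEND - Y[i][j]) < eps:
                state = "Y"
            elif abs(M[i][j - 1] - open_cost - Y[i][j]) < eps:
                state = "M"
            else:
                state = "X"
            j -= 1
    ops.reverse()
    runs: list[tuple[str, int]] = []
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    return Alignment(read_id=read_id, locus_id=locus_id, insert_start=j,
                     ops=runs, seq=read, quals=list(quals), score=int(best))


def align_to_insert(read: str, insert: str,
                    quals: Optional[Sequence[int]] = None,
                    expected_start: Optional[int] = None,
                    max_mismatch_frac: float = 0.12,
                    read_id: str = "", locus_id: str = "") -> Alignment:
    """Align a trimmed read to its reference insert.

    When ``expected_start`` is given, the ungapped placement there is
    accepted if its mismatch fraction is at most ``max_mismatch_frac``;
    otherwise the full glocal dynamic program is run.
    """
    if not read:
        raise ValueError("empty read")
    if quals is None:
        quals = [40] * len(read)
    if expected_start is not None and 0 <= expected_start \
            and expected_start + len(read) <= len(insert):
        window = insert[expected_start:expected_start + len(read)]
        mm = sum(a != b for a, b in zip(read, window))
        if mm <= max(2, int(max_mismatch_frac * len(read))):
            return Alignment(read_id=read_id, locus_id=locus_id,
                             insert_start=expected_start,
                             ops=[("M", len(read))], seq=read,
                             quals=list(quals),
                             score=len(read) - 2 * mm)
    return glocal_align(read, insert, quals, read_id=read_id,
                        locus_id=locus_id)


def _quals_from_string(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]  # Sanger +33 encoding


def align_pair(pair: TrimmedPair, amp: AmpliconDef) -> tuple[Alignment, Alignment]:
    """Align both mates of a trimmed pair; mate 2 is reverse-complemented
    into insert orientation first."""
    exp1 = len(amp.fwd_primer)
    aln1 = align_to_insert(pair.seq1, amp.insert_seq,
                           _quals_from_string(pair.qual1),
                           expected_start=exp1, read_id=pair.read_id,
                           locus_id=amp.locus_id)
    rc = revcomp(pair.seq2)
    rq = _quals_from_string(pair.qual2)[::-1]
    exp2 = len(amp.insert_seq) - len(amp.rev_primer) - len(rc)
    aln2 = align_to_insert(rc, amp.insert_seq, rq,
                           expected_start=exp2, read_id=pair.read_id,
                           locus_id=amp.locus_id)
    return aln1, aln2


@dataclass
class PileupColumn:
    locus_id: str
    insert_offset: int
    ref: str
    allele_depths: dict[Allele, int] = field(default_factory=dict)
    raw_depth: int = 0

    @property
    def filtered_depth(self) -> int:
        return sum(self.allele_depths.values())


def build_pileup(pair_alignments: Iterable[tuple[Alignment, Optional[Alignment]]],
                 amp: AmpliconDef, cfg: FilterConfig) -> list[PileupColumn]:
    """Quality-filtered pileup over the whole insert.

    Bases with phred >= ``min_base_quality`` increment their allele's depth;
    lower-quality bases increment ``raw_depth`` only.  Mate-overlapping
    positions count once per fragment (higher-quality base wins).
    """
    insert = amp.insert_seq
    columns = [PileupColumn(amp.locus_id, o, insert[o])
               for o in range(len(insert))]
    minq = cfg.min_base_quality
    for aln1, aln2 in pair_alignments:
        frag: dict[int, tuple[str, int]] = {}
        indel_obs: dict[tuple[int, Allele], int] = {}
        for aln in (aln1, aln2):
            if aln is None:
                continue
            if aln.insert_start < 0 or \
                    aln.insert_start + aln.ref_span() > len(insert):
                raise ValueError("alignment outside insert")
            for o, base, q in aln.aligned_bases():
                prev = frag.get(o)
                if prev is None or q > prev[1]:
                    frag[o] = (base, q)
            for anchor, key, q in aln.indels(insert):
                prev_q = indel_obs.get((anchor, key))
                if prev_q is None or q > prev_q:
                    indel_obs[(anchor, key)] = q
        for o, (base, q) in frag.items():
            col = columns[o]
            col.raw_depth += 1
            if q >= minq:
                col.allele_depths[base] = col.allele_depths.get(base, 0) + 1
        for (anchor, key), q in indel_obs.items():
            if anchor < 0:
                continue
            col = columns[anchor]
            if q >= minq:
                col.allele_depths[key] = col.allele_depths.get(key, 0) + 1
    return columns


# ---------------------------------------------------------------------------
# genotyping

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"


@dataclass
class GenotypeCall:
    sample_id: str
    chrom: str
    pos: int  # genomic, 1-based
    ref: str
    alt: Optional[str]  # None for reference-only calls
    genotype: str
    depth: int  # quality-filtered depth
    allele_depths: dict[str, int]
    allele_ratio: float
    locus_id: str = ""

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt or ".")

    @property
    def n_alt(self) -> int:
        return {GT_HOM_REF: 0, GT_HET: 1, GT_HOM_ALT: 2}.get(self.genotype, 0)


def _top_two(column: PileupColumn, cfg: FilterConfig):
    """Qualifying alleles (depth >= min_allele_depth) ranked by depth with a
    ref-first tie-break.  Returns (major, minor_or_None, ratio)."""
    qualifying = {a: d for a, d in column.allele_depths.items()
                  if d >= cfg.min_allele_depth}
    if not qualifying:
        return None, None, 0.0
    ranked = sorted(
        qualifying,
        key=lambda a: (-qualifying[a], a != column.ref, str(a)),
    )
    major = ranked[0]
    minor = ranked[1] if len(ranked) > 1 else None
    if minor is None:
        return major, None, 1.0
    dm, dn = qualifying[major], qualifying[minor]
    return major, minor, dm / (dm + dn)


def genotype_site(column: PileupColumn, cfg: FilterConfig):
    """Allele-ratio diploid genotype of one pileup column.

    Returns ``(genotype, major, minor, allele_ratio, filtered_depth)`` where
    genotype is one of hom_ref/het/hom_alt/missing relative to the column's
    reference base.  Missing iff filtered depth < ``min_depth`` (or no
    allele reaches ``min_allele_depth``).
    """
    depth = column.filtered_depth
    if depth < cfg.min_depth:
        return GT_MISSING, None, None, 0.0, depth
    major, minor, ratio = _top_two(column, cfg)
    if major is None:
        return GT_MISSING, None, None, 0.0, depth
    if ratio >= cfg.hom_ratio_threshold:
        gt = GT_HOM_REF if major == column.ref else GT_HOM_ALT
        return gt, major, None, ratio, depth
    return GT_HET, major, minor, ratio, depth


def allele_to_vcf(amp: AmpliconDef, offset: int,
                  allele: Allele) -> tuple[int, str, str]:
    """Map a pileup allele to (genomic pos, ref, alt) with VCF anchoring."""
    insert = amp.insert_seq
    if isinstance(allele, str):
        return amp.offset_to_pos(offset), insert[offset], allele
    kind, payload = allele
    if kind == "D":
        k = int(payload)
        ref = insert[offset:offset + k + 1]
        return amp.offset_to_pos(offset), ref, insert[offset]
    ref = insert[offset]
    return amp.offset_to_pos(offset), ref, ref + str(payload)


def _alt_key_for(amp: AmpliconDef, offset: int, ref: str,
                 alt: str) -> Allele:
    """Inverse of :func:`allele_to_vcf` for looking up pileup alleles."""
    if len(ref) == 1 and len(alt) == 1:
        return alt
    if len(ref) > len(alt):
        return ("D", len(ref) - len(alt))
    return ("I", alt[len(ref):] if alt.startswith(ref) else alt[1:])


def sample_pileups(groups: dict[str, list[TrimmedPair]], panel: Panel,
                   cfg: FilterConfig) -> dict[str, list[PileupColumn]]:
    """Pileups for one sample, keyed by locus."""
    out = {}
    for locus_id, pairs in groups.items():
        amp = panel[locus_id]
        alns = [align_pair(p, amp) for p in pairs]
        out[locus_id] = build_pileup(alns, amp, cfg)
    return out


def discover_sites(pileups: dict[str, list[PileupColumn]], panel: Panel,
                   cfg: FilterConfig) -> set[tuple[str, int, str, str]]:
    """Sites where a non-reference allele passes ``min_allele_depth`` in a
    column that itself passes ``min_depth``."""
    sites = set()
    for locus_id, columns in pileups.items():
        amp = panel[locus_id]
        for col in columns:
            if col.filtered_depth < cfg.min_depth:
                continue
            for allele, d in col.allele_depths.items():
                if allele == col.ref or d < cfg.min_allele_depth:
                    continue
                pos, ref, alt = allele_to_vcf(amp, col.insert_offset, allele)
                sites.add((amp.chrom, pos, ref, alt))
    return sites


def genotype_at(sample_id: str, pileups: dict[str, list[PileupColumn]],
                panel: Panel, cfg: FilterConfig, chrom: str, pos: int,
                ref: str, alt: Optional[str]) -> list[GenotypeCall]:
    """Genotype one sample at one site, one call per covering amplicon with
    read data (merged downstream)."""
    calls = []
    for amp in panel.loci_covering(chrom, pos):
        columns = pileups.get(amp.locus_id)
        if columns is None:
            continue
        col = columns[amp.pos_to_offset(pos)]
        gt, major, minor, ratio, depth = genotype_site(col, cfg)
        alt_key = _alt_key_for(amp, amp.pos_to_offset(pos), ref, alt) \
            if alt and alt != "." else None
        if gt == GT_MISSING or alt_key is None:
            genotype = gt
        else:
            called = {major} if minor is None else {major, minor}
            if gt != GT_HET:
                n_alt = 2 if major == alt_key else 0
            else:
                n_alt = 1 if alt_key in called else 0
            genotype = (GT_HOM_REF, GT_HET, GT_HOM_ALT)[n_alt]
        ad = {
            "ref": col.allele_depths.get(col.ref, 0),
            "alt": col.allele_depths.get(alt_key, 0) if alt_key else 0,
        }
        calls.append(GenotypeCall(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref,
            alt=None if not alt or alt == "." else alt,
            genotype=genotype, depth=depth, allele_depths=ad,
            allele_ratio=ratio, locus_id=amp.locus_id,
        ))
    return calls


def call_sample_variants(sample_id: str,
                         groups: dict[str, list[TrimmedPair]],
                         panel: Panel, cfg: FilterConfig,
                         extra_sites: Optional[Iterable[tuple]] = None,
                         ) -> list[GenotypeCall]:
    """Per-sample calls at every discovered non-reference site, at panel
    known resistance sites (so wild-type is reported), and at any
    ``extra_sites`` (chrom, pos, ref, alt) tuples."""
    pileups = sample_pileups(groups, panel, cfg)
    sites = discover_sites(pileups, panel, cfg)
    if extra_sites:
        sites |= {tuple(s) for s in extra_sites}
    calls: list[GenotypeCall] = []
    for chrom, pos, ref, alt in sorted(sites):
        calls.extend(genotype_at(sample_id, pileups, panel, cfg,
                                 chrom, pos, ref, alt))
    covered = {(c.chrom, c.pos) for c in calls}
    for amp in panel:
        for ks in amp.known_sites:
            if (amp.chrom, ks.pos) in covered:
                continue
            calls.extend(genotype_at(
                sample_id, pileups, panel, cfg, amp.chrom, ks.pos,
                amp.ref_base(ks.pos), None))
    return calls


CALLS_COLUMNS = ["sample_id", "locus_id", "chrom", "pos", "ref", "alt",
                 "genotype", "depth", "ad_ref", "ad_alt", "allele_ratio"]


def write_calls_tsv(calls: Iterable[GenotypeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for c in calls:
            fh.write("\t".join(map(str, [
                c.sample_id, c.locus_id, c.chrom, c.pos, c.ref,
                c.alt or ".", c.genotype, c.depth,
                c.allele_depths.get("ref", 0), c.allele_depths.get("alt", 0),
                f"{c.allele_ratio:.6f}",
            ])) + "\n")


def read_calls_tsv(path) -> list[GenotypeCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            r = dict(zip(header, line.rstrip("\n").split("\t")))
            calls.append(GenotypeCall(
                sample_id=r["sample_id"], chrom=r["chrom"],
                pos=int(r["pos"]), ref=r["ref"],
                alt=None if r["alt"] == "." else r["alt"],
                genotype=r["genotype"], depth=int(r["depth"]),
                allele_depths={"ref": int(r["ad_ref"]),
                               "alt": int(r["ad_alt"])},
                allele_ratio=float(r["allele_ratio"]),
                locus_id=r["locus_id"],
            ))
    return calls
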