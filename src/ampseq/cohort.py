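"""Cohort-level merging, cross-sample retention filtering, consequence
annotation and VCF/TSV output.

A site is retained iff at least ``min_mosquitoes`` samples carry an
alternate allele AND those carriers span at least ``min_pools`` distinct
pools.  Sites are keyed by (chrom, pos, ref, alt) regardless of how many
overlapping amplicons cover them; duplicate per-sample calls from
overlapping amplicons are merged (higher filtered depth wins on conflict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio.Seq import Seq

from .panel import AmpliconDef, CdsSegment, FilterConfig, Panel, PanelError, \
    SampleSheet
from .varcall import GT_HET, GT_HOM_ALT, GT_MISSING, GenotypeCall
from . import vcfio

SiteKey = tuple[str, int, str, str]  # chrom, pos, ref, alt

SPLICE_INTRON_WINDOW = 8  # bases into the intron from an exon boundary
SPLICE_EXON_WINDOW = 3  # bases into the exon


@dataclass
class ConsequenceAnnotation:
    site: SiteKey
    effect: str  # synonymous | missense | stop_gained | intronic |
    # splice_region | truncated_codon | indel
    gene: str = ""
    codon_change: Optional[str] = None
    aa_pos: Optional[int] = None
    aa_change: Optional[str] = None
    exon_distance: Optional[int] = None  # to nearest exon boundary
    splice_region: bool = False  # exonic sites within the 3bp exon window

    def csq_string(self) -> str:
        return "|".join([
            self.effect, self.gene, self.codon_change or "",
            self.aa_change or "",
        ])


@dataclass
class CohortTable:
    samples: list[str]
    sites: list[SiteKey]
    calls: dict[tuple[str, SiteKey], GenotypeCall]
    pool_map: dict[str, str]
    flags: dict[SiteKey, tuple[Optional[bool], str]] = field(default_factory=dict)
    conflicts: list[tuple[str, SiteKey]] = field(default_factory=list)

    def call(self, sample: str, site: SiteKey) -> Optional[GenotypeCall]:
        return self.calls.get((sample, site))

    def genotype_counts(self, site: SiteKey) -> dict[str, int]:
        counts = {"hom_ref": 0, "het": 0, "hom_alt": 0, "missing": 0}
        for s in self.samples:
            c = self.call(s, site)
            counts[c.genotype if c else "missing"] += 1
        return counts

    def carriers(self, site: SiteKey) -> list[str]:
        return [s for s in self.samples
                if (c := self.call(s, site))
                and c.genotype in (GT_HET, GT_HOM_ALT)]

    def n_genotyped(self, site: SiteKey) -> int:
        return sum(1 for s in self.samples
                   if (c := self.call(s, site))
                   and c.genotype != GT_MISSING)

    def alt_frequency(self, site: SiteKey) -> float:
        n, alt = 0, 0
        for s in self.samples:
            c = self.call(s, site)
            if c and c.genotype != GT_MISSING:
                n += 1
                alt += c.n_alt
        if n == 0:
            return float("nan")
        return alt / (2 * n)

    def retained_sites(self) -> list[SiteKey]:
        return [s for s in self.sites if self.flags.get(s, (None, ""))[0]]


def merge_cohort(callsets: dict[str, list[GenotypeCall]],
                 sheet: SampleSheet, panel: Panel) -> CohortTable:
    """Merge per-sample call sets into one cohort table.

    Duplicate calls for one (sample, site) coming from overlapping amplicons
    collapse to a single genotype: concordant duplicates keep the deeper
    call, discordant ones keep the call from the amplicon with the higher
    filtered depth and are flagged as conflicts.
    """
    pool_map = sheet.pool_map()
    for sample in callsets:
        if sample not in pool_map:
            raise PanelError(f"sample {sample!r} not in sample sheet")
    calls: dict[tuple[str, SiteKey], GenotypeCall] = {}
    conflicts: list[tuple[str, SiteKey]] = []
    site_set: set[SiteKey] = set()
    for sample, sample_calls in callsets.items():
        for c in sample_calls:
            if c.alt is None:
                continue  # reference-only known-site reporting, not a variant
            key = (sample, c.site_key)
            site_set.add(c.site_key)
            prev = calls.get(key)
            if prev is None:
                calls[key] = c
            else:
                if prev.genotype != c.genotype and \
                        GT_MISSING not in (prev.genotype, c.genotype):
                    conflicts.append(key)
                keep, other = (c, prev) if c.depth > prev.depth else (prev, c)
                if keep.genotype == GT_MISSING and \
                        other.genotype != GT_MISSING:
                    keep = other
                calls[key] = keep
    samples = [s for s in sheet.sample_ids if s in callsets] or \
        sheet.sample_ids
    return CohortTable(
        samples=samples,
        sites=sorted(site_set),
        calls=calls,
        pool_map=pool_map,
        conflicts=conflicts,
    )


def apply_cohort_filters(table: CohortTable,
                         cfg: FilterConfig) -> CohortTable:
    """Flag every site as retained or dropped (singleton / single_pool).

    Idempotent: flags are recomputed from the genotype matrix each call.
    """
    for site in table.sites:
        carriers = table.carriers(site)
        pools = {table.pool_map[s] for s in carriers}
        if len(carriers) < cfg.min_mosquitoes:
            table.flags[site] = (False, "singleton")
        elif len(pools) < cfg.min_pools:
            table.flags[site] = (False, "single_pool")
        else:
            table.flags[site] = (True, "retained")
    return table


# ---------------------------------------------------------------------------
# consequence annotation

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _codon_of(amp: AmpliconDef, seg: CdsSegment, pos: int):
    """Return (codon_number, index_within_codon 0-2, genomic positions of the
    codon in translation order) or None when the codon is incomplete."""
    if seg.strand == "+":
        idx = pos - seg.start - seg.frame
        if idx < 0:
            return None
        codon_no = idx // 3 + seg.codon_start
        within = idx % 3
        first = pos - within
        positions = [first, first + 1, first + 2]
    else:
        idx = seg.end - seg.frame - pos
        if idx < 0:
            return None
        codon_no = idx // 3 + seg.codon_start
        within = idx % 3
        first = pos + within
        positions = [first, first - 1, first - 2]
    return codon_no, within, positions


def annotate_consequence(site: SiteKey, panel: Panel) -> ConsequenceAnnotation:
    """Coding consequence of a site from the panel's CDS geometry.

    Exonic SNVs are translated (standard genetic code, strand- and
    frame-aware); intronic sites within 8 bases of an exon boundary are
    splice_region; exonic sites within 3 bases keep their coding effect and
    carry a splice flag.  Codons extending past the amplicon or before the
    first complete codon are reported as truncated_codon, not guessed.
    """
    chrom, pos, ref, alt = site
    covering = panel.loci_covering(chrom, pos)
    if not covering:
        raise PanelError(f"site {chrom}:{pos} in no amplicon")
    amps_with_cds = [a for a in covering if a.cds_segments] or covering
    amp = amps_with_cds[0]
    if len(ref) != 1 or len(alt) != 1:
        return ConsequenceAnnotation(site=site, effect="indel", gene=amp.gene)

    seg = next((s for s in amp.cds_segments if s.contains(pos)), None)
    if seg is None:
        dist = None
        for a in covering:
            for s in a.cds_segments:
                d = s.start - pos if pos < s.start else pos - s.end
                if d > 0 and (dist is None or d < dist):
                    dist = d
        effect = ("splice_region"
                  if dist is not None and dist <= SPLICE_INTRON_WINDOW
                  else "intronic")
        return ConsequenceAnnotation(site=site, effect=effect, gene=amp.gene,
                                     exon_distance=dist)

    exon_dist = min(pos - seg.start, seg.end - pos) + 1  # bases into the exon
    located = _codon_of(amp, seg, pos)
    if located is None:
        return ConsequenceAnnotation(site=site, effect="truncated_codon",
                                     gene=amp.gene, exon_distance=exon_dist)
    codon_no, within, positions = located
    if any(not (amp.contains_pos(p) and seg.contains(p)) for p in positions):
        return ConsequenceAnnotation(site=site, effect="truncated_codon",
                                     gene=amp.gene, exon_distance=exon_dist)
    bases = [amp.ref_base(p) for p in positions]
    if seg.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_base = alt.translate(_COMPLEMENT)
    else:
        alt_base = alt
    ref_codon = "".join(bases)
    alt_codon_list = list(bases)
    alt_codon_list[within] = alt_base
    alt_codon = "".join(alt_codon_list)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gained"
    else:
        effect = "missense"
    return ConsequenceAnnotation(
        site=site, effect=effect, gene=amp.gene,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_pos=codon_no,
        aa_change=f"{ref_aa}{codon_no}{alt_aa}",
        exon_distance=exon_dist,
        splice_region=exon_dist <= SPLICE_EXON_WINDOW,
    )


def annotate_all(table: CohortTable,
                 panel: Panel) -> dict[SiteKey, ConsequenceAnnotation]:
    return {site: annotate_consequence(site, panel) for site in table.sites}


# ---------------------------------------------------------------------------
# output

def write_cohort_vcf(table: CohortTable,
                     annotations: dict[SiteKey, ConsequenceAnnotation],
                     path: Union[str, Path], panel: Panel,
                     retained_only: bool = True) -> None:
    """One record per unique retained site, all samples as columns
    (GT:DP:AD:AR), consequence in INFO.  Round-trips byte-stably through
    :mod:`ampseq.vcfio`."""
    records = []
    sites = table.retained_sites() if retained_only else table.sites
    for site in sites:
        chrom, pos, ref, alt = site
        ns = table.n_genotyped(site)
        af = table.alt_frequency(site)
        info = f"NS={ns};AF={af:.6g}"
        ann = annotations.get(site)
        if ann is not None:
            info += f";CSQ={ann.csq_string()}"
        fields = []
        for s in table.samples:
            c = table.call(s, site)
            if c is None:
                fields.append(vcfio.format_sample_field("missing", 0, 0, 0, 0))
            else:
                fields.append(vcfio.format_sample_field(
                    c.genotype, c.depth,
                    c.allele_depths.get("ref", 0),
                    c.allele_depths.get("alt", 0),
                    c.allele_ratio))
        records.append(vcfio.VcfRecord(chrom=chrom, pos=pos, ref=ref,
                                       alt=alt, info=info,
                                       sample_fields=fields))
    vcfio.write_vcf(path, table.samples, panel.chroms(), records)


def retention_report(table: CohortTable) -> pd.DataFrame:
    rows = []
    for site in table.sites:
        chrom, pos, ref, alt = site
        carriers = table.carriers(site)
        pools = sorted({table.pool_map[s] for s in carriers})
        retained, reason = table.flags.get(site, (None, "unfiltered"))
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "carriers": len(carriers), "pools": len(pools),
            "retained": retained, "reason": reason,
        })
    return pd.DataFrame(rows)


def consequence_report(table: CohortTable,
                       annotations: dict[SiteKey, ConsequenceAnnotation],
                       retained_only: bool = True) -> pd.DataFrame:
    """Per-site consequence table: chrom, gene, position, ref, alt,
    consequence, aa change, n genotyped, n carriers, alt allele frequency
    in percent."""
    rows = []
    sites = table.retained_sites() if retained_only else table.sites
    for site in sites:
        chrom, pos, ref, alt = site
        ann = annotations.get(site)
        rows.append({
            "chrom": chrom,
            "gene": ann.gene if ann else "",
            "pos": pos, "ref": ref, "alt": alt,
            "consequence": ann.effect if ann else "",
            "aa_change": (ann.aa_change or "") if ann else "",
            "n_genotyped": table.n_genotyped(site),
            "n_carriers": len(table.carriers(site)),
            "alt_freq_pct": round(100 * table.alt_frequency(site), 1),
        })
    return pd.DataFrame(rows)
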