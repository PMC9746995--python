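"""End-to-end orchestration: demultiplex per pool, build per-sample
pileups, discover variant sites across the cohort, genotype every sample at
every site, merge, filter and annotate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import cohort as cohort_mod
from .demux import DemuxStats, Read, TrimmedPair, demultiplex
from .panel import FilterConfig, Panel, SampleSheet
from .varcall import (GenotypeCall, PileupColumn, discover_sites,
                      genotype_at, sample_pileups)


@dataclass
class StudyResult:
    table: cohort_mod.CohortTable
    annotations: dict
    demux_stats: dict[str, DemuxStats]
    pileups: dict[str, dict[str, list[PileupColumn]]]  # sample -> locus
    callsets: dict[str, list[GenotypeCall]] = field(default_factory=dict)


def run_study(panel: Panel, sheet: SampleSheet,
              pool_pairs: dict[str, Iterable[tuple[Read, Read]]],
              cfg: Optional[FilterConfig] = None) -> StudyResult:
    """Run the full pipeline over one or more pools.

    ``pool_pairs`` maps pool_id to a mate-synchronized read-pair stream
    (e.g. ``SimResult.pairs()`` or :func:`ampseq.demux.fastq_pairs`).
    """
    if cfg is None:
        cfg = FilterConfig()
    demux_stats: dict[str, DemuxStats] = {}
    groups_by_sample: dict[str, dict[str, list[TrimmedPair]]] = {}
    for pool_id, pairs in pool_pairs.items():
        pool_sheet = sheet.subset(pool_id)
        groups, stats = demultiplex(pairs, panel, pool_sheet, cfg)
        demux_stats[pool_id] = stats
        for (sample_id, locus_id), reads in groups.items():
            groups_by_sample.setdefault(sample_id, {}) \
                .setdefault(locus_id, []).extend(reads)

    pileups = {
        sample: sample_pileups(groups, panel, cfg)
        for sample, groups in groups_by_sample.items()
    }

    # pass 1: union of discovered variant sites across samples
    all_sites: set[tuple[str, int, str, str]] = set()
    for sample, p in pileups.items():
        all_sites |= discover_sites(p, panel, cfg)

    # pass 2: genotype every sample at every site (and at panel known sites)
    callsets: dict[str, list[GenotypeCall]] = {}
    for sample, p in pileups.items():
        calls: list[GenotypeCall] = []
        for chrom, pos, ref, alt in sorted(all_sites):
            calls.extend(genotype_at(sample, p, panel, cfg,
                                     chrom, pos, ref, alt))
        covered = {(c.chrom, c.pos) for c in calls}
        for amp in panel:
            for ks in amp.known_sites:
                if (amp.chrom, ks.pos) not in covered:
                    calls.extend(genotype_at(sample, p, panel, cfg,
                                             amp.chrom, ks.pos,
                                             amp.ref_base(ks.pos), None))
        callsets[sample] = calls

    table = cohort_mod.merge_cohort(callsets, sheet, panel)
    cohort_mod.apply_cohort_filters(table, cfg)
    annotations = cohort_mod.annotate_all(table, panel)
    return StudyResult(table=table, annotations=annotations,
                       demux_stats=demux_stats, pileups=pileups,
                       callsets=callsets)
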