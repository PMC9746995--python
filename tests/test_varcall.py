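from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampseq.demux import TrimmedPair, demultiplex
from ampseq.panel import FilterConfig
from ampseq.simreads import (GenotypeEntry, GenotypeSpec, SimConfig,
                             RDL_SITE_POS, demo_sheet, simulate_pool)
from ampseq.varcall import (Alignment, GenotypeCall, PileupColumn,
                            align_pair, align_to_insert, build_pileup,
                            call_sample_variants, discover_sites,
                            genotype_site, glocal_align, read_calls_tsv,
                            sample_pileups, write_calls_tsv)

# ---------------------------------------------------------------------------
# alignment


def dp_oracle(read: str, insert: str) -> int:
    """Independent recursive affine-gap glocal scorer: match +1, mismatch
    -1, gap of length k costs 4 + k; leading/trailing insert is free."""
    m, n = len(read), len(insert)

    @lru_cache(maxsize=None)
    def go(i, j, gap):
        if i == m:
            return 0  # rest of the insert is free
        best = -10 ** 9
        if j < n:
            s = 1 if read[i] == insert[j] else -1
            best = max(best, s + go(i + 1, j + 1, None))
            best = max(best, -(1 if gap == "D" else 5) + go(i, j + 1, "D"))
        best = max(best, -(1 if gap == "I" else 5) + go(i + 1, j, "I"))
        return best

    return max(go(0, j, None) for j in range(n + 1))


def test_exact_substring_alignment(panel):
    insert = panel["Rdl_Aeg"].insert_seq
    read = insert[30:280]
    aln = glocal_align(read, insert)
    assert aln.insert_start == 30
    assert aln.ops == [("M", 250)]
    assert aln.score == 250


def test_single_substitution_same_placement(panel):
    insert = panel["Rdl_Aeg"].insert_seq
    read = list(insert[30:280])
    read[100] = "A" if read[100] != "A" else "C"
    aln = glocal_align("".join(read), insert)
    assert aln.insert_start == 30
    assert aln.ops == [("M", 250)]
    assert aln.score == 248


def test_alignment_handles_deletion(panel):
    insert = panel["Ace1"].insert_seq
    read = insert[50:120] + insert[123:190]  # 3bp deletion
    aln = glocal_align(read, insert)
    assert aln.insert_start == 50
    assert ("D", 3) in aln.ops
    assert aln.ref_span() == 140


def test_glocal_score_matches_dp_oracle():
    rng = np.random.default_rng(77)
    for _ in range(200):
        n = int(rng.integers(10, 61))
        m = int(rng.integers(3, min(n, 25)))
        insert = "".join(rng.choice(list("ACGT"), size=n))
        if rng.random() < 0.5:
            start = int(rng.integers(0, n - m + 1))
            read = list(insert[start:start + m])
            for _ in range(int(rng.integers(0, 3))):  # sprinkle mutations
                i = int(rng.integers(0, m))
                read[i] = rng.choice(list("ACGT"))
            read = "".join(read)
        else:
            read = "".join(rng.choice(list("ACGT"), size=m))
        assert glocal_align(read, insert).score == dp_oracle(read, insert)


def test_empty_read_rejected(panel):
    with pytest.raises(ValueError, match="empty read"):
        glocal_align("", panel["Ace1"].insert_seq)
    with pytest.raises(ValueError, match="empty read"):
        align_to_insert("", panel["Ace1"].insert_seq)


def test_fast_path_agrees_with_dp(panel):
    insert = panel["DomainI"].insert_seq
    read = insert[20:220]
    fast = align_to_insert(read, insert, expected_start=20)
    slow = glocal_align(read, insert)
    assert (fast.insert_start, fast.ops, fast.score) == \
        (slow.insert_start, slow.ops, slow.score)


# ---------------------------------------------------------------------------
# pileup


def column_fixture(amp, offset, bases_quals):
    """Build a pileup column via build_pileup from synthetic one-base
    alignments."""
    alns = []
    for base, q in bases_quals:
        alns.append((Alignment(read_id="r", locus_id=amp.locus_id,
                               insert_start=offset, ops=[("M", 1)],
                               seq=base, quals=[q]), None))
    return build_pileup(alns, amp, FilterConfig())[offset]


def test_quality_filter_splits_depths(panel):
    amp = panel["Rdl_Aeg"]
    col = column_fixture(amp, 230, [("A", 37)] * 60 + [("G", 20)] * 10)
    assert col.allele_depths == {"A": 60}
    assert col.raw_depth == 70


def test_empty_pileup(panel):
    amp = panel["Rdl_Aeg"]
    cols = build_pileup([], amp, FilterConfig())
    assert len(cols) == len(amp.insert_seq)
    assert all(c.raw_depth == 0 and not c.allele_depths for c in cols)


def test_mate_overlap_counted_once(panel):
    amp = panel["Rdl_Aeg"]
    a1 = Alignment("r", amp.locus_id, 100, [("M", 5)], "ACGTA",
                   [37, 37, 37, 10, 37])
    a2 = Alignment("r", amp.locus_id, 102, [("M", 5)], "GTTAC",
                   [37, 37, 37, 37, 37])
    cols = build_pileup([(a1, a2)], amp, FilterConfig())
    for o in range(100, 107):
        assert cols[o].raw_depth == 1  # one fragment, counted once
    # at offset 103 mate1 has qual 10 ('T'), mate2 qual 37 ('T'): highest wins
    assert cols[103].allele_depths == {"T": 1}


def test_pileup_recount_oracle(panel, cfg):
    """allele_depth totals equal a brute-force recount from alignments."""
    sheet = demo_sheet(samples_per_pool=3)
    res = simulate_pool(panel, sheet, GenotypeSpec(),
                        SimConfig(coverage=8, base_error_rate=0.02,
                                  quality_model="two_level", seed=21))
    groups, _ = demultiplex(res.pairs(), panel, sheet, cfg)
    for (sample, locus), pairs in list(groups.items())[:4]:
        amp = panel[locus]
        alns = [align_pair(p, amp) for p in pairs]
        cols = build_pileup(alns, amp, cfg)
        # independent recount
        expect = {}
        for a1, a2 in alns:
            frag = {}
            for aln in (a1, a2):
                for o, b, q in aln.aligned_bases():
                    if o not in frag or q > frag[o][1]:
                        frag[o] = (b, q)
            for o, (b, q) in frag.items():
                if q >= cfg.min_base_quality:
                    expect[(o, b)] = expect.get((o, b), 0) + 1
        got = {(c.insert_offset, a): d for c in cols
               for a, d in c.allele_depths.items() if isinstance(a, str)}
        assert got == expect


# ---------------------------------------------------------------------------
# genotyping


def simple_column(amp, depths, offset=230):
    return PileupColumn(amp.locus_id, offset, amp.insert_seq[offset],
                        allele_depths=dict(depths),
                        raw_depth=sum(depths.values()))


def test_genotype_hom_reassignment_at_ratio_09(panel, cfg):
    amp = panel["Rdl_Aeg"]
    ref = amp.insert_seq[230]
    col = simple_column(amp, {ref: 90, "T": 10})
    gt, major, minor, ratio, depth = genotype_site(col, cfg)
    assert (gt, major, ratio, depth) == ("hom_ref", ref, 0.9, 100)


def test_genotype_het_below_threshold(panel, cfg):
    amp = panel["Rdl_Aeg"]
    ref = amp.insert_seq[230]
    col = simple_column(amp, {ref: 60, "T": 40})
    gt, major, minor, ratio, _ = genotype_site(col, cfg)
    assert gt == "het" and ratio == 0.6 and {major, minor} == {ref, "T"}


def test_genotype_minor_below_allele_depth(panel, cfg):
    amp = panel["Rdl_Aeg"]
    ref = amp.insert_seq[230]
    col = simple_column(amp, {ref: 45, "T": 5})
    gt, major, minor, ratio, depth = genotype_site(col, cfg)
    assert (gt, ratio, depth) == ("hom_ref", 1.0, 50)
    assert minor is None


def test_genotype_missing_below_min_depth(panel, cfg):
    amp = panel["Rdl_Aeg"]
    ref = amp.insert_seq[230]
    col = simple_column(amp, {ref: 30, "T": 10})
    gt, *_ , depth = genotype_site(col, cfg)
    assert gt == "missing" and depth == 40


def test_hom_boundary_is_inclusive(panel):
    amp = panel["Rdl_Aeg"]
    ref = amp.insert_seq[230]
    cfg = FilterConfig()
    col = simple_column(amp, {ref: 80, "T": 20})  # ratio exactly 0.8
    gt, *_ = genotype_site(col, cfg)
    assert gt == "hom_ref"


@st.composite
def random_columns(draw):
    depths = draw(st.dictionaries(
        st.sampled_from(list("ACGT")),
        st.integers(min_value=0, max_value=300), min_size=1, max_size=4))
    return depths


@given(random_columns(), st.integers(0, 200), st.integers(0, 100))
@settings(max_examples=200, deadline=None)
def test_min_depth_monotonicity(depths, d1, extra):
    from ampseq.simreads import demo_panel
    amp = demo_panel()["Rdl_Aeg"]
    col = simple_column(amp, depths)
    lo = FilterConfig(min_depth=d1)
    hi = FilterConfig(min_depth=d1 + extra)
    gt_lo, *_ = genotype_site(col, lo)
    gt_hi, *_ = genotype_site(col, hi)
    if gt_lo == "missing":
        assert gt_hi == "missing"  # raising min_depth never rescues a site


@given(random_columns(),
       st.floats(min_value=0.51, max_value=0.99),
       st.floats(min_value=0.0, max_value=0.4))
@settings(max_examples=200, deadline=None)
def test_hom_threshold_monotonicity(depths, t1, dt):
    from ampseq.simreads import demo_panel
    amp = demo_panel()["Rdl_Aeg"]
    t2 = min(1.0, t1 + dt)
    col = simple_column(amp, depths)
    gt1, *_ = genotype_site(col, FilterConfig(hom_ratio_threshold=t1))
    gt2, *_ = genotype_site(col, FilterConfig(hom_ratio_threshold=t2))
    if gt1 == "het":
        assert gt2 == "het"  # raising the threshold never makes a hom


def test_het_ratio_distribution_at_coverage_200(panel, cfg):
    """A true het at coverage 200 is called het with ratio in [0.5, 0.8) in
    >= 99% of 1,000 seeded replicates."""
    amp = panel["Rdl_Aeg"]
    ref = amp.insert_seq[230]
    rng = np.random.default_rng(2024)
    good = 0
    for _ in range(1000):
        x = int(rng.binomial(200, 0.5))
        col = simple_column(amp, {ref: 200 - x, "T": x})
        gt, _, _, ratio, _ = genotype_site(col, cfg)
        if gt == "het" and 0.5 <= ratio < 0.8:
            good += 1
    assert good >= 990


def test_het_ratio_converges_to_half(panel, cfg):
    amp = panel["Rdl_Aeg"]
    ref = amp.insert_seq[230]
    rng = np.random.default_rng(5)
    x = int(rng.binomial(10_000, 0.5))
    col = simple_column(amp, {ref: 10_000 - x, "T": x})
    _, _, _, ratio, _ = genotype_site(col, cfg)
    assert ratio == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# per-sample calling on simulated data


def one_sample_groups(panel, genotype, coverage=200, err=0.001, seed=0):
    sheet = demo_sheet(samples_per_pool=1)
    amp = panel["Rdl_Aeg"]
    off = amp.pos_to_offset(RDL_SITE_POS)
    entries = ([GenotypeEntry("S001", "Rdl_Aeg", off, "G", "T", genotype)]
               if genotype else [])
    res = simulate_pool(panel, sheet, GenotypeSpec(entries),
                        SimConfig(coverage=coverage, base_error_rate=err,
                                  seed=seed))
    groups, _ = demultiplex(res.pairs(), panel, sheet, FilterConfig())
    return {locus: pairs for (s, locus), pairs in groups.items()}


def test_hom_alt_sample_yields_single_variant(panel, cfg):
    groups = one_sample_groups(panel, "hom_alt")
    calls = call_sample_variants("S001", groups, panel, cfg)
    variant = [c for c in calls if c.alt is not None]
    assert len(variant) == 1
    c = variant[0]
    assert (c.chrom, c.pos, c.ref, c.alt) == ("2", RDL_SITE_POS, "G", "T")
    assert c.genotype == "hom_alt"


def test_wildtype_sample_reports_known_sites_hom_ref(panel, cfg):
    groups = one_sample_groups(panel, None)
    calls = call_sample_variants("S001", groups, panel, cfg)
    assert all(c.alt is None for c in calls)
    by_pos = {(c.chrom, c.pos): c for c in calls}
    from ampseq.simreads import ACE1_SITE_POS
    for key in (("2", RDL_SITE_POS), ("3", ACE1_SITE_POS)):
        assert by_pos[key].genotype == "hom_ref"
        assert by_pos[key].allele_ratio == 1.0


def test_genotype_recovery_over_1000_sites(panel):
    """>= 99% exact genotype recovery at coverage 200 / error 0.1%; any
    discordance is het<->hom at an extreme sampled ratio."""
    cfg = FilterConfig()
    rng = np.random.default_rng(31)
    loci = ["Rdl_Aeg", "Ace1", "DomainI", "DomainII"]
    n_sites, n_correct = 0, 0
    for rep in range(5):
        sheet = demo_sheet(samples_per_pool=10, seed=100 + rep)
        site_freqs, truth_gt = {}, {}
        entries = []
        for locus in loci:
            amp = panel[locus]
            lo, hi = amp.insert_region
            offsets = rng.choice(
                np.r_[lo:244, 260:hi - 10], size=5, replace=False)
            for off in offsets:
                off = int(off)
                ref = amp.insert_seq[off]
                alt = {"A": "T", "C": "A", "G": "T", "T": "C"}[ref]
                for e in sheet:
                    gt = ("hom_ref", "het", "hom_alt")[int(rng.integers(3))]
                    entries.append(GenotypeEntry(e.sample_id, locus, off,
                                                 ref, alt, gt))
                    truth_gt[(e.sample_id, locus, off)] = gt
        spec = GenotypeSpec(entries)
        res = simulate_pool(panel, sheet, spec,
                            SimConfig(coverage=200, base_error_rate=0.001,
                                      seed=500 + rep))
        groups, _ = demultiplex(res.pairs(), panel, sheet, cfg)
        by_sample = {}
        for (sample, locus), pairs in groups.items():
            by_sample.setdefault(sample, {})[locus] = pairs
        for sample, sgroups in by_sample.items():
            pileups = sample_pileups(sgroups, panel, cfg)
            for (s, locus, off), gt_true in truth_gt.items():
                if s != sample:
                    continue
                col = pileups[locus][off]
                called, _, _, ratio, _ = genotype_site(col, cfg)
                n_sites += 1
                if called == gt_true:
                    n_correct += 1
                else:
                    assert {called, gt_true} <= \
                        {"het", "hom_ref", "hom_alt"}
    assert n_sites >= 1000
    assert n_correct / n_sites >= 0.99


def test_calls_tsv_roundtrip(panel, cfg, tmp_path):
    groups = one_sample_groups(panel, "het", coverage=100, err=0)
    calls = call_sample_variants("S001", groups, panel, cfg)
    write_calls_tsv(calls, tmp_path / "c.tsv")
    back = read_calls_tsv(tmp_path / "c.tsv")
    assert [(c.sample_id, c.chrom, c.pos, c.ref, c.alt, c.genotype)
            for c in back] == \
        [(c.sample_id, c.chrom, c.pos, c.ref, c.alt, c.genotype)
         for c in calls]
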