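"""Population-genetic and quality statistics: allele frequencies, MAF
spectrum, Hardy-Weinberg chi-squared tests, Tajima's D and genotype
concordance between call sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .panel import FilterConfig

HWE_ALPHA = 1e-3


@dataclass
class SiteStats:
    site: object
    n_genotyped: int
    hom_ref: int
    het: int
    hom_alt: int
    alt_freq: float
    maf: float
    hwe_chi2: float
    hwe_p: float
    hwe_flag: bool  # significant deviation at p < 0.001


def site_stats(hom_ref: int, het: int, hom_alt: int,
               site: object = None) -> SiteStats:
    """Frequency, MAF and HWE chi-squared (1 df, no continuity correction)
    from diploid genotype counts."""
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("all-missing site: no genotyped samples")
    p = (het + 2 * hom_alt) / (2 * n)
    q = 1.0 - p
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    observed = np.array([hom_ref, het, hom_alt], dtype=float)
    if p in (0.0, 1.0):
        chi2 = 0.0
    else:
        if expected.min() < 5:
            warnings.warn(
                "HWE chi-squared approximation is unreliable at expected "
                "counts < 5", stacklevel=2)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return SiteStats(
        site=site, n_genotyped=n, hom_ref=hom_ref, het=het, hom_alt=hom_alt,
        alt_freq=p, maf=min(p, q), hwe_chi2=chi2, hwe_p=pval,
        hwe_flag=pval < HWE_ALPHA,
    )


def maf_spectrum(mafs: Iterable[float], threshold: float = 0.1) -> float:
    """Fraction of sites with minor allele frequency strictly below the
    threshold."""
    mafs = list(mafs)
    if not mafs:
        raise ValueError("no sites")
    return sum(m < threshold for m in mafs) / len(mafs)


# ---------------------------------------------------------------------------
# Tajima's D

@dataclass
class TajimaResult:
    region: str
    n: int  # chromosomes sampled
    S: int  # segregating sites
    k_hat: float  # mean pairwise differences
    a1: float = 0.0
    a2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    e1: float = 0.0
    e2: float = 0.0
    D: Optional[float] = None  # None when S == 0 (undefined)


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(genotypes: Union[np.ndarray, Sequence[Sequence[int]]],
              region: str = "") -> TajimaResult:
    """Tajima's D from an unphased diploid genotype matrix.

    ``genotypes`` is samples x sites with entries 0/1/2 alternate-allele
    copies (negative = missing; sites containing any missing genotype are
    dropped listwise).  Mean pairwise differences are computed from allele
    counts: for a biallelic site with x alternate alleles among 2N
    chromosomes, the per-site contribution is 2*x*(2N-x)/(2N*(2N-1)),
    which equals direct pairwise-difference averaging over chromosomes.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x sites)")
    n = 2 * g.shape[0]
    if n < 4:  # fewer than 2 diploid samples
        raise ValueError("need at least 2 chromosomes from >= 2 samples")
    complete = g[:, ~np.any(g < 0, axis=0)] if g.size else g
    x = complete.sum(axis=0)  # alt chromosomes per site
    segregating = (x > 0) & (x < n)
    S = int(segregating.sum())
    xs = x[segregating]
    k_hat = float((2.0 * xs * (n - xs) / (n * (n - 1))).sum())
    consts = _tajima_constants(n)
    result = TajimaResult(region=region, n=n, S=S, k_hat=k_hat, **consts)
    if S == 0:
        return result
    variance = consts["e1"] * S + consts["e2"] * S * (S - 1)
    result.D = (k_hat - S / consts["a1"]) / math.sqrt(variance)
    return result


# ---------------------------------------------------------------------------
# concordance

@dataclass
class ConcordanceReport:
    sites: int
    compared: int
    concordant: int
    percent: float
    matrix: dict[tuple[str, str], int] = field(default_factory=dict)
    discordant: list[tuple[str, object, Optional[float]]] = field(
        default_factory=list)


# A call is "gt", ("gt", allele_ratio) or ("gt", allele_ratio, major) where
# major is "ref" or "alt" (identity of the majority allele, needed to recall
# a high-ratio het to the right homozygote).
GenotypeLike = Union[str, tuple]


def _as_gt_ratio(v: GenotypeLike) -> tuple[str, Optional[float], Optional[str]]:
    if isinstance(v, str):
        return v, None, None
    gt = v[0]
    ratio = v[1] if len(v) > 1 else None
    major = v[2] if len(v) > 2 else None
    return gt, ratio, major


def concordance(calls_a: Mapping[tuple, GenotypeLike],
                calls_b: Mapping[tuple, GenotypeLike],
                apply_reassignment: bool = False,
                cfg: Optional[FilterConfig] = None) -> ConcordanceReport:
    """Pairwise genotype agreement between two call sets keyed by
    (sample, site).

    Values are genotype strings, (genotype, allele_ratio) or
    (genotype, allele_ratio, major_allele) tuples; missing genotypes are
    excluded.  With ``apply_reassignment``, heterozygous calls in A whose
    allele ratio is at or above the homozygous threshold are recalled to
    homozygous of their own major allele before comparing (hets lacking
    major-allele information are left as hets).
    """
    if cfg is None:
        cfg = FilterConfig()
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("no overlapping (sample, site) keys")
    compared = concordant = 0
    matrix: dict[tuple[str, str], int] = {}
    discordant: list[tuple[str, object, Optional[float]]] = []
    site_ids = set()
    for key in shared:
        gt_a, ratio_a, major_a = _as_gt_ratio(calls_a[key])
        gt_b, _, _ = _as_gt_ratio(calls_b[key])
        if gt_a == "missing" or gt_b == "missing":
            continue
        if apply_reassignment and gt_a == "het" and ratio_a is not None \
                and ratio_a >= cfg.hom_ratio_threshold and major_a:
            gt_a = "hom_ref" if major_a == "ref" else "hom_alt"
        compared += 1
        site_ids.add(key[1] if len(key) > 1 else key)
        matrix[(gt_a, gt_b)] = matrix.get((gt_a, gt_b), 0) + 1
        if gt_a == gt_b:
            concordant += 1
        else:
            discordant.append((key[0], key[1] if len(key) > 1 else key,
                               ratio_a))
    if compared == 0:
        raise ValueError("no comparable non-missing genotypes")
    return ConcordanceReport(
        sites=len(site_ids), compared=compared, concordant=concordant,
        percent=100.0 * concordant / compared, matrix=matrix,
        discordant=discordant,
    )


def calls_for_concordance(genotype_calls) -> dict[tuple, tuple]:
    """Index GenotypeCall objects as (sample, site) -> (gt, ratio, major)
    for :func:`concordance`."""
    out = {}
    for c in genotype_calls:
        ad_ref = c.allele_depths.get("ref", 0)
        ad_alt = c.allele_depths.get("alt", 0)
        major = "ref" if ad_ref >= ad_alt else "alt"
        out[(c.sample_id, c.site_key)] = (c.genotype, c.allele_ratio, major)
    return out
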