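# ampseq

Toolkit for analysing multiplexed, dual-barcode targeted amplicon sequencing
of insecticide-resistance loci (e.g. *vgsc*, *ace-1*, *rdl* panels in
*Aedes aegypti*-style assays).

Pools are built by tagging each mosquito's PCR products with a unique
(forward, reverse) pair of 6bp inline barcodes across all panel loci.  The
toolkit:

* **panel** — data model and I/O for the amplicon panel (primers with IUPAC
  degenerate bases, reference inserts, CDS geometry, known resistance
  sites), sample sheets and filter thresholds;
* **simreads** — a seeded pool simulator emitting barcoded 250bp read pairs
  with configurable per-sample diploid genotypes, substitution error and
  barcode mistagging, plus a per-read truth table (a demonstration 11-locus
  panel with synthetic inserts is built in, so nothing needs downloading);
* **demux** — assignment of read pairs to (sample, locus) by dual barcode +
  primer match, mistag removal, technical-sequence trimming, conservation-
  checked statistics;
* **varcall** — glocal alignment to the reference insert, quality-filtered
  pileups (phred >= 30 per counted base, mate overlaps counted once),
  SNP/indel calling (min depth 50, min allele depth 10) and allele-ratio
  diploid genotyping (hets with major-allele ratio >= 0.8 recalled to
  homozygous);
* **cohort** — merging across samples and overlapping amplicons, retention
  filtering (variant in >1 mosquito and >=2 independent pools), coding and
  splice-region consequence annotation, multi-sample VCF 4.2 output;
* **popgen** — allele frequencies, MAF spectrum, Hardy-Weinberg chi-squared
  tests, Tajima's D (validated against a brute-force pairwise oracle) and
  genotype concordance between call sets (optionally applying the
  0.8-ratio homozygous reassignment).

## CLI

```sh
ampseq panel-validate --panel panel.tsv --inserts inserts.fasta
ampseq simulate --panel ... --inserts ... --sheet sheet.tsv \
    --genotypes genotypes.tsv --pool P1 --coverage 100 --seed 1 --out pool1
ampseq demux --panel ... --inserts ... --sheet sheet.tsv \
    --r1 pool1.R1.fastq.gz --r2 pool1.R2.fastq.gz --out demuxed/
ampseq call --panel ... --inserts ... --sample-dir demuxed/ \
    --sample S001 --out calls/S001.tsv
ampseq cohort --panel ... --inserts ... --calls calls/ --sheet sheet.tsv \
    --out cohort          # cohort.vcf + retention/consequence TSVs
ampseq popgen --vcf cohort.vcf --out stats
ampseq concord --a run1.vcf --b run2.vcf --reassign
```

File formats are plain text: tab-separated panel/CDS/sample-sheet tables, a
FASTA of reference inserts, gzip FASTQ for reads and VCF 4.2 for cohort
output (see `ampseq/panel.py` docstrings for column definitions;
coordinates are 1-based inclusive in files).

The Python API mirrors the CLI; `ampseq.run_study` drives the whole
pipeline from read streams to a filtered, annotated cohort table:

```python
import ampseq

panel = ampseq.demo_panel()
sheet = ampseq.demo_sheet(samples_per_pool=20, n_pools=2)
spec = ampseq.random_genotype_spec(panel, sheet, {("Rdl_Aeg", 230): 0.6})
pools = {
    pid: ampseq.simulate_pool(panel, sheet, spec,
                              ampseq.SimConfig(coverage=100, seed=i),
                              pool_id=pid).pairs()
    for i, pid in enumerate(sheet.pool_ids)
}
result = ampseq.run_study(panel, sheet, pools)
print(result.table.retained_sites())
```

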