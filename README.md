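# arvc — androgen-receptor splice-variant compendium and quantification

`arvc` detects and quantifies androgen receptor (AR) splice variants
(AR-Vs) such as AR-V7, AR-V3 and AR45 from cohort RNA-seq alignments.
AR-Vs — AR mRNA isoforms that incorporate cryptic exons or lose the
ligand-binding domain — are candidate biomarkers of resistance to
AR-directed therapy in metastatic castration-resistant prostate cancer
(mCRPC). The package is aimed at computational biologists who have
aligned, duplicate-marked RNA-seq (SAM/BAM with `XS` strand attributes,
e.g. from a STAR alignment) and want a reproducible junction-level
inventory of AR-Vs across a cohort.

## Method

1. **Junction extraction.** All primary-aligned, properly paired,
   non-duplicated spliced alignments overlapping the AR locus
   (GRCh37 `chrX:66763863-66951462:+` by default) are collected per
   sample; every `N` CIGAR gap yields one splice junction
   `(chrom, donor, acceptor, strand)` with intron-anchored, 1-based
   coordinates.
2. **Recurrence filter & compendium.** Junctions supported by ≥ 5
   strand-correct spliced reads in ≥ 10 samples are flagged recurrent
   and merged with a user-editable table of literature variant-defining
   junctions into a variant compendium.
3. **Relative expression.** For sample *s* and variant *x* with
   distinctive junction support SJ_x and canonical exon1→exon2 support
   SJ_E1E2,

   &nbsp;&nbsp;&nbsp;&nbsp;y(s, x) = 100 · SJ_x(s) / SJ_E1E2(s)  [%]

   A sample is called positive for a variant at y ≥ 1%. Samples with
   SJ_E1E2 = 0 are *undefined*, not 0%; variants without a usable
   distinctive junction (AR-V11) are *exempt*, never silently zero.
4. **Cohort statistics.** Prevalence and oncoprint (memo-sort)
   co-occurrence ordering; two-sided Mann–Whitney comparison of
   normalized AR expression between AR-V-positive and negative samples
   (Benjamini–Hochberg adjustment for the per-count pairwise family);
   univariate screening (p < 0.05) followed by multivariate OLS of
   relative variant expression on clinical covariates, on complete
   cases; single-treatment subgroups retained at ≥ 10 patients.

A seeded synthetic-cohort generator (`arvc simulate`) emits SAM files
from a toy AR-like gene with known variant fractions, contamination and
clinical covariates, so the whole pipeline is testable without access to
restricted patient data.

## Worked example

```bash
arvc demo --seed 1 --out demo/
```

simulates a 30-sample cohort (reference depth 300×, six variants at
realistic prevalences, an enzalutamide effect on AR-V7) and runs every
stage. It prints:

```
stages complete: extract, compendium, quantify, stats
variant  n_positive  n_total  prevalence_pct
   AR45          17       30            57.0
  AR-V3          14       30            47.0
  AR-V7          11       30            37.0
  AR-V9           1       30             3.0
  AR-V1           1       30             3.0
   AR23           1       30             3.0
```

i.e. 17 of 30 samples carry AR45 at ≥ 1% of canonical AR junction
support, and so on. `demo/results/` contains the junction table, the
compendium with recurrence annotation, per-sample relative expression,
the clinical regression tables, the oncoprint ordering and a
`recovery_report.tsv` comparing the estimates with the simulator's
ground truth (here: zero positivity-call errors, RMSE ≈ 2·10⁻⁶ %).
The `manifest.json` echoes the full configuration with output checksums;
reruns with the same seed are byte-identical.

The stage commands `arvc extract`, `arvc compendium`, `arvc quantify`
and `arvc stats` run the same steps on real data; see `arvc --help`.
The bundled GRCh37 definition table carries the canonical exon1→exon2
reference junction and placeholder variant rows whose cryptic-exon
coordinates must be filled in from your annotation source before a
real-data run.

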