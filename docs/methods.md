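# Methods

## Problem and model

Androgen-receptor splice variants (AR-Vs) are detected from splice
junctions: a variant transcript that incorporates a cryptic exon, or an
alternative first exon (AR45-style), produces at least one splice
junction absent from the canonical 8-exon AR transcript. Read support
for that distinctive junction, relative to support for the canonical
exon 1 → exon 2 junction, is a per-sample measure of the variant's
relative expression that cancels library size and locus-level coverage:

    y(s, x) = 100 · SJ_x(s) / SJ_E1E2(s)   [percent]

This is a junction-ratio estimator, not isoform deconvolution: each
variant is quantified by a single designated distinctive junction, and
junctions shared between isoforms are never apportioned. Variants
without any usable distinctive junction (AR-V11) are carried in the
compendium but exempt from quantification.

## Coordinates and junction identity

Junctions are intron-anchored, 1-based, inclusive: `donor` is the first
intronic base after the upstream exon and `acceptor` the last intronic
base before the downstream exon, matching the common splice-junction
table convention. `(chrom, donor, acceptor, strand)` is the identity
key. Strand comes from the spliced read's `XS` attribute; a record
without it cannot satisfy strand matching and is tallied
"strand-unresolved" rather than failing the run.

## Alignment filters

Defaults: primary (secondary and supplementary excluded), properly
paired, non-duplicated, strand-matching the locus. No mapping-quality
cut is applied; multimappers are handled via the primary-alignment
requirement only. A record overlaps the locus if any gapless aligned
block intersects it — a read whose intron merely spans the interval does
not count. Junctions on an overlapping read are retained even if their
endpoints fall outside the interval. Each alignment record contributes
one count per junction it spans; mate pairs both spanning a junction
count twice (per record, documented rather than collapsed, since
fragment-level deduplication is upstream's concern).

## Recurrence filter

A junction is recurrent when at least `min_reads` (default 5)
strand-correct spliced reads support it in each of at least
`min_samples` (default 10) samples — per-sample support first, then the
sample tally. An alternative reading (cohort-wide summed support ≥
`min_reads` with any support in ≥ `min_samples` samples) is available as
`mode="cohort-total"`. Recurrence never gates quantification of
literature-defined variants; it is carried as an annotation.

## Positivity and prevalence

A sample is positive for a variant at relative expression ≥ 1%
(inclusive). Samples with zero reference support are *undefined* —
distinct from 0% — and are by default kept in prevalence denominators as
non-positive (prevalence out of all samples); `exclude_undefined`
switches to defined-only denominators. Values carry full precision
internally; prevalence is rounded to integer percent and summary
percentages to one decimal only at report time.

## Statistical machinery

* Mann–Whitney U (two-sided): exact null distribution when both groups
  have ≤ 8 tie-free observations, otherwise the normal approximation
  with midrank tie correction (scipy backend). Verified in the test
  suite against exhaustive enumeration of all group assignments at
  (3,3) and (6,6).
* Benjamini–Hochberg step-up q-values over the pairwise family of
  per-variant-count group comparisons (statsmodels backend); singleton
  groups are skipped with notice.
* Clinical regressions: ordinary least squares on complete cases only.
  The univariate screen tests each covariate separately per variant at
  p < 0.05 with no multiplicity correction across the screen (the
  selection step is deliberately liberal); all selected covariates then
  enter one multivariate model per variant, and coefficients at
  p < 0.05 are reported as retained. Constant covariates and fits
  without residual degrees of freedom are flagged inestimable; perfectly
  collinear features are dropped with notice. Samples with undefined
  relative expression are excluded per variant.
* Single-treatment subgroups: patients whose indicator row sums to one,
  grouped by that agent; groups below 10 patients are dropped.
* Oncoprint ordering: variants by descending prevalence (name
  tie-break); samples by their positivity bit pattern read in variant
  order, sorted descending as a binary number (memo-sort), with sample
  id as the deterministic tie-break. The ordering is invariant to input
  order.

## Synthetic cohorts

The generator emulates a cohort of spliced reads over a toy AR-like gene
(8 canonical exons, 5 cryptic exons, one alternative first exon) on a
20 kb contig. Reads are junction-spanning two-block records
(`50M <intron> 50M`) because only junction support enters any
computation in scope. Per sample:

* every canonical junction draws Poisson(depth) reads (default depth
  300); the exon1→exon2 draw is the reference;
* each active variant draws Binomial(reference draw, fraction) reads —
  fraction is the configured relative expression. Contamination
  re-flags each drawn read as duplicate / secondary / wrong-strand with
  the configured rates (defaults 5% / 2% / 2%); because both reference
  and variant reads are thinned at the same rates, the surviving-read
  ratio remains an unbiased estimate of the configured fraction. A
  separate `duplicate_rate_variants` override exists to silence variant
  support selectively (rate 1.0 removes all qualifying variant reads).
* unspliced reads (20% of depth) and sporadic noise junctions at random
  coordinates (2% of depth) exercise the upstream filters;
* clinical covariates: age ≈ N(67, 8) truncated to 46–85, treatment
  indicators at the observed cohort probabilities (docetaxel 0.826,
  enzalutamide 0.526, cabazitaxel 0.258, abiraterone 0.235,
  radium-223 0.131), treatment-line counts derived from the indicators,
  and 23.4% of records with the treatment block missing. A configured
  treatment effect multiplies a variant's fraction in treated patients,
  giving the regressions a recoverable signal; an optional expression
  shift raises sequencing depth (hence normalized AR expression) in
  variant-positive samples for the group tests.

Default variant set and conditions: AR45 5% fraction at 0.66
prevalence, AR-V3 2%/0.41, AR-V7 2%/0.37, AR-V9 1.5%/0.12,
AR23 1.5%/0.08, AR-V1 1.5%/0.06, over 30 samples.

All randomness flows through one `numpy` Generator seeded from
`rng_seed`, and counts are drawn as integers, so cohorts (SAM bytes and
truth tables) are bit-reproducible across runs.

**What the simulator does not model:** sequence content, base
qualities, alignment error, soft-clipping, chimeric reads, fragment-
level mate correlation, expression outside the locus and genuine
isoform-level read sharing. Passing recovery tests therefore
demonstrates correctness of the counting, filtering and ratio
arithmetic under the stated sampling model — not robustness to aligner
artifacts on real data.

## Numerical and design choices

* The relative-expression ratio is computed as variant over reference;
  the quantity is a percentage of canonical AR junction support and all
  cohort uses (values well below 100%) fix this orientation.
* 0/positive = 0% (true zero), anything/0 = undefined (NaN); the two
  are never conflated downstream.
* Prevalence rounding uses `np.rint` (half-to-even is irrelevant at the
  printed values).
* The bundled GRCh37 definition table ships the canonical exon1→exon2
  reference junction with placeholder variant rows: published
  cryptic-exon coordinates vary between annotation sources, so the
  table is deliberately a user-supplied input and pipeline correctness
  is established on synthetic coordinates instead.
* Test problem sizes (15–30 samples, depths 100–1000, hundreds of
  simulation replicates for the null-rate checks) were chosen as the
  smallest cohorts at which the binomial sampling envelopes and nominal
  error rates are informative.

## Known limitations

* Per-record counting slightly overweights junctions spanned by both
  mates of a fragment.
* The recurrence filter's per-sample reading is one of two defensible
  interpretations; both are implemented, only the default is used in
  the analyses.
* Exact Mann–Whitney is only engaged for tie-free small groups; heavily
  tied small-sample data fall back to the asymptotic approximation.
* The multivariate model assumes homoscedastic Gaussian errors on a
  percentage response; with many zero-valued samples a two-part or
  Tobit-style model would be more faithful, but OLS matches the
  analysis this package reproduces.
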