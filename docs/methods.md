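# Methods

This note documents the statistical procedures, parameter choices, and
numerical conventions implemented in `svharmony`, and what the synthetic
data generator does and does not emulate.

## Replication rate

For one site and a set of replicate pairs (two samples sharing a donor
genome), the replication rate is

    RR = (# pairs with matching non-reference genotypes)
       / (# pairs with at least one non-reference genotype)

A pair with a missing genotype in either member is dropped from both
numerator and denominator; missingness is policed separately by the
call-rate filters. Two concordance definitions are provided because
"matching" is genuinely ambiguous for a (het, hom-alt) pair:

- `strict` (default): both genotypes identical and non-reference. This is
  the conservative reading and the package default.
- `nonref_only`: both non-reference, regardless of allele count.

For multiallelic CNVs the genotype channel is the integer copy number;
"non-reference" means different from the modal copy number across samples,
and concordance means equal copy number. Class-level RR is the unweighted
mean over sites with a defined RR.

Threshold sweeps restrict to sites with the metric present and report the
count and mean RR at each cut. Comparison direction follows each metric's
published convention: MSQ is strict (`> t`), GSCNQUAL and QUAL are
inclusive minima (`>= t`).

## Hard filters

Filters are rule lists applied per record; each record receives an ordered
set of reason codes, so planted-count audits are exact and filters are
idempotent. Two interpretation choices were open and are resolved as
follows:

- The SpeedSeq breakend evidence rule ("25% support from split or
  paired-end reads") is computed as (SR + PE) / SU, with SU the caller's
  total-support count.
- The inversion evidence rule applies only to inversions with QUAL > 100;
  lower-QUAL inversions still face the MSQ > 90 rule.
- HipSTR per-call failures convert the genotype to missing rather than
  dropping the site; the site-level rule then requires > 80% call rate in
  every designated sample subset.
- Large-CNV carrier copy-number rules (> 2.75 for duplications, < 1.25 for
  deletions) are evaluated on the carrier samples' copy numbers (the
  max for duplications, the min for deletions).

## Redundancy graphs

All clustering is connected components of an explicit pair graph, processed
in sorted (chrom, start, site_id) order so output never depends on input
order. Conventions that the source procedures leave open:

- A Pearson correlation with zero variance in either vector is undefined
  and fails the threshold: a monomorphic genotype row carries no evidence
  that two records are the same variant.
- The "< 5% non-mode genotype difference" rule uses as denominator the
  union of samples that are non-mode at either site.
- Quality ties break to the lexicographically smaller site id, for
  determinism.
- Allele-balance correlations are computed over all samples (not only
  non-reference carriers).
- Sex chromosomes are out of the default path; the generator emits
  autosomal-style contigs only.

Stitching builds a per-chromosome correlation graph (copy-number r > 0.9),
sorts each component by position, and merges adjacent pairs that also show
>= 80% concordance among the union of non-mode samples and lie within 30 kb.
The stitch interval spans min start to max end; when one member already
covers the whole interval it is flagged as a pre-existing breakpoint.
`validate_stitch` accepts a genotyped stitch row from outside (re-genotyping
from reads is out of scope) and unstitches below mean r = 0.9, filtering new
breakpoints with > 10% low-quality genotypes or no polymorphism.

## Unification

Stage 1 links type-compatible cross-caller pairs (same class; mCNV with
DEL/DUP; DEL with rMEI) with reciprocal overlap > 0.5 or full containment at
>= 40% of the larger length. Stage 2 re-tests every pair within a stage-1
component on genotype evidence: squared Pearson correlation of the caller's
native channel (copy number for read-depth calls, allele balance for
read-pair calls; cross-channel between them, over shared samples). The
general threshold is R² > 0.5; a component containing a SpeedSeq duplication
and deletion together with a Genome STRiP mCNV relaxes to R² > 0, because a
multiallelic site legitimately splits its signal across the two biallelic
views. The cross-channel statistic is this package's construction — the
source procedure does not define one — and is the natural generalization of
"genotype correlation" to heterogeneous evidence. Primary selection is
degree-then-quality per caller (ties to smaller id), read-depth primary by
default, read-pair primary when a deletion pairs with an rMEI.

## Cohort QC

Both tests are plain chi-squared without continuity correction. The batch
test compares full genotype-category distributions (missing included as a
category; zero-total categories dropped) between the two studies; the HWE
test compares observed biallelic genotype counts to expectations from the
estimated allele frequency with df = 1, zero-expected cells contributing 0.
Bonferroni m is the number of sites actually tested in the family. mCNVs
are batch-tested on full copy-number categories rather than collapsed.

## IRS validation

Array probe intensities are first residualized on batch/plate covariates by
per-probe least squares. For each CNV overlapping >= 3 probes, each probe's
residuals are ranked across samples, ranks are summed into one score per
sample, and carrier scores are compared to non-carrier scores with a
one-sided Mann–Whitney test (deletions: carriers lower; duplications:
carriers higher; mCNVs take the sign of the mean carrier deviation). Summing
ranks *before* the single rank test keeps the null exact even though probes
within a site share sample-level noise — a pooled probe-by-sample rank sum
would be anticonservative under that correlation. The procedure is this
package's own documented construction (the upstream annotator's internals
are not published) and is validated by permutation calibration. The
call-set FDR estimate is 2 × P(p >= 0.5) over tested sites, with both the
factor and the cut point configurable.

## LD tagging

For each SV/STR passing an optional site mask, the dosage is the alt-allele
count (biallelic), the copy number (mCNV), or a supplied repeat-length
deviation (STR). The report is the maximum squared Pearson correlation
against all SNP/indel dosages within ±50 kb of the SV boundaries, computed
on shared non-missing samples; sites with zero dosage variance or no SNP in
the window report NA.

## Synthetic data generator

Defaults mirror the targeted study design: 477 donors in two studies
(iPSCORE-style blood samples including 25 MZ twin pairs; HipSci-style
fibroblast/iPSC samples including 152 fibroblast–iPSC pairs), superpopulation
mix ~87% EUR, loci on three 10-Mb contigs (desk scale). Per class the
generator plants truth sites with allele frequencies uniform on [0.05, 0.5]
and Hardy–Weinberg genotypes drawn per donor and copied to replicate
partners; mCNVs draw three copy-number alleles from a Dirichlet(2, 5, 2)
prior. Caller views add:

- breakpoint jitter bounded by 20 bp (default);
- symmetric genotype flips among {0, 1, 2} with probability
  `e(q) = e_max · logistic(−8(q − 0.5))`, `e_max` = 0.2, in the site's latent
  quality q — this reproduces the monotone RR-versus-quality curves that
  motivate score filtering (a flat `uniform_error` override exists for
  calibration studies);
- allele balance concentrated near 0 / 0.5 / 1 by genotype (sd 0.03),
  integer copy numbers for read-depth views;
- fragmentation of 15% of eligible read-depth CNVs into 2–5 adjacent
  pieces with identical genotype rows (the stitching targets);
- MELT flags with configured probabilities, flagged sites carrying +0.25
  extra error (so flag filtering demonstrably raises RR), ASSESS tranches
  increasing in quality;
- within-caller duplicates (10%) and labelled false positives with low
  scores and sparse random genotypes;
- probe intensities Normal(α·(cn−2)/2 + batch + plate, σ = 0.25) with >= 3
  probes per testable CNV, and one tagging SNP per truth site copying the
  SV dosage with flip probability 0.02 plus independent background SNPs.

The generator emulates the *statistical* structure the pipeline consumes —
genotype matrices, quality scores, overlap/fragment geometry — not reads,
sequence content, repeat structure, or realistic genome-wide site counts.
Passing tests therefore demonstrate the correctness and calibration of the
harmonization logic under the stated noise models, not the field accuracy
of any upstream caller.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale by design: hundreds of
sites, tens to hundreds of samples, 100-instance oracle sweeps with <= 100
records per instance, 500-replicate QC calibrations, and a 200-parent /
200-decoy stitching audit. Internal coordinates are 0-based half-open; VCF
I/O follows the padding-base convention for DEL/DUP/INV (POS on the base
before the event, SVLEN equal to the span, so END = POS + SVLEN as modern
htslib expects) and explicit END for other classes; breakends and insertions
are 1-bp point records matched by distance. Floats surviving a VCF
round-trip are rounded to 4 decimals (htslib stores float32). All emission
and the full pipeline are deterministic functions of (config, seed); rerun
outputs are byte-identical.

## Known limitations

- Genotype error is symmetric among {0, 1, 2}; real callers err toward the
  reference and with allele-frequency dependence.
- The IRS statistic is a stand-in for the unpublished annotator internals;
  its p-values are calibrated by construction but not numerically identical
  to the original tool's.
- Sex-chromosome handling (separate male/female correlation) is not in the
  default path.
- Half-missing diploid genotypes are treated as fully missing.
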