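# Methods

This note documents the models, parameter choices and numerical decisions
behind `mbdmeth`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Capture model and region definition

MBD-seq enriches methylated DNA fragments, so read density over a region is
treated as proportional to its methylation level times a region-specific
capture propensity. Coordinates are 0-based half-open throughout (BED on
disk).

**Read filtering.** Reads with mapping quality below 37 are removed;
duplicates share (sample, chrom, 5′ start, strand) — the standard
single-end duplicate key — and keep their first occurrence, so filtering is
order-stable.

**Peak calling** is a declared simplification of a capture peak caller.
Each read is extended to the 250 bp fragment length from its 5′ end along
its strand. Fixed 250 bp windows are tested with a Poisson upper tail,
λ = max(genome-wide rate, local rate over a centered 10 kb span), both
scaled by the expected fragment–window overlap length (window + fragment).
Windows with p < 1e-8 are joined when adjacent. There is no model-based
shift estimation, no FDR by control swap, and no paired-end logic; the
contract is the significance rule, not a particular caller's internals.
A window with zero fragments is never significant (P(X ≥ 0) = 1).

**Merging.** Two regions merge when their overlap exceeds 50% of the
*shorter* region (strict inequality, so exactly-half overlap does not
merge; containment always merges). The merge is single-linkage: connected
components of the pairwise relation collapse to their union span, and the
procedure repeats on the new spans until a fixpoint. This makes the result
deterministic and independent of input order, and it is what the
brute-force oracle in the tests computes by a different route (all-pairs
adjacency plus BFS). A plain left-to-right accumulator sweep is *not*
equivalent on staggered interval stacks, which is why the component
formulation is used.

**Counting and the RPM floor.** A filtered read contributes to every merged
region its extended fragment overlaps by at least one base (a fragment
spanning two regions counts in both; counts are per-region independent and
documented as such). Library size is the sample's total filtered reads.
Regions are kept iff they reach 20 reads per million in at least one
sample, boundary inclusive.

## Differential model

Counts are modelled NB with var = μ + φμ². A **common dispersion** is
estimated from the control columns only: per region, the method-of-moments
value max(0, (s² − m̄)/m̄²) on library-size-normalized counts; the common φ
is the median over regions with mean ≥ 10, floored at 1e-4. Patients are
excluded because their columns carry true effects and a single-sample
"group" has no within-group replication. The MoM median from five controls
is mildly biased low (recovery band [0.05, 0.2] at true φ = 0.1 in the
tests); calibration statements about the exact test therefore condition on
the dispersion actually used.

**Normalization** is TMM-style: scaling factors from the trimmed mean (30%
of log-ratios, 5% of abundances per tail) of per-region log2 ratios against
the largest library, over regions nonzero in both samples, rescaled to unit
geometric mean. Pseudo-counts for the exact test use simple proportional
scaling to the mean effective size (not quantile adjustment) and are
rounded to integers; this is a documented approximation.

**Exact test.** With r = 1/φ, patient count ~ NB(μ, r) and the summed
controls ~ NB(nμ, nr) share the success probability r/(r + μ), so the
patient count conditioned on the total T follows a beta-negative-binomial
law independent of μ — computed in log space from gammaln grids (cached
across regions, which keeps 100-seed power studies fast). The two-sided p
sums conditional probabilities ≤ the observed one (tolerance 1e-9 in log
space for ties). At φ < 1e-8 the law degenerates to Binomial(T, 1/(n+1)).
An all-zero region returns p = 1, log2fc = 0. Note that for φ > 0 and
n > 1 the conditional law is skewed, so a perfectly balanced split is not
always the unique mode and its two-sided p can be ~0.8–0.9 rather than
exactly 1; the Poisson and 1-vs-1 limits do give p = 1.

log2 fold change is log2((patient + 0.5)/(control mean + 0.5)) on the
pseudo-count scale; the +0.5 shrinkage avoids infinities at total loss.
BH adjustment is delegated to statsmodels (`fdr_bh`); the step-up formula
is re-derived independently in the tests. Significance is inclusive at
adjusted p ≤ 0.05, direction by the sign of log2fc; a significant region
with zero log2fc is impossible under the exact test and raises.

**Sharing** is by region identity on the merged universe (every patient is
tested on the same regions, so positional re-intersection is unnecessary)
and is direction-stratified: hypo and hyper calls at the same region never
pool. Venn cells partition (region, direction) pairs exactly.

## Annotation

TGCCGC is counted with an overlap-aware scan, by default on both strands
(forward plus forward occurrences of GCGGCA; a flag restricts to forward
only — the motif is counted on a methylated duplex and either convention is
defensible, so both are supported). Fractions "k or more" are inclusive;
"more than t datasets" is strict, matching the usual reporting of such
summaries. AMR overlap is a dataset-level indicator (≥1 bp with any
interval of a dataset). CpG islands use the classic sliding-window
criteria (200 bp, GC ≥ 0.5, observed/expected CpG ≥ 0.6 with
O/E = n_CG·L/(n_C·n_G)), overlapping qualifying windows merged; island
calls mirror exactly under reverse complement. Transcript mapping measures
from the region center to the nearest transcript 5′ end (start on +,
end − 1 on −), with "TSS-proximal" inclusive at 1 kb.

## Bisulfite arm

Sample indexes are inline 6-mers (the printed index set is only guaranteed
unique at 6 bases even where 5 are described; the demultiplexer takes an
explicit `index_len` and refuses ambiguous truncated tables). Alignment is
ungapped at every offset against the reference, for the read and its
reverse complement, with reference-C/read-T treated as conversion rather
than mismatch; best placement under a 10% mismatch budget wins (ties:
fewer mismatches, then + strand, then smaller offset). Amplicons are short
PCR products where indels are rare; rejected-read counts surface any
violation of that assumption. At covered CpGs, C calls methylated, T
unmethylated, anything else no call.

"Methylated–unmethylated ratio" is implemented as the bounded fraction
m/(m+u), not the odds m/u: fractions are averageable and consistent with
"methylation level" usage; the per-amplicon overall value is the
unweighted mean over CpGs with coverage ≥ 10 (lower-coverage CpGs are
excluded and reported; no covered CpG flags the overall value as
undefined). Concordance pairs per-individual, per-locus log2 ratios
against the control mean with ε = 0.01 added to both numerator and
denominator to avoid −∞ at total loss; a zero-variance axis flags the
correlation as undefined rather than propagating NaN.

## Synthetic cohorts

The default scenario mirrors the cohort structure the analysis assumes:
4 patients, 3 heterozygotes, 5 controls; 60 non-overlapping regions on two
200 kb contigs; 3 regions totally hypomethylated (multiplier 0) in all
four patients, six private partial losses (0.5), one private gain (2.0);
heterozygotes methylated normally. Defaults: NB dispersion φ = 0.1
(visibly overdispersed yet detectable at desk depth), 36-base reads,
250 bp fragments, 30% background reads, 5% sub-threshold-mapq reads, 5%
duplicates, 40 k reads per sample. Designated DMRs receive
Poisson(4) planted TGCCGC copies (about the two-copies-on-average scale
reported for imprinting control regions, made comfortably detectable at
n = 10 DMRs), background regions Poisson(0) by default. Region sequences
are GC-rich CpG islands on a CpG-depleted background so island detection
has signal; accidental TGCCGC/GCGGCA matches inside regions are scrubbed
before planting so the recorded truth equals a brute-force scan of the
emitted sequence. In-region counts are gamma-Poisson draws with mean
depth · weight · multiplier / Σweights; capture weights are Uniform(0.5,
1.5). All generators are byte-deterministic in the seed.

The bisulfite validation scenario uses 8 synthetic ~90 bp amplicons,
control methylation Uniform(0.25, 0.88) (the intermediate-methylation
range such loci show in blood), patient multipliers drawn from
{0.1, 0.5, 1.0}, 300 reads per sample per amplicon, 0.1% substitution
error.

**What the simulations do not capture:** real mappability and GC bias,
fragment-size variation, CpG-density-dependent capture efficiency,
paired-end information, cell-type heterogeneity, and genuine
allele-specific methylation (AMR inputs are arbitrary interval sets).
Passing tests demonstrate the pipeline's statistical behaviour under its
own model assumptions, not performance on patient libraries.

## Problem sizes in the tests

The suite keeps simulation sizes at desk scale: the null calibration uses
2000 regions × (1 patient + 5 controls); power uses 100 seeds of
100 regions sharing a depth of 1e6; end-to-end recovery uses 100 seeds of
a 30-region, 30 k-reads-per-sample cohort; concordance uses 20 seeds of
the validation scenario; oracle-equivalence checks run ≥200 random
instances per operation. Moment checks use 3-standard-error bands.

## Known limitations

* The peak caller is intentionally minimal; very broad or adjacent regions
  separated by less than one window merge at calling time.
* The common-dispersion model ignores region-specific dispersion; with
  n = 5 controls, tagwise estimation would be noise-dominated.
* Pseudo-count rounding makes the exact test slightly discrete at very low
  counts; the +0.5-shrunk fold change is biased toward zero for counts
  near zero.
* Ungapped bisulfite alignment cannot place reads across indels and does
  not model incomplete conversion (conversion failure of non-CpG C).
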