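# Methods

## Scope and model

`tohscan` tests whether *tracts of homozygosity* (TOHs) — contiguous runs of
homozygous SNP genotypes in one individual — are differentially represented
between disease cases and controls, and integrates exome-derived annotations
inside the associated regions.  The analysis unit is the *common TOH*
(cTOH): a stretch of consecutive array markers at which at least
`min_subjects` individuals simultaneously carry a TOH over at least
`min_snps` markers.  Carrier status of a cTOH is a binary per-individual
variable entering a logistic case-control model with sex and genotype
principal components as covariates.

The method assumes a dense biallelic SNP panel with known chromosome/bp
coordinates, unrelated individuals, and genotype calls of array quality
(low missingness after QC).  Linkage disequilibrium is not modelled: a TOH
is defined purely by the observed genotype string.

## TOH calling

A TOH is a maximal window on one chromosome containing at least `min_snps`
homozygous calls, at most `max_het` heterozygous and at most `max_missing`
missing calls, starting and ending on a homozygous call.  Defaults
(100 / 0 / 2) demand strict homozygosity at the 100-SNP scale used by the
cTOH definition while tolerating sporadic array dropout; all three are
configurable, and an optional physical-length floor `min_bp` is off by
default because the marker-count criterion already fixes the scale.

"Maximal" means no valid window strictly contains the reported one.  When
the interruption allowances are positive, two maximal windows can overlap
(they bridge different subsets of the allowed interruptions), so the caller
returns *every* maximal window rather than an arbitrary disjoint subset;
with zero allowances the output is provably disjoint.  The scan is linear
in the number of interrupting calls and is validated against an exhaustive
every-window oracle.

## cTOH regions and carriers

Per-marker coverage counts distinct individuals whose (unioned) TOHs cover
the position.  cTOH regions are maximal runs with coverage ≥
`min_subjects` (default 10), kept at ≥ `min_snps` (default 100) markers;
runs never cross chromosome boundaries, and the maximal qualifying run is
reported without trimming to a shared core.  An individual carries a region
when their TOHs cover at least `min_cover_frac` (default 0.9) of its
markers.  The 0.9 default counts near-complete sharing as carriage while
boundary jitter from tract ends does not; the marker-count threshold is
computed as `ceil(0.9·n − 1e−9)` so that, e.g., 90% of 150 markers is
exactly 135 despite binary floating-point representation.  Shared TOH state
is counted regardless of which homozygous allele is carried (standard
run-of-homozygosity overlap semantics).

## Quality control

Samples with genotype call rate < 0.95 are removed first, so every per-SNP
statistic is computed on retained individuals.  SNPs are then removed, in
fixed order, for missingness > 0.05, exact Hardy–Weinberg *P* < 10⁻⁷, or
MAF < 0.03.  The HWE test is the exact conditional test: given the observed
allele counts, all compatible heterozygote counts are enumerated with a
mode-anchored probability recurrence and the p-value is the total
probability of configurations no more likely than the observed one.  It is
computed on cases and controls combined (the cohort as genotyped);
a controls-only variant is a one-line change at the call site.  Checks that
have no algorithmic definition at this level (non-random genotyping
failure, pipetting contamination) are recorded in the QC report as not
assessed.

## Population-structure covariates

Genotypes are standardized per SNP as (x − 2p̂)/√(2p̂(1−p̂)) with missing
entries zeroed after centering and monomorphic columns dropped; individual
scores are the leading left singular vectors of the standardized matrix,
sign-fixed so each component's largest-magnitude entry is positive.  The
default of k = 2 components is a conventional choice for cohorts where no
substructure is expected; k is configurable.

One pipeline-level choice matters at simulation scale: the PCA input
excludes markers inside detected cTOH regions.  In a miniature genome
(8,000 markers) a single 150-marker tract shared identically by ~25% of the
cohort dominates the first principal component (correlation ≈ 0.96 with
carrier status), so adjusting for it would condition away the predictor
under test.  This mirrors the standard practice of excluding known
atypical-sharing/long-range-LD regions before stratification PCA; on a
full-size panel the exclusion is immaterial because any one tract is a
negligible fraction of markers.

## Association and multiplicity

Each region's model is logit P(case) = β₀ + β₁·carrier + β₂·sex + Σγₖ·PCₖ,
fitted by Newton scoring with convergence at max|score| < 10⁻⁸ within 50
iterations and standard errors from the inverse observed information.
Regions whose carrier column is constant are non-estimable; fits that do
not converge — or that quasi-converge with |β| > 15, the numerical
signature of separation — are flagged and excluded from the FDR adjustment
rather than reported with unreliable standard errors (a Firth-type
correction would be the natural extension).  Wald p-values use the exact
normal quantile (z = Φ⁻¹(0.975), not 1.96) for the 95% CI, and q-values
are Benjamini–Hochberg step-up computed genome-wide across all estimable
regions.

## Integration of exome annotations

Indel calls (characterized only by chromosome, 0-based start, length and
type; the affected span is [start, start+length) for both types) are
clustered across samples by interval single-linkage: two calls link when
their spans, each widened by `merge_window` (default 10 bp), strictly
overlap — robust to alignment jitter, and with window 0 exactly the
overlapping calls group.  A cluster is retained when it recurs in ≥
`min_samples` (default 3) distinct samples *and* its span overlaps an
inverted or simple repeat (the repeat condition applies at cluster level).
Genes overlapping both a significant region (q < 0.05 by default) and a
retained cluster are shortlisted with their supporting samples, clusters
and repeats.  Interval intersection is an event-driven sort-and-sweep over
0-based half-open coordinates; strand is ignored throughout.  The
per-chromosome repeat summary restricts repeats to those inside cTOH
regions and reports count, min/max/mean length and the number of genes hit;
by default only the inverted class is summarized.

## Synthetic data

The cohort generator emulates a Human610-Quad-scale panel: exponential
marker spacing with mean 5 kb (≈ the genome-wide average spacing of a
~570k-SNP array), per-SNP allele frequencies uniform on a configurable MAF
band ((0.05, 0.5] by default), Hardy–Weinberg genotypes, independent 1%
per-call dropout, and optional two-subpopulation structure with
Balding–Nichols subpopulation frequencies Beta(p(1−F)/F, (1−p)(1−F)/F).
Planted tracts overwrite carrier genotypes (after dropout, so tract spans
contain no missing call) with the locally major allele at every tract SNP,
making carriers identical homozygotes across the span; carrier flags are
drawn Bernoulli per group and recorded as ground truth.  Default study
dimensions — 100 cases + 100 controls, 4 chromosomes × 2,000 SNPs, one
150-SNP tract at carrier probabilities 0.30/0.10 (implied odds ratio
3.857, inside the 2.4–8.4 range typical of over-represented regions in
this kind of scan) — keep a full replicate under ~1 s so hundreds of
replicates fit in a routine test run.

The exome generator draws indel lengths uniform on [1, 191] bp and repeat
lengths log-uniform on [39, 21 947] bp across eight samples, plants one
gene satisfying the full integration filter inside a cTOH region, and adds
three decoys that each fail exactly one conjunct (two-sample cluster;
recurrent cluster with no repeat; everything right but outside every
region).  Background indels are placed clear of the cTOH regions so the
expected shortlist equals the recorded truth exactly.

What the simulator does *not* emulate: linkage disequilibrium and
haplotype structure (tracts arise only where planted, so background TOH
rates are far below real-cohort levels), genotyping batch effects,
relatedness, and sequence-level error processes.  Passing tests therefore
demonstrate correctness of the machinery and calibration under the stated
generative model, not performance on real arrays where background
homozygosity is pervasive.

## Randomness and determinism

Every stochastic component draws from child streams of a single
`SeedSequence`, one stream per stage, so outputs are bit-identical given a
config and adding a stage never perturbs the others.  Replicate studies
derive per-replicate seeds the same way (kept below 2³¹).  Two pipeline
runs with the same configuration produce byte-identical tabular outputs;
only the run log carries timestamps.

## Known limitations

- No LD-aware or likelihood-based (HMM) tract calling; allowances are hard
  counts, not genotyping-error rates.
- Separation is excluded, not corrected; rare-carrier regions in small
  cohorts may go unreported.
- The FDR is computed over regions discovered in the same data
  (selection and testing are not independent; this mirrors the standard
  practice for this design).
- PED parsing assumes biallelic markers and maps a monomorphic SNP's single
  observed allele to the A (reference) state.
- bp spans of tracts/regions run from the first to the last covered marker;
  physical boundaries between markers are unknowable at array resolution.
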