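# Methods

`tmbsim` is an in-silico framework for asking how the technical choices of a
panel-based tumor mutation burden (TMB) assay — panel size, somatic-mutation
detection accuracy, the psTMB computation rules, and the VAF cutoff — affect
the accuracy of the whole-exome TMB estimate the panel reports. This note
documents the models, the defaults and why, the numerical choices, and what
a green test does and does not establish.

## Core quantities

**wesTMB / psTMB.** TMB is a mutation count per megabase of interrogated
coding region. The reference quantity, wesTMB, applies the harmonized
whole-exome filter (six coding variant classes — missense, nonsense, and the
four in-frame/frame-shift indel classes — with VAF ≥ 5%, depth > 25, alt
count > 3, both comparisons strict) and divides by the exome's exonic size.
psTMB divides the *apparent* mutation count inside a panel's target
intervals by the panel's exonic size in Mb. Panel size means exonic target
size only; when a panel is assembled from genes, all exons of each member
gene are included.

**Detection-error model.** Somatic mutation detection with recall *r* and
precision *p* reports, in expectation,

    apparent = true · (1 + 1/p − 1/r) = true · (1 + rgbrp)

where `rgbrp = 1/p − 1/r` is the *reciprocal gap between recall and
precision*. The implementation evaluates this formula verbatim as the model
under test, although textbook confusion-matrix algebra would give
`apparent = true · r/p`; the two agree only at `r = p` or `r = 1`. On the
experiment grid the constraint `r ≥ p` keeps `1 + rgbrp ∈ [1, 2]`, so the
floor-at-zero never triggers there. Two modes exist:

* *expected-count* (default): the fractional expectation above;
* *stochastic*: true calls kept independently with probability *r*
  (false negatives), plus a Poisson number of injected false positives whose
  mean tops the expectation up — unbiased for the expected-count value,
  seeded and reproducible.

A consequence worth stating explicitly: in expected-count mode the profile
multiplies every sample's count by the same positive constant, and the
ordinary-least-squares psTMB→wesTMB recalibration absorbs any positive
scale into its slope. Expected-count metrics after recalibration are
therefore *exactly invariant* across profiles, and the
"balance beats imbalance" property holds with equality. The stochastic mode
is where detection balance genuinely moves the error, because false
positives and false negatives stop cancelling sample by sample.

**Error metrics.** Continuous accuracy is RMSLE,
`sqrt(mean((ln(e+1) − ln(r+1))²))` with natural logs, chosen because TMB is
right-skewed and log differences damp hypermutators. Discrete accuracy is
`(TP+TN)/(TP+TN+FP+FN)` on the binary TMB-H / non-TMB-H call at a 10 mut/Mb
cutoff; ternary submissions (TMB-M, TMB-L) are collapsed to non-TMB-H
before scoring. Classification ties go high (`TMB-H iff tmb ≥ cutoff`),
matching the ≥ 10 mut/Mb companion-diagnostic convention. Estimated wesTMB
from the linear model is floored at zero before logging or classifying.

## Synthetic cohort generator

The generator states a cohort, it is not a tuning knob. Defaults:

| parameter | default | rationale |
|---|---|---|
| n_samples / n_genes | 500 / 2000 | desk-scale stand-in for a pan-cancer exome cohort |
| wesTMB law | log-normal, log-mean ln 2.5, log-sd 1.0 (mut/Mb) | right-skewed bulk with median ≈ 2.5 mut/Mb and a minority above 10 |
| hypermutators | 3% of samples, ×10 | POLE/MSI-like tail |
| tumor purity | Uniform(0.2, 0.9) per sample | typical clinical tissue range; stored because the VAF×purity experiment rescales against it |
| variant classes | ≈ 62% missense, 22% silent, 4% nonsense, 3% splice, ~6.5% indels, rest minor | approximate exome class frequencies |
| clonal fraction | 75% fully clonal (1.0), 25% subclonal Uniform(0.1, 1) | most somatic variants in a tumor are clonal; the clonal mass makes purity-diluted VAF cutoffs behave like cell-line dilution series |
| VAF | 0.5 × purity × clonal_fraction, observed through depth | heterozygous diploid somatic variant |
| depth | negative binomial (Gamma–Poisson), mean 300, shape 5 | capture-panel-like overdispersion |
| hotspots | 5% of genes eligible, 20% of their mutations flagged | recurrence concentrated in a small gene subset |

Mutation loci are uniform over exonic bp; counts are Poisson at the latent
TMB times exome Mb; alt counts are binomial(depth, VAF) and zero-alt calls
are dropped as undetectable. The stored per-sample reference wesTMB is the
*realized* filtered count over the exome, so recomputing wesTMB from the
emitted MAF reproduces it exactly (a self-consistency anchor used by the
tests). The generator does **not** model trinucleotide signatures, strand
bias, germline leakage, FFPE artifacts, or copy-number-driven VAF shifts; a
green test establishes that the pipeline's arithmetic and qualitative
trends are right under the stated world, not that real-cohort thresholds
(e.g. absolute Mb cutoffs) transfer.

## Panels and panel families

Panels are merged, per-chromosome, 0-based half-open interval sets with a
member-gene set; BED input/output follows the standard convention, MAF I/O
converts to 1-based at the boundary. Synthetic panel families are grown by
real-world gene popularity: genes are ranked by how many real panel designs
cover them (ties shuffled within a tier under a seed, since no canonical
tie rule exists) and added a configurable number per step, each with all
its exons, yielding a nested family with strictly increasing size. The
default step is 1 gene; the curves in the tests use coarser steps for
speed and say so.

## The grid experiment

A method = (panel × computation rule × detection profile). The rule axes
are five optional class-inclusion flags (synonymous, nonsense, nonstop,
splice site, translation start site), hotspot filtering, and a VAF cutoff
in {1, 2, 3, 5, 10}%; profiles run over a 0.1-step recall/precision lattice
on [0.5, 1.0] restricted to recall ≥ precision (the step is a package
choice; only the range is given upstream). Evaluation: the cohort is split
8:1:1 ten times (one shared split sequence across grid combinations, for
variance reduction); each repetition fits OLS wesTMB ~ psTMB on train; the
winner is selected by validation R² with ties broken by lower validation
RMSLE then lower repetition index (the upstream selection criterion is
ambiguous between three metrics; this ordering is the package's
documented choice and is configurable in code); test-split R², RMSLE and
discrete accuracy are reported. Zero-variance training psTMB flags the
result degenerate and excludes it from curves, except in the VAF×purity
grid where the constant predictor (train-mean wesTMB) stands in — a lab
whose filter removes every mutation still reports a TMB.

**Efficiency thresholds.** Best score per panel size is made monotone by
isotonic regression, lightly smoothed (endpoint-preserving 3-point moving
average), and two thresholds are read off: the smallest size reaching 95%
of the plateau (fitted value at the largest size), and the knee — the
interior point of maximum distance between the curve and the chord joining
its endpoints after normalizing both axes to [0, 1] (a deterministic,
parameter-free kneedle criterion). Because "95% of optimum" is ill-posed
for a loss, RMSLE is first mapped through the order-preserving bounded
score `exp(−RMSLE) ∈ (0, 1]`.

**Rule importance.** Per panel, the top combinations are those jointly at
or above the 95th percentile of R² and discrete accuracy and at or below
the 5th percentile of RMSLE (joint, not marginal — the stricter reading).
Per rule the summary counts panels where ≥ 1 / 100% / 0% of top
combinations include it; `matters_pct` is the share of panels whose top
combinations are unanimous either way.

**VAF × purity.** Dilution to a target purity rescales each observed VAF by
`target / original` (dilution only — never above the original); samples
whose original purity is below the target are skipped with a warning. Each
(purity, cutoff) cell refilters at the cutoff and recalibrates, so a cutoff
that removes a roughly constant fraction of calls per sample is absorbed by
the slope, and accuracy only collapses when the cutoff eats into the clonal
VAF mass (e.g. a 10% cutoff at 10% purity, where clonal VAF ≈ 5%).

## EQA scoring

Consensus truth sets keep variants reported by ≥ 3 of 4 replicate WES call
sets (exact key match after normalization: shared ref/alt suffixes then
prefixes are trimmed, with the position advanced; full left-alignment
against a reference FASTA is deliberately out of scope), with the mean VAF
over supporting sets and a credibility flag at the empirically validated
9% VAF floor. Diluted samples inherit the truth set with VAFs multiplied by
the dilution fraction; variants falling under the floor are retained but
flagged, not dropped. Variant scoring restricts truth to the submitting
panel's intervals (off-target truth would be unfair false negatives;
configurable off) and reports recall, precision, F1 and the observed rgbrp,
with zero-denominator ratios reported as undefined rather than zero. TMB
scoring computes RMSLE only on samples at ≥ 40% simulated purity, discrete
accuracy on all scored samples, and counts TMB-H calls on negative-control
samples separately. The reference wesTMB is the mean over a configurable
assay subset, so a low-quality assay can be excluded without code changes.

## Factor ranking

Grid results are encoded one row per combination with recall/precision
collapsed to the single signed rgbrp scalar (removing their collinearity by
construction); constant columns are dropped and |Pearson r| > 0.9 pairs are
flagged. A gradient-boosting regressor (squared-error loss, 200 shallow
trees — fixed rather than searched, because ranking stability, not model
quality, is the goal) is fitted per target metric and explained with exact
tree-path-dependent Shapley values, computed in-package by enumerating the
subsets of each tree's own split features (features a tree never uses carry
zero value, so the subset lattice is small for shallow trees; conditional
expectations are cover-weighted). The attribution is exact, deterministic
under the seed, and satisfies the efficiency property, which the tests
assert against the model's own predictions.

## Numerical choices and degenerate inputs

* VAF comparisons are inclusive (`vaf ≥ cutoff`); depth/alt-count are
  strict (`>`), mirroring the reference filter's wording.
* Derived seeds come from CRC32 of `(base_seed, purpose, index)` — stable
  across platforms and sessions, always < 2³¹.
* Empty mutation lists filter to empty; empty panels, empty BED files,
  invalid proportions, negative TMBs and mismatched vector lengths raise
  `ValidationError` naming the offending field.
* Chromosome-name mismatches in interval intersection warn and return zero
  hits rather than raising, since mixed "chr1"/"1" inputs are a data issue
  the caller may want to survive.

## Known limitations

* Expected-count mode cannot show detection-balance effects after
  recalibration (see above); use stochastic mode for that question.
* Synthetic exomes are small (a few Mb), so counting noise is larger than
  in a 30-Mb exome at the same TMB; trends, not absolute thresholds, are
  the reproducible object.
* The truth-set matcher does not left-align against a reference genome, so
  differently-placed representations of the same indel in repeat context
  can fail to match.
* Hotspot status is an input flag; no external database is queried.
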