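# Methods

## Overview

`urocnv` estimates tumor-derived copy-number abnormality in cell-free DNA
(cfDNA) from shallow single-end whole-genome sequencing. The pipeline is:

1. **Binning.** The reference (hg19 primaries by default) is tiled into
   fixed 60 kb windows by per-chromosome ceiling tiling; the last window of
   each chromosome is truncated at the chromosome end. For hg19
   chr1–chr22, chrX, chrY this yields exactly 51,607 bins. Coordinates are
   0-based half-open everywhere; BED exports follow the BED standard and
   TSV reports state their convention in the header.
2. **Counting.** Each primary, mapped, non-duplicate read with MAPQ ≥ 1
   increments the bin containing its leftmost aligned base. Leftmost-base
   assignment is used because the data regime is single-end sequencing, so
   fragment midpoints are unavailable. The MAPQ cut is configuration, not
   dogma: "mappable" is whatever the upstream aligner reported, and the
   default of 1 simply excludes reads the aligner itself distrusts.
3. **Scaling.** Counts are divided by the sample's mean count over
   unmasked bins, putting every sample on a depth-1 scale. Masked bins are
   excluded from the mean but keep their scaled values so all vectors stay
   aligned to the tiling.
4. **Ratio.** The per-bin log2 ratio of scaled cfDNA to scaled matched
   germline DNA (PBMC gDNA) cancels constitutional CNVs. Bins are usable
   only where the genome mask is clear, the numerator is positive and the
   raw germline count is ≥ `min_denominator_raw` (default 10, guarding
   log2 against germline dropout). Missing values propagate as unusable,
   never as zeros.
5. **GC correction.** Residual dependence of the log2 ratio on bin GC
   fraction is removed by subtracting a locally weighted regression
   (lowess, span 0.3) of ratio on GC, adding back the fit's median so the
   correction is level-preserving — important because the abnormality
   score sums absolute segment levels. A 1 %-wide GC-strata-median
   alternative is provided. Correction never changes which bins are
   usable, and is idempotent to within 0.01.
6. **Segmentation.** A circular-binary-segmentation style recursion per
   chromosome: the candidate change is the arc (contiguous run vs its
   complement) maximizing the pooled two-sample t statistic; it is
   accepted when a within-span permutation test (default 1,000 label
   shuffles, seed 17) gives p ≤ alpha (default 0.01), and the recursion
   continues inside accepted pieces. Ties in the split statistic break to
   the earliest genomic position, making segmentation fully deterministic
   given the seed. Permutations run in batches with early stopping once
   the exceedance count already guarantees p > alpha; this changes no
   accept/reject decision. Chromosomes are segmented independently.
   Segments bridge masked gaps (they are runs over *usable* bins).
7. **Filtering.** Segments of ≤ 4 bins are marked `too_small`
   (repeat-driven artifacts are short); segments overlapping a centromere
   padded by ±1 Mb are marked `centromere`. Filtering marks rather than
   deletes so reports can show why a segment was excluded.
8. **Scoring.** The genome abnormality score (UGA for urine, PGA for
   plasma — same algorithm, different specimen label) is the sum of the
   ten largest absolute mean log2 ratios among unfiltered segments,
   ranking by |mean| by default. When fewer than ten unfiltered segments
   exist, all are summed and the count k is recorded, so low-burden
   samples still score. The treatment-efficacy index is
   TEff = log2(pre-score / post-score) × 100; positive TEff means the
   abnormality declined after treatment. TEff is undefined (an error, not
   0) when either score is non-positive.
9. **Locus calls and shared regions.** A gene is called
   amplified/deleted when its best-matching unfiltered segment (maximal
   reciprocal overlap, which resolves genes spanning a breakpoint
   deterministically) has mean log2 ≥ +0.15 / ≤ −0.15. Cross-sample
   minimal-overlap regions are computed by decomposing the genome at all
   segment boundaries and merging adjacent elementary intervals with
   identical supporting-sample sets, keeping those supported by ≥ 2
   samples; every emitted region is therefore fully covered by each of
   its supporters. The TCRA locus is on the default exclude list:
   lymphocyte-derived control DNA carries somatic deletions there, so
   cfDNA/gDNA ratios show pseudo-amplification.
10. **Treatment-change profiles.** Post/pre log2 ratios are formed
    directly from scaled counts of the two cfDNA samples of one patient
    (no gDNA in the denominator) and segmented identically. GC correction
    is off by default for these pair profiles (they are built directly
    from scaled counts; the shared library chemistry largely cancels) but
    can be enabled by flag.
11. **Survival association.** Patients are split at the cohort median of
    the biomarker (value ≤ median → "low"; the tie rule is fixed for
    determinism), compared with Kaplan-Meier curves and the standard
    two-sample log-rank chi-square (1 df, no continuity correction). The
    CRPC endpoint is overall survival, the HSPC endpoint progression to
    castration resistance; the endpoint is a configuration field.

## Key parameters

| parameter | default | unit | why |
|---|---|---|---|
| window_size | 60,000 | bp | resolution/noise trade-off for ~5–15 M reads (~130 reads per bin) |
| min_mapq | 1 | — | proxy for "mappable"; configurable |
| min_denominator_raw | 10 | reads | guards log2 against germline dropout |
| gc span | 0.3 | fraction | standard lowess span for binned depth |
| alpha | 0.01 | — | per-span false-split rate of the permutation test |
| n_permutations | 1,000 | — | p-value resolution 1/1001 |
| segmentation seed | 17 | — | determinism; recorded in outputs |
| min_bins filter | 4 | bins | segments ≤ 4 bins excluded from scoring |
| centromere pad | 1,000,000 | bp | repeat-rich flanks of centromeres |
| score k | 10 | segments | top-ten absolute segment values |
| gain/loss threshold | ±0.15 | log2 | locus-call aberrance cut at low tumor fraction |

"Most significant" segment ranking is |mean_log2| by default, with
|mean|·√n_bins (`abs_mean_sqrt_n`) as a flagged alternative; the choice is
stamped into every score record. The summed quantity is always the
absolute segment mean.

## Synthetic data model

The generator emulates the shallow-WGS regime the pipeline targets:
~51,000 60 kb bins at a mean depth of ~134–150 reads per bin (the default
toy genome is 22 chromosomes totalling 5,000 bins for desk-scale tests;
hg19-scale generation is a parameter, not a different code path).

* **Mixture model.** A tumor fraction f of the cfDNA carries integer copy
  states cn; the expected scaled ratio per bin is 1 + f·(cn − 2)/2 and the
  expected log2 ratio log2(1 + f·(cn − 2)/2). This is the standard
  two-population dilution model; it is the generator's declared model, not
  an inference.
* **Noise.** Counts are negative-binomial with variance 1.3× the mean,
  matching the overdispersion of real shallow-WGS bin counts; a Poisson
  option (dispersion 1.0) exists for oracle simplicity.
* **GC bias.** An optional smooth (linear/quadratic in GC − 0.45)
  coverage multiplier shared by the cfDNA and gDNA of a pair.
* **Scenarios.** Named presets mirror the qualitative study findings:
  AR-region gain, PTEN loss, interstitial TMPRSS2–ERG loss, a
  many-segment high-burden genome vs a few-segment low-burden genome, a
  pre/post pair with a treatment-emergent gain, and a TCRA-artifact
  scenario in which the deletion sits in the *germline* truth, producing
  ratio pseudo-gain although the cfDNA is neutral.

What the generator does **not** model: fragment-length effects,
mappability structure, replication timing, base-level errors, or
inter-bin correlation beyond the segment structure. Passing tests
therefore demonstrate algorithmic correctness under the declared model,
not performance on real libraries.

## Test problem sizes

Simulation-based checks use sizes chosen to exercise the estimators while
keeping the default suite desk-scale: change-point localization uses
200-bin profiles over 100 seeds; parameter recovery a 1,200-bin
four-chromosome genome (aberrant segments of ~120 bins) at depth 150;
score-vs-tumor-fraction monotonicity a 1,100-bin 22-chromosome genome
over 20 seeds; the high-vs-low-burden contrast a 2,200-bin genome over 50
paired seeds; log-rank power 200 replicates at 50 per arm. These sizes
are the package's own test scale; all thresholds (breakpoint ±2 bins,
mean recovery ±0.05, Spearman ρ > 0.9, win rate ≥ 90 %, power ≥ 95 %) are
stated in the tests themselves.

## Numerical and design notes

* The published bin total appears twice in the source material (51,672
  and 51,607); ceiling-tiling of the 24 hg19 primaries reproduces 51,607
  exactly, so that is the canonical count.
* The segmentation stands in for a proprietary vendor step whose settings
  are not public; the CBS-style permutation algorithm with recorded
  parameters is an open, reproducible replacement, and outputs always
  carry (alpha, n_permutations, seed).
* At alpha = 0.01 per tested span, roughly 0.2–0.3 false splits per
  22-chromosome null genome are expected; on a tumor-free sample this
  occasionally adds a short segment to the score. The typical (median)
  null score at depth 150 stays below 0.2.
* Degenerate inputs: all-zero counts, all-identical biomarker values,
  zero-score TEff, empty comparison groups and genes without overlapping
  segments all raise typed errors or return explicit `no_data` — never
  silent zeros.
* Gene coordinates for the treatment-change gene set are embedded exactly
  as published (including the published chr7 placement of FGFR1); the
  core gene set (AR, PTEN, TMPRSS2, ERG, NOTCH1, MYCL) uses RefSeq hg19
  spans.
* Clustering of paired profiles uses average linkage on 1 − Pearson over
  co-usable bins; pairs sharing < 50 co-usable bins are flagged
  unreliable rather than silently distance-0.

## Limitations

* No allele-specific copy number, no integer-copy calling on real data,
  no fusion breakpoints from split reads (TMPRSS2–ERG appears only as
  interstitial copy loss), no joint multi-sample segmentation.
* No mappability or replication-timing correction; GC is the only
  coverage covariate.
* The permutation segmentation is O(n²) per tested span; at hg19 scale
  (chromosomes of ~4,000 bins) full runs are minutes, not seconds. The
  early-stopping permutation loop keeps null spans cheap.
* Survival tooling implements the two-group setting used here (median
  dichotomization, log-rank); there is no Cox regression or multivariable
  adjustment.
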