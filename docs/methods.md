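# Methods

## Measurement model and estimation

A CpG dyad carries 5mC, 5hmC or neither, with proportions
(p_m, p_h, p_u) on the simplex. Bisulfite sequencing (BS) reads both
modified forms as "methylated" (success probability p_m + p_h); oxidative
bisulfite (OxBS) first oxidises 5hmC to 5fC, which converts, so only 5mC is
read as methylated (probability p_m). The two libraries of one animal give
independent binomial observations, and the constrained ML estimate over the
simplex is obtained in closed form: when the BS fraction is at least the
OxBS fraction the unconstrained per-assay fractions already satisfy the
constraints (interior case); otherwise the maximum lies on the p_h = 0
boundary, where the product likelihood reduces to a single binomial with a
common success probability whose MLE is the pooled fraction
(m_bs + m_ox)/(n_bs + n_ox). No iterative solver is needed for the
two-assay design, and the test suite checks the closed form against a
brute-force grid maximization of the product log-likelihood (step 1e-3)
over all integer inputs with totals ≤ 20.

The log-likelihood is evaluated with real-valued "counts" so the fractional
values produced by pooling are accepted; scaling both assays by a common
positive factor leaves the estimate unchanged, which is what makes
fractional pooled counts admissible. Sites where either assay has zero
coverage are reported missing, never zero-filled: one assay alone cannot
separate 5mC from 5hmC.

Genome-wide summaries are computed two ways and reported side by side:
*report subtraction* (per-library aggregate percentage 100·Σm/Σn over raw,
unpooled counts; 5mC = mean over OxBS libraries, 5hmC = mean over BS minus
mean over OxBS) and *MLML mean* (mean of the per-site, per-animal estimates
after pooling). Subtraction averages libraries first and subtracts the
treatment means; a per-animal paired variant would differ only through
unequal library weighting and is not the default. A negative subtraction
value is possible on pathological input and is reported as-is with a
warning.

## Coverage pooling

At ~8X per library a ~4% 5hmC fraction is far below the per-CpG detection
limit (≈100X would be needed), so depth is traded for resolution:

1. **Median normalization.** Each library is scaled by
   (median of all libraries' median coverages) / (its own median coverage
   over covered sites); methylated and total counts are scaled together, so
   proportions are untouched. Scaled counts stay real-valued.
2. **Outlier removal.** Per library, the nearest-rank 99.9th percentile of
   coverage over covered sites (the ceil(0.999·n)-th order statistic —
   nearest-rank avoids interpolation-mode ambiguity) defines a threshold;
   a site is dropped entirely if any library strictly exceeds its own
   threshold there. High-coverage pileups are the signature of collapsed
   repeats and PCR stacks.
3. **Unite.** A site is kept iff every (group × treatment) stratum has at
   least `min_per_group` (default 1) libraries with non-zero coverage.
   Positivity is invariant under the normalization scaling, so applying
   this after normalization equals applying it to raw counts. Idempotent.
4. **Windows.** Sliding windows of 30 consecutive *retained* CpGs with step
   2, per chromosome, never straddling chromosomes; each interior CpG lies
   in exactly 15 windows. Indices refer to the post-filter CpG order, so
   membership stays well defined after filtering.
5. **Pooling.** Per window and library, counts are summed over member
   CpGs. "Combined coverage ≥ 100X" is interpreted per animal: a window
   survives for an animal when both its BS and its OxBS library reach 100
   summed coverage (estimation needs both channels; this is the strictest
   reading). The alternative — the sum over all libraries — is available as
   `combined_mode="all-libraries"`. Surviving windows assign
   (sum/30, meth_sum/30) to each member CpG; a CpG's final value is the
   mean over the surviving windows containing it. Methylated counts are
   pooled by the identical procedure as totals so proportions remain
   defined, and values are carried as reals end to end — rounding after
   division by 30 would destroy a 4% 5hmC signal.

If every member CpG of every window shares proportion p in a library, every
pooled proportion equals p exactly; this and the monotonicity of the
coverage floor are tested properties.

Note that the assignment-and-average step is a ±29-CpG moving average of
the local counts: pooled tracks are intentionally smooth, which matters for
region calling (below).

## DMR calling

DMR calling consumes the **unpooled** per-CpG, per-animal estimates (p_m
for the 5mC track, p_h for 5hmC), not the pooled ones. Two reasons: the
per-CpG counts are the natural input of smoothing-based region callers,
which perform their own variance reduction; and the pooling kernel
attenuates the mean difference of a 10–30 CpG region to 0.37–0.71 of its
true value, which would push threshold-sized effects below the effect-size
filter by construction. The caller accepts any track, so running it on
pooled estimates remains possible.

Stages:

- **Prefilter.** A site is removed when no sample in either group reaches
  `min_reads` (default 2). A stricter reading — every group must contain
  such a sample — is available (`strict_prefilter`). Per-animal coverage is
  the smaller of the two channel totals, the evidence floor for an
  estimate.
- **Smoothing.** Per sample, a coverage-weighted local-linear fit with a
  tricube kernel on genomic distance, evaluated at each CpG over the larger
  of ±`h_bp` and the span of the `min_cpgs` nearest CpGs; fitted values are
  clamped to [0, 1]. Chromosomes shorter than `min_cpgs` fall back to a
  whole-chromosome fit with a warning. Missing per-animal values get zero
  weight.
- **t statistic.** t = (mean_case − mean_control) / (sd_pooled ·
  √(1/n1 + 1/n2)) per CpG, with the pooled within-group SD of smoothed
  values locally smoothed along the genome (running mean of the variance
  over 101 CpGs) and floored at its genome-wide 0.75 quantile. t is capped
  at ±50 to guard zero-variance degeneracies and is exactly 0 where group
  means are equal. Swapping group labels negates every t and mean
  difference exactly (tested).
- **Region finding.** Cutoffs are the empirical 2.5% / 97.5% quantiles of
  the genome-wide t distribution (absolute cutoffs may be supplied);
  candidates are maximal runs of consecutive CpGs strictly beyond the same
  cutoff side, never merged across a sub-threshold CpG. Boundaries are the
  genomic positions of the first/last member CpG, emitted 0-based
  half-open.
- **Filtering and ranking.** Keep candidates with ≥3 CpGs and
  |mean_diff| ≥ 0.10 (5mC) or 0.01 (5hmC), where mean_diff is the mean
  smoothed case−control difference over member CpGs — consistent with the
  statistic that defined the region. Ranking is by |areaStat| (the plain
  sum of member t values) descending, ties broken by coordinate; an
  n_cpg-weighted variant of the score was considered and rejected in
  favour of the plain sum that the name denotes.

**Bandwidth.** Defaults are h_bp = 1000 and min_cpgs = 70, suitable for
broad kilobase-scale regions. The smoothing span must not exceed the span
of the smallest regions of interest: a 70-CpG window attenuates the
smoothed mean difference of a 10-CpG region roughly two-fold, enough to
push a threshold-sized effect below the filter. The synthetic-study
analyses therefore use h_bp = 500, min_cpgs = 21 (≈ two thirds of the
smallest injected DMR at the simulated CpG spacing), selected by this
matched-filter principle and a pilot bandwidth sweep on seeds separate from
the frozen test seed.

**Power at threshold-sized effects.** The synthetic study injects 5mC
effects of exactly 0.10 — equal to the filter threshold. The mean
difference of a matched candidate is then centred on ≈ 0.10 with an SD
bounded below by the total read count of the region (a 30-CpG DMR at 8X
with 3 animals/group holds ~720 reads per group, so SD ≥ 0.026), and the
probability of clearing the filter is capped near 50–60% regardless of
bandwidth. End-to-end recovery measured by the test suite reflects this:
candidate-level detection at ≥50% reciprocal overlap reaches 75–80%, while
post-filter recovery sits near 50%. This is a property of thresholding at
the true effect size, not of the implementation; effects even slightly
above threshold (or lower per-CpG noise) recover at much higher rates.
5hmC effects (0.01) are an order of magnitude below per-CpG noise and are
recovered only sporadically; their sensitivity is reported, not gated.

## Element enrichment and closest genes

All intervals are 0-based half-open; a CpG at 1-based position p is the
width-1 interval [p−1, p), so CpG–element and DMR–element overlap share one
geometry kernel (an interval tree, cross-checked against brute-force
all-pairs intersection in the tests). The enrichment score for a class is
n_overlapping_pairs / (n_DMR + n_elements) — the intersection-over-union
style metric with the *sum* denominator; the set-theoretic Jaccard
denominator (subtracting the intersection) and unique-DMR counting (a DMR
touching two elements counted once) are flags. Element mean methylation is
the unweighted mean of per-CpG estimates over the CpGs inside the element;
elements without estimated CpGs are missing. Closest-gene assignment
minimises interval distance (0 when overlapping), ties broken by distance
between element start and gene start, then lexicographic gene id.

## Expression integration

TMM factors follow the trimmed-mean-of-M-values definition: the reference
sample is the one whose upper-quartile/library-size ratio is closest to the
mean ratio; genes with zero counts in sample or reference are excluded;
M (log2 ratio of library-size-scaled counts) and A (log2 abundance) are
two-sided rank-trimmed at 30% and 5%; the factor is 2 to the
precision-weighted mean of the surviving M values (delta-method binomial
weights), and factors are recentred to geometric mean 1. The implementation
is verified against an independently coded straight-from-definition
evaluator and against edgeR's `calcNormFactors` via Rscript.

Correlation uses normalized expression (counts per million of effective
library size). Spearman's rank correlation is invariant to monotone
transforms, so no log/pseudocount step is applied. The observation unit is
the element: a gene assigned to several elements contributes once per
element. Per-sample coefficients are averaged per group and combined (both
layouts are emitted; cells with fewer than 3 complete pairs, or zero rank
variance, are missing).

## Synthetic data generator

What it emulates: two groups (default 3 + 3 animals) with one BS and one
OxBS library each; per-dyad coverage Poisson(8) per library (zero-coverage
sites occur, exercising the unite/pooling filters), split binomially
between the two strands of the dyad so strand collapsing is exercised;
background methylation piecewise-constant over blocks of 50–200 CpGs with
Beta-distributed block means around bases 0.587 (5mC, concentration 120 —
chosen so the genome mean concentrates within a few tenths of a point at
20k CpGs while leaving visible between-block structure) and 0.044 (5hmC,
concentration 300); injected non-overlapping DMRs shifting exactly one
methylation type in the case group by exactly the configured effect
(defaults 0.10 / 0.01, the calling thresholds); genes laid out
non-overlapping with promoter/exon/intron/CDS elements and uniformly placed
enhancer/CTCF/TF/open-chromatin elements; expression with expected count
baseline_g · exp(coupling · z/2), z the standardised group-truth mean
intronic 5hmC, negative-binomial (Gamma–Poisson) counts with dispersion
0.1, and per-sample library-size factors in [0.6, 1.6] to exercise TMM.

Optional error terms: `bs_conversion_error` adds to the BS methylated
probability of unmethylated cytosines; `oxbs_oxidation_failure` lets that
fraction of 5hmC read as methylated in OxBS. Both default to 0 and the
estimator does not correct for them (kit spike-in QC is out of scope).

What it does not model: read-level artifacts (FASTQ, alignment, PCR
duplicates), CpH contexts, copy-number variation, and — importantly —
inter-animal biological variability: animals within a group share the group
truth, so within-group variance is purely binomial sampling noise. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated measurement model, not robustness to biological overdispersion.
The Poisson coverage shape is a stand-in (real data only pin the ~8X mean)
and is configurable.

Determinism: a single integer seed feeds four spawned PCG64 streams
(genome, truth, reads, expression); outputs are byte-identical across runs
and platforms, with no hash-order dependence.

## Problem sizes and numerical choices

The validation analyses use a 20,000-CpG chromosome (3v3 at 8X) for
estimation and DMR recovery — large enough that the genome-mean SD from
block sampling is ~0.35 percentage points for 5mC — and a 4 × 10,000-CpG
genome (~95 genes) for the expression correlation, where the effective n is
the number of genes rather than CpGs. Degenerate inputs are handled
explicitly: empty cytosine reports warn and return empty; libraries with no
covered sites are errors; chromosomes shorter than a window emit no
windows; single-replicate groups are rejected by the t statistic with a
pointer to mean-difference-only calling; tie handling in Spearman uses
average ranks. Simplex outputs are renormalised against float round-off and
satisfy p_m + p_h + p_u = 1 to 1e−12.
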