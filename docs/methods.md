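# Methods

`dmrscan` implements a three-stage blood DNA-methylation marker analysis —
small-cohort discovery of differentially methylated regions (DMRs),
replication in independent cohorts, and diagnostic model selection — plus a
synthetic-data generator that produces methylation count matrices with the
statistical structure each stage assumes.  This note records the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic experiments do and do not demonstrate.

## Data model

A cohort is a per-CpG × per-sample pair of integer matrices (methylated
count, total coverage) with 1-based plus-strand cytosine coordinates.  CpG
methylation is strand-symmetric, so minus-strand calls at position *p* are
collapsed onto the plus-strand cytosine at *p − 1* at read time; the
collapse is idempotent.  A site missing in a sample is coverage 0 and is
never imputed — the coverage filter removes it.  The per-sample methylation
level at a site is β = meC/(meC+C) ∈ [0, 1]; Δβ denotes the AD-minus-CN
difference in group-mean β (negative = hypomethylated in cases).

## Stage 1: DMP calling

A differentially methylated position (DMP) must pass three thresholds,
applied in order over the discovery cohort:

1. **Coverage**: every sample ≥ `min_cov` (default 10) reads.  The default
   mode requires the rule in *all* samples (unite-style), matching how
   validation amplicons with any low-coverage sample are excluded.
2. **Test**: the per-site p-value is the 1-df likelihood-ratio test of the
   group term in a binomial logistic regression with the per-sample
   methylated count as the response out of its coverage.  With an
   intercept+group design the MLE is the group-pooled rate, so the
   statistic is computed in closed form as the pooled two-proportion
   G-statistic (identical inference, vectorized over sites).  A pooled
   Fisher exact test and a beta-binomial LRT with shared dispersion are
   available options; the default intentionally assumes binomial counts,
   and its null calibration is therefore demonstrated on data with
   between-sample dispersion ρ = 0.
3. **Selection**: BH q ≤ `max_q` (default 0.01), with q computed over all
   tested sites, and |Δβ| ≥ `min_abs_delta` (default 0.15), where group β
   is the unweighted mean of per-sample rates.

Sex-chromosome DMPs are removed afterwards by an explicit exclusion step so
the count of removals is reported.  Degenerate sites (no variation, all-0
or all-1 methylation) get p = 1 rather than a numerical failure.

## Stage 2: DMR detection

The sliding-window definition: a window is any genomic interval of length
≤ `window_bp` (default 1000, inclusive span max−min ≤ 1000) whose endpoints
are DMP positions.  A window **qualifies**, per direction of change, when
it contains at least `k_lo` = 5 same-direction DMPs with |Δβ| ≥ 0.15 or at
least `k_hi` = 3 with |Δβ| ≥ 0.25.  All qualifying windows of one
direction are merged transitively whenever they overlap (touching at a
shared position counts); each merged component is one DMR, reported as the
span of its member DMPs.  Opposite-direction regions may abut but never
merge.  A merged DMR may be longer than one window — that is the intended
"consecutive windows" semantics.

`call_dmrs` avoids window enumeration.  Every qualifying window contains a
*core* of k consecutive qualifying DMPs spanning ≤ `window_bp`, and the
union of all windows containing a given core is a single closed interval
(from the leftmost DMP position ≥ core_end − window, to the rightmost DMP
position ≤ core_start + window).  Merging those reachable intervals is
provably equivalent to merging the windows themselves, and the package
carries an exhaustive O(n²) oracle (`brute_force_dmrs`) that enumerates
every DMP-endpoint window; equivalence on randomized instances is the
module's central test.

Two off-by-one conventions are fixed deliberately and mirrored in the
oracle: window length uses the inclusive span, and interval merging treats
intervals sharing a single base as overlapping.

## Stage 3: cohort validation

Validation cohorts are deep amplicon-style data restricted to candidate
DMR regions.

* **Per-CpG screen**: two-sided Welch's t on per-sample rates, Bonferroni
  threshold α/m with m = all CpGs analyzed in the cohort (not per-DMR).
  Welch is used because rates at ~1000× depth are effectively continuous
  with unequal group variances; a zero-variance pair of groups gives p = 1
  when the means agree and is flagged degenerate otherwise.
* **Burden test**: per sample, B = Σ w_j · rate_j over the DMR's CpGs
  (flat weights by default; a Beta(1,25)-density option mimics
  rare-variant weighting but only rescales the 1-df statistic).  The score
  statistic for adding B to the logistic null `phenotype ~ 1 + sex + age`
  is Q = U²/Var with U = Σ(y−μ̂)B and Var = B′VB − B′VX(X′VX)⁻¹X′VB,
  V = diag(μ̂(1−μ̂)).  For a covariate-adjusted null the p-value is
  χ²₁(Q).  For an intercept-only null the exact conditional null of U
  given Σy is the permutation distribution of the case-burden sum, and
  when C(n, n_cases) ≤ 300,000 the p-value is evaluated exactly by
  enumeration: at small n the χ² tail is visibly off the permutation
  distribution (an O(1/n) error), and the exact conditional computation
  removes that approximation entirely.  Separation in the null fit falls
  back to a ridge-penalized fit.
* **FDR**: BH q-values across the DMRs tested within a cohort.
* **Meta-analysis**: signed Stouffer, z_k = Φ⁻¹(1−p_k/2)·sign(Δβ_k),
  combined with weights √n_k and a two-sided meta p.  This is the standard
  sample-size-weighted convention; evidence in opposite directions
  cancels.  A pooled refit with cohort-indicator covariates is available.
* **Confirmation rule chain** (each step configurable): ≥ 3 member CpGs
  Bonferroni-significant in the primary validation cohort; burden FDR
  q < 0.05 there; meta-analysis p < 0.05 across both cohorts.

## Stage 4: diagnostic models

Marker CpGs are those Bonferroni-significant in *both* validation cohorts
with concordant Δβ sign.  Features are the per-CpG methylation rates (one
feature per marker CpG) plus clinical covariates: age, sex, and the APOE
ε4 allele count encoded ordinally (0/1/2).  Samples are pooled across
validation cohorts and split 4:1 stratified by label.  Every nonempty DMR
subset plus a covariate-only base model is fitted as elastic-net logistic
regression (`saga`, l1_ratio 0.5) with the penalty C chosen from
{0.1, 1, 10, 100} on the same stratified CV folds (3 by default); models
are ranked by mean CV AUC; the winner is refit on the full discovery split
and evaluated on the held-out split.  Standardization is fitted inside
training folds only, so no selection or scaling information leaks into
held-out folds.  AUC is the tie-corrected Mann–Whitney statistic; its 95%
CI uses DeLong's variance with a normal approximation clipped to [0, 1].
Exhaustive enumeration is refused above 20 DMRs (2²⁰ subsets).
A sensitivity analysis repeats the search at 3/5/10 folds and flags winner
changes.

## Synthetic cohorts

The generator emulates targeted bisulfite data at the level the pipeline
consumes:

* **Positions**: exponential spacings (mean 150 bp, minimum 2 bp) per
  chromosome; an optional fraction of CpGs on chrX/chrY exercises the
  exclusion step.  Implanted DMR spans contain exactly the spec's evenly
  spaced CpGs; background CpGs never fall inside a span, so ground truth
  is unambiguous.
* **Baselines** π_j: a low/intermediate/high beta mixture
  (weights 0.3/0.4/0.3; Beta(2,38), Beta(8,8), Beta(38,2)).  The
  intermediate band is deliberately heavy because validated blood DMRs sit
  in intermediately methylated regions.  Implanted-effect experiments in
  the test suite use the intermediate band only, which both matches that
  observation and avoids β-scale clipping artifacts at extreme baselines.
* **Counts**: meth ~ BetaBinomial(coverage, μ, ρ), with ρ the
  across-sample intra-class dispersion; ρ = 0 reduces to binomial.  The
  default ρ = 0.02 (between-sample SD ≈ 0.07 at π = 0.5) is a
  conventional choice — the study supplies no per-CpG variance estimates —
  and is stated once, not fitted.
* **Effects**: group effects add Δβ on the β scale for case samples with
  clipping to [0, 1] (a logit-scale option exists but is off by default,
  since reported effects are on the percentage scale); an optional linear
  age slope ties methylation to age; APOE genotypes are drawn from
  group-conditional frequencies and are independent of methylation.
* **Coverage**: negative binomial mean 30, dispersion 0.3 for
  discovery-like data; Poisson(1000) for amplicon-like data.  Note the
  NB(30, 0.3) default is heavy-tailed enough that the all-samples ≥10
  filter retains only ~15% of sites at n = 24; the end-to-end demo in
  `scripts/acceptance.py` therefore uses NB(30, 0.05), whose ≥20×
  fraction (~90%) matches deep capture data, and states that as its run
  condition.

Same config + seed reproduces byte-identical cohorts, including on-disk
files.

**What the synthetic experiments do not show.**  The generator does not
simulate reads, bisulfite conversion failure, PCR duplicates, mapping
artifacts, SNP-induced false calls (C→T transitions), capture efficiency,
or correlation between neighboring CpGs within a sample.  Passing tests
therefore demonstrate the statistical machinery — calibration, power
ordering, selection behavior, winner's-curse shrinkage — under the assumed
count model, not performance on real cohorts.

## Numerical and design notes

* BH q-values are used throughout for FDR (the same procedure applied at
  the DMR level); the SLIM method some callers default to is not
  re-implemented.
* Ties in DMR location annotation resolve by precedence
  promoter > exon–intron > exon > intron; the promoter window is 2 kb
  upstream of a transcription start, strand-aware.
* The sliding-window thresholds (5 @ |Δβ|≥0.15 / 3 @ |Δβ|≥0.25 per 1 kb)
  are plain configuration numbers; stricter variants (7/5) seen in some
  descriptions of this design are a one-line config change.
* The 4:1 split uses scikit-learn's stratified `train_test_split`, so 192
  samples split 153/39 (test size rounded up).
* Monte-Carlo problem sizes in the test suite (e.g. 100 seeded runs for
  null FDR behavior, 2,000 burden null simulations, 50 selection runs,
  500 random DMR instances) were chosen to keep the whole suite under a
  couple of minutes on one core while leaving comfortable margins on every
  stochastic assertion.

## Known limitations

* The burden test's exact conditional path exists only for the
  intercept-only null; covariate-adjusted p-values rely on the χ²₁
  asymptotics (adequate at n = 96, as the KS calibration test shows).
* The beta-binomial per-site test option uses direct likelihood
  optimization per site and is not vectorized; it is intended for small
  candidate sets, not genome-wide scans.
* `select_marker_cpgs` matches CpGs across cohorts by exact coordinate;
  assay designs whose amplicons tile different CpGs per cohort will
  produce warnings and a reduced marker set.
* The elastic-net subset search treats the penalty grid as given; it does
  not refine C beyond the four canonical values.
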