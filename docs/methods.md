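# Methods

This note records the statistical model behind `t2dclust`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Matrix construction

Associations are aligned to the T2D risk-increasing allele of the variant
manifest; an association whose alleles match in neither orientation is an
error, as is a manifest entry with a strand-ambiguous pair ({A,T} or
{C,G}), since such pairs cannot be harmonized across GWAS reliably.

Standardized effects are z = β/se. To make traits measured in studies of
very different size comparable, z is **divided** by √(n̄\_t), with n̄\_t
the mean per-SNP sample size in trait *t*'s table. Dividing (rather than
multiplying) puts every trait on a per-sample effect scale; multiplying
would amplify the largest studies, the opposite of the intent. The
direction is a config switch (`scale_direction`) for sensitivity analyses.

Filters applied before clustering:

- **Trait filter.** A trait is kept only if at least one variant reaches
  the Bonferroni-corrected two-sided threshold p < 0.05/N (|z| ≳ 3.47 at
  N = 94). The filter runs on *unscaled* z, because the p-value is a
  property of β/se, not of the √n̄ rescaling.
- **Variant selection.** Candidates need at least nominal support
  (p < 0.05) in the reference T2D meta-analysis; among non-distinct-signal
  variants, only the smaller-p variant survives within any 500 kb window on
  a chromosome (ties break by genomic order, deterministically). Variants
  marked as distinct signals at a locus are exempt.

Cells with no GWAS entry for a variant-trait pair are zero-filled and
recorded in an observed-mask; zero is the neutral value for the
nonnegative factorization, and the mask plus logged counts keep the
imputation auditable.

The signed matrix **Z** is split per trait into `_pos` (positive z) and
`_neg` (negated negative z) columns. The split is lossless
(`X_pos − X_neg = Z` holds to machine precision) and keeps the
direction-of-effect information available to a nonnegative model; trait
weights downstream always carry their `_pos`/`_neg` direction label.

## ARD factorization

The objective is the negative log posterior

    F = ||X − WH||²_F / (2σ²)
        + Σ_k (||W·k||² + ||H_k·||²) / (2λ_k)
        + ((N + M)/2 + a + 1) Σ_k log λ_k + Σ_k b/λ_k

with W ≥ 0 (N × K0), H ≥ 0 (K0 × M), and per-component relevance weights
λ_k (the shared variance of the half-normal priors on W's column k and H's
row k, under an inverse-gamma(a, b) hyperprior). It is minimized by
alternating multiplicative updates,

    W ← W ⊙ (X Hᵀ) ⊘ (W H Hᵀ + σ² W Λ⁻¹)
    H ← H ⊙ (Wᵀ X) ⊘ (Wᵀ W H + σ² Λ⁻¹ H)

and the closed-form stationary update
λ_k = (||W·k||²/2 + ||H_k·||²/2 + b) / ((N+M)/2 + a + 1). Each step is
non-increasing in F (the standard majorization argument for L2-regularized
multiplicative updates; the λ update is an exact minimization), which the
test suite asserts at 1e-9 relative tolerance per iteration.

Defaults and rationale (all exposed in `BnmfConfig`):

- **K0 = 20** starting components — comfortably above the plausible number
  of pathways, leaving ARD room to prune.
- **a = 10**, **b auto-derived**: the prior mean of λ is set so the
  expected reconstruction scale matches the data,
  E[(WH)_ij] = K0·2λ/π = mean(X), hence b = (a−1)·π·mean(X)/(2K0). This
  makes the whole procedure invariant to rescaling X (W and H scale as
  √c when X scales by c, σ² as c², b as c — every objective term is
  preserved up to an additive constant), which the tests check.
- **σ² auto-derived as a robust null-noise estimate**: the lower quartile
  of the squared *nonzero* entries of X, divided by the χ²(1) 25th
  percentile (≈0.1015). A GWAS z-score has unit sampling variance, and in
  a variant×trait matrix most cells are null, so a low quantile of the
  squared entries estimates the noise floor even when up to three quarters
  of the nonzero cells carry signal. The naive alternative — the variance
  of all entries of X — includes the signal variance and overstates the
  noise so badly that the prior wins everywhere and the factorization
  collapses to W = H = 0 at realistic problem sizes; the quantile
  estimator avoids that failure mode. `sigma_sq` can be fixed explicitly
  (e.g. for matrices that are not sparse z-score matrices, where the
  quantile heuristic does not apply).
- **tol = 1e-7** relative objective change, **max_iter = 100000**. Runs on
  planted data typically converge in a few hundred to a few thousand
  iterations.
- **Pruning.** A component survives if its largest W entry and largest H
  entry both exceed `prune_eps` (= 1e-5) times the respective global
  maxima *and* its peak contribution max(W·k)·max(H_k·) reaches
  `prune_eps`·max(X); the data-scale anchor makes a fully-shrunk run
  report K = 0 rather than counting collapsed components. During
  iteration, components that fail the criterion are actively zeroed — but
  only when doing so does not increase F — which removes dying components
  quickly without breaking monotone descent.
- **Initialization.** W and H are i.i.d. uniform(0,1) scaled so the
  expected reconstruction matches mean(X); run *i* of an ensemble uses
  seed base+i, so ensembles are bitwise reproducible.
- **Model selection.** Over the ensemble, the modal effective K is chosen
  (ties toward the smaller K — the more parsimonious model), and the
  reported solution is the minimum-F run among those at the modal K.

A note on the MAP bias: the half-normal prior shrinks W and H, so even on
exactly low-rank data the reconstruction error is O(σ²/λ) rather than
machine precision; conversely, making σ² very small to chase exact
reconstruction disables the ARD pressure and duplicated components stop
being pruned. Rank selection and near-exact reconstruction are therefore
not achievable simultaneously in a single run; the defaults favour correct
rank selection, which is what the pipeline needs.

## Membership thresholds

- **Delta rule.** All variant weights, pooled across clusters, are sorted
  in descending order; consecutive deltas are ranked and the top 5%
  (`top_frac`) counted as significant, with two deliberate refinements:
  only *nonzero* deltas can be significant (duplicate tail weights never
  matter), and ties among equal deltas resolve toward higher weights. The
  cutoff is the weight at the last significant delta — the boundary where
  the long tail of uninformative weights begins. Degenerate inputs (fewer
  than 3 weights, all weights equal) are errors with messages.
- **Stepwise rule.** Per cluster, the IVW meta-analysis of the cluster's
  top trait is evaluated on the full member set, then repeatedly with the
  lowest-weighted variant removed; the sweep stops at the first local
  minimum of the p-value (ends of the sweep count as p = +∞ neighbours).
  Comparisons use |z| rather than p so that very small p-values cannot
  underflow; exact-tie sweeps (identical stats everywhere) fall back to
  the global minimum.
- **Membership is inclusive** (weight ≥ cutoff) and soft: multi-cluster
  variants are preserved and reported separately.

## GRS associations from summary statistics

The IVW fixed-effects combination with optional per-variant multipliers
w_i is

    β = Σ w_i β_i/se_i² / Σ w_i²/se_i²,   se = (Σ w_i²/se_i²)^(-1/2)

with a two-sided normal p. With w_i = 1 (the default — the cluster GRS
uses the top-weighted variants unweighted) this is the textbook
fixed-effects estimator; cluster-weight multipliers are available for
sensitivity analyses. Member variants without aligned stats for a trait
are dropped with a warning; an empty remainder is an error. Bonferroni
reporting thresholds are computed per test family (e.g. 0.05/235 for 47
traits × 5 clusters; both the 0.05/50 and 0.05/60 outcome conventions can
be requested since either grouping of the ten outcomes is defensible).

## Credible sets and enrichment

Per locus, the supplied member variants (all variants within ±500 kb in LD
r² > 0.1 with the index variant; LD resolution is upstream of this
package) form a 100% credible set. The Wakefield approximate Bayes factor

    ABF = √(se²/(se²+ω)) · exp(ω β² / (2 se² (se²+ω)))

uses prior effect variance ω = 0.04 by default (prior SD 0.2 on the
log-odds scale, the common choice for binary-trait fine-mapping);
posteriors are ABFs normalized within the locus.

Annotations are BED-like intervals (0-based, half-open) per cell type; the
qualifying chromatin states default to {Active Enhancer 1, Active Enhancer
2, Weak Enhancer, Genic Enhancer, Active Promoter}. A variant at 1-based
position p overlaps [start, end) iff start ≤ p−1 < end. A cluster's
cell-type probability is the summed posterior of credible-set variants
inside qualifying intervals, divided by the number of loci in the cluster;
loci appearing in a cluster more than once (multi-signal loci) are counted
once.

Significance is permutation-based, one-tailed, with add-one p-values
(p = (1 + #{perm ≥ obs})/(n_perm + 1), bounded in [1/(n_perm+1), 1]):

- **within cluster**: each permutation independently shuffles the
  cell-type labels of every locus's overlap profile — i.e. the
  locus↔cell-type pairings are randomized while each locus keeps its own
  overlap mass; the wording "permute locus and cell type labels" admits a
  joint single-permutation variant, but the per-locus shuffle gives a
  richer, exactly enumerable null and is what the calibration tests
  validate;
- **across clusters**: cluster labels are shuffled over the pooled loci,
  preserving cluster sizes.

`n_perm` defaults to 10⁴ in tests; 10⁶ reproduces publication-grade
resolution. A heuristic warns when no variant overlaps any interval in any
cell type (the signature of a genome-build mismatch).

## Cohort stratification

Cluster GRS per individual = Σ dosage·weight over the cluster's
above-cutoff variants; a member variant missing from the dosage matrix is
an error (silent dropping would bias scores), as are dosages outside
[0, 2]. Decile flags use the nearest-rank 90th percentile: the threshold
is the ⌈n/10⌉-th largest score, flags are inclusive, ties at the boundary
are all included and the inflation is logged (deciles are computed per
cohort). An individual flagged in exactly one cluster is uniquely
assigned; under independent scores the expected unique fraction is
5·0.1·0.9⁴ ≈ 32.8% for five clusters.

GRS-trait associations use OLS for continuous traits and logistic
regression for binary ones (auto-detected 0/1, overridable), adjusting
additively for sex, age and principal components; rows with missing values
are dropped per trait (complete-case, counts logged) and effects can be
rescaled per raw trait SD. Cross-cohort combination is the same IVW
fixed-effects estimator. Subgroup contrasts use Kruskal-Wallis for
continuous traits and a chi-squared contingency test for the sex
proportion.

## Synthetic data

The generators produce exactly the inputs the pipeline reads, each with a
machine-readable truth record (seed included), and downstream recovery
tests read truth only from those records.

- `gen_summary_stats`: planted sparse nonnegative W_true (disjoint variant
  blocks, ≥3 variants each, weights ~ U(0.8, 1.2)) and H_true (≥2 defining
  traits per cluster, random direction, |z| ~ U(5, 15) — the scale of
  genome-wide-significant loci); observed z = planted z + N(0, noise_sd)
  with noise_sd = 1 (the sampling noise of a GWAS z-score); β = z·se with
  se = 1/√n_t and per-trait sample sizes n_t ~ U(50 000, 200 000). About
  half the rows are emitted in flipped allele orientation to exercise
  alignment. Variants sit 1 Mb apart with unambiguous alleles so the
  manifest passes every filter.
- `gen_cohort`: Hardy-Weinberg dosages (Binomial(2, f), f ~ U(0.1, 0.9)),
  phenotypes as linear combinations of cluster GRSs plus fixed sex/age/PC
  effects and unit Gaussian noise; binary traits through a logistic link
  centred at ~50% prevalence.
- `gen_annotations`: credible-set variants of loci in planted
  (cluster, cell type) pairs are covered by qualifying intervals with
  probability `overlap_prob_high`, others with `overlap_prob_low`;
  non-covered variants get non-qualifying intervals so files are never
  empty.

What the generators deliberately do **not** emulate: linkage
disequilibrium between variants (each variant is independent),
population structure and relatedness, allele-frequency-dependent standard
errors, correlated traits measured on overlapping samples, missing
variant-trait cells with informative missingness, and real chromatin-state
segment length distributions. Passing recovery tests therefore show that
the algorithms do what they claim under the stated statistical model —
not that the pipeline is robust to LD leakage, stratification
confounding, or sample overlap in real consortium data; those need real
inputs and upstream care.

## Problem sizes used by the test suite

Tests run at desk scale, chosen as the smallest sizes at which each
statistical claim is meaningful: planted models default to 8 variants and
4 traits per cluster (so K = 5 gives a 40 × 40 doubled matrix); ensembles
use 25 restarts for rank recovery and 5–10 elsewhere; permutation nulls
use 999 permutations × 500 simulated datasets; regression calibration uses
500 cohorts of 250 individuals; the stratification check uses 100 000
individuals. Publication-scale settings (1000 restarts, 10⁶ permutations)
are plain parameter changes.

## Known limitations

- The ARD landscape is multi-modal; single runs can return split or merged
  components, which is why the ensemble-modal-K protocol is the supported
  interface for rank selection.
- The membership cutoff lives on the scale of the fitted weights, which in
  turn depends on the matrix scaling convention; cutoffs are therefore
  data-derived (delta/stepwise rules) rather than fixed constants.
- The within-cluster permutation test conditions on each locus's total
  overlap mass; loci whose credible sets overlap nothing in any cell type
  contribute no discrimination.
- Logistic associations use maximum likelihood without small-sample or
  separation safeguards beyond statsmodels' defaults.
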