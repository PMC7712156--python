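# Methods

## Data model

The pipeline's universal currency is a wide sample × metabolite matrix of
non-negative relative abundances with per-sample metadata (subject,
cohort ∈ {ASD, TD}, week ∈ {0, 3, 10, 18}).  Missing cells are an explicit
`NaN` sentinel, deliberately distinct from zero: a below-detection-limit
measurement and a true zero are different states.  Invariants enforced at
construction: one sample per (subject, week), controls only at week 0, no
negative values.  Metabolite identifiers are opaque strings; no chemical
validation is attempted.

## Preprocessing

Order of operations is impute → filter → normalize.

* **Imputation.** Each missing cell of metabolite *m* becomes
  `min_observed(m)/√2`, the standard convention for vendor-imputed
  below-detection values.
* **Detection-limit filter.** The detection limit is the minimum recorded
  value of a metabolite over the N week-0 samples (both cohorts pooled);
  retention requires at least `floor(0.4·N)` measurements strictly above
  it — 15 at the design size N = 38.  `floor` (not ceiling) is used
  because 0.4 × 38 = 15.2 and the design-size rule is stated as 15
  measurements; a literal "at least 40%" would give 16.  For a metabolite
  with any missing cells the post-imputation minimum is `min/√2`, so the
  above-limit count equals the number of observed cells; for a fully
  observed metabolite ties at the minimum do not count.  Defining the
  count this way makes the filter commute with imputation (imputed values
  sit strictly below the limit), which is tested.  The filter is invariant
  to strictly monotone per-metabolite rescaling.
* **Normalization.** Every metabolite is divided by its TD week-0 median,
  so the TD week-0 median is exactly 1.0; the same factors apply to all
  weeks, keeping follow-up samples on the reference scale.  The
  post-scaling TD week-0 sample standard deviation (ddof = 1; the
  convention is a package choice) is retained for the deviation score.
  σ-scaling is deliberately *not* applied to the discriminant inputs at
  later weeks — the reference σ enters only the deviation score, where
  its definition places it.  A `impute=False` path supports tables whose
  missing cells were already replaced upstream.

## Univariate screening

AUROC is computed from the rank-sum statistic (ties ½) and folded to
`max(A, 1−A)` so the direction of a cohort difference is irrelevant; the
candidate rule is strictly `AUROC > 0.6` (the boundary case at exactly
0.6 is excluded; the threshold is configurable).  Note the folded
statistic's null mean is not 0.5 but 0.5 + σ√(2/π) ≈ 0.576 at n = 18/20;
the unfolded statistic is the one centered at 0.5.

The week-0 vs week-18 change test routes on Anderson–Darling normality at
**both** time points (α = 0.05, interpolated p-values): normal at both →
paired t-test, otherwise Wilcoxon signed-rank (zero differences dropped;
exact null for ≤ 25 non-zero pairs, continuity-corrected normal
approximation above).  All-zero differences return p = 1 with a
"degenerate" marker.

The leave-n-out FDR is the proportion of all C(N, n) leave-n-out subject
subsets whose rerun change test is non-significant.  Enumeration is exact
up to a configurable cap (default 20 000 subsets) and switches to seeded
uniform subsampling beyond it.

Correlation panels use Pearson r over the pooled week-0 samples with the
two-sided t transform on n − 2 degrees of freedom; only pairs with
p < α are reported, and zero-variance metabolites are skipped with a
warning.  At the design size this closed form reproduces the published
negative-correlation anchor (r = −0.32 → p = 0.050) exactly.

## Fisher discriminant

Scatter matrices carry class-size weights in **both** terms,

  S_B = Σ_k n_k (x̄_k − x̄)(x̄_k − x̄)ᵀ,
  S_W = Σ_k n_k Σ_{i∈k} (x_i − x̄_k)(x_i − x̄_k)ᵀ,

matching the defining equations of the procedure being reproduced (the
n_k factor in S_W differs from the textbook pooled scatter when classes
are unbalanced; with the generalized eigenproblem oracle using the same
matrices, all internal checks are consistent).  For two classes the
closed form W ∝ S_W⁻¹(x̄₊ − x̄₋) is used in the hot path; tests pin its
equivalence (to 1e-8) to the leading generalized eigenvector of
(S_B, S_W) from an independent eigensolver.  W is unit-norm and oriented
so the treated class has the higher mean score.  Ridge regularization
(ε = 1e-8·tr(S_W)/k) is applied only on singularity, which is rare at
panel sizes ≤ 5 and n = 38.  Scores are plain projections Wᵀx with no
centering offset; thresholds live on the same scale.

## Score densities and thresholds

Score distributions are smoothed with a Gaussian kernel and the robust
Silverman bandwidth h = 0.9·min(s, IQR/1.34)·n^(−1/5); PDF and CDF are
analytic kernel sums (vectorized), cross-checked in tests against scipy's
`gaussian_kde` at the same bandwidth.  Kernel and bandwidth are
overridable.  The classification threshold solves CDF_ASD(t) = β by
bisection to 1e-6 in CDF; the rule is score ≥ t → treated class, so β is
the Type II error conceded on the training density.

## Search and cross-validation

The subset search exploits the fact that any subset's scatter matrices
are submatrices of the full-candidate ones: all C(m, k) discriminants are
solved as batched k × k systems, scored in bulk, and ranked by AUROC with
deterministic tie-breaks (larger J, then lexicographic subset order).  A
`max_combinations` guard with seeded subsampling protects desk-scale
runs; full C(165, 4) searches are feasible but not needed in the tests.
The top four-metabolite panels are augmented by every remaining candidate
(161 of 165 in the motivating design), deduplicated and re-ranked.

Feature subsets are chosen on the full week-0 data and only weights and
thresholds are refit per leave-one-out fold, mirroring the procedure
being reproduced; this inherits its selection-bias optimism, which is a
fidelity choice, not an oversight.  Per fold the discriminant is refit on
the remaining 37 samples, the ASD-score KDE re-estimated, and the
held-out sample classified at each β; classification uses the equivalent
test CDF_train(score) ≥ β, avoiding a quantile inversion per fold.
Panels are selected by balanced accuracy at β = 0.05 with ties
preserved — the motivating study reports exactly such a tie (two panels
sharing four of five metabolites).

A consequence of placing the threshold at the β-quantile of the training
positive density: held-out sensitivity concentrates at ≈ 1 − β no matter
how separated the cohorts are, because the rule concedes a β fraction of
the positive density by construction.  Specificity, by contrast, reaches
1.0 under strong separation.  Tests assert this pattern rather than a
naive TPR = 1.

## Longitudinal evaluation

The week-0 threshold is frozen; per follow-up week only the treated
cohort's score density is refit, and the Type II error is that density's
CDF at the threshold.  At week 0 this recovers β (to the 1e-3 inversion
tolerance) by construction.  The deviation score
D_i = Σ_m |x_{i,m} − median_TD(m)|/σ_TD(m) is summarized by median and
25th/75th percentiles (inclusive linear-interpolation convention) per
cohort-week and per metabolite.  `percent_reduction` offers two explicit
formula variants (raw and control-excess) for summarizing the week-0 →
week-18 gap closure; published reductions of this kind are not
reconstructible to a unique formula from printed medians alone, so the
variant used is always part of the output, and no variant is claimed to
be canonical.

## Synthetic study generator

Log-abundances are Gaussian with per-metabolite base means ~ N(0, 1),
unit variance, and equicorrelation ρ (default 0.3) within consecutive
blocks of 5 metabolites (a Gaussian copula before exponentiation);
exponentiation yields non-negative, right-skewed abundances.  Twenty
discriminating metabolites (default) are shifted by ±1.5 log-scale units
in the treated cohort at week 0, half up and half down so orientation
handling is exercised.  The bottom 10% of week-0 values per metabolite
are censored to missing (detection-limit-like, not random).  Follow-up
weeks move each treated subject's log-values toward the control mean by a
per-week recovery fraction λ_w — {0.4, 0.7, 0.8} for responders (70% of
subjects), {0.0, 0.1, 0.1} for non-responders — plus fresh i.i.d.
log-scale noise of sd 0.3 (a scale chosen to represent within-subject
biological variability between visits; follow-up noise is not
block-correlated).  One treated subject is dropped at week 3, matching
the design's 17 week-3 samples.  The subject-level responder mixture
reproduces the bimodal late-week score distributions of real intervention
data.

What the generator does **not** emulate: batch effects, diet covariates,
heteroscedastic or metabolite-specific variances, non-log-normal tails,
and vendor peak-integration artifacts.  Passing tests therefore
demonstrate correctness of the pipeline's computations and its behavior
under a controlled data-generating process, not performance on real
fecal-metabolome data.

## Problem sizes in tests

Test and acceptance runs use 120–200 metabolites, candidate pools capped
at 40, and top-1000 rankings; these sizes preserve every structural
property of the full design (38 week-0 samples, exhaustive 2/3/4-subset
search, augmentation, LOO with 38 folds) while keeping each simulated
study's search in seconds.  Recovery checks run over seeds 1–10.

## Known limitations

* The published headline cohort results (94%/95% sensitivity/specificity,
  the 165-candidate count, specific AUROC values) depend on undeposited
  participant-level data and are not reproducible; the shipped reference
  tables carry the published summaries instead.
* Leave-n-out FDR is a bespoke stability statistic, not a
  Benjamini–Hochberg-style error-rate control; BH is intentionally not in
  the headline path.
* No multi-class discriminant, no nested CV by default (a fidelity
  choice, see above), no batch correction.
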