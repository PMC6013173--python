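# Methods

## The response: breadth of expression as a binomial proportion

Each transcript's breadth of expression (BoE) is the fraction of
expression libraries in which it exceeds a TPM cutoff. The cutoff is
strict (`> 10 TPM`; a cell exactly at the cutoff counts as off), and the
response is carried through the pipeline as (successes *k*, trials *n*)
rather than as the ratio, so binomial error structure is preserved. The
default *n* = 1660 matches the number of CAGE libraries in the
full-scale expression panel. The regression tree is the one component
that consumes the plain proportion, because its deviance criterion is a
sum of squares about node means.

## Data integration

Coordinates are 0-based half-open (BED convention) throughout. Promoter
windows are symmetric, `[tss − w, tss + w)` with *w* = 500 bp by default,
clipped at zero; strand never changes the window, it only defines which
annotated coordinate is the TSS. Peaks are filtered on quality score
strictly above 500 (of 1000), then assigned to windows **by midpoint**
(`floor((start+end)/2)`): midpoint assignment makes counting independent
of peak length and gives each peak a unique location, while a peak whose
midpoint falls into two overlapping windows counts in both, because each
transcript's architecture is defined independently. Architectures are
multisets — two peaks of the same TF in one window count twice. Transcripts
sharing (chrom, strand, tss) share a promoter and are collapsed to one
representative, the lexicographically smallest transcript id (the
grouping is what matters; the tie-break is a convention).

Architecture size comes in raw (sum of counts) and unique (number of
distinct TFs) variants, each with optional exclusion of polymerase
columns. Polymerase-II covariates can be excluded from model inputs
altogether: polymerase occupancy is a consequence of activation, not a
cause, and controlling for it would mask the TF effects of interest.

## Correlation structure and collinearity

TF–TF association is measured by Spearman's ρ (Pearson on mid-ranks).
Asymptotic p-values use t = ρ√((M−2)/(1−ρ²)) with M−2 df. Because
genome-wide count columns are not a sample from a population, significance
is additionally judged against an empirical permutation null: each of 10
permutations shuffles every TF column independently across transcripts
(destroying co-binding, preserving marginals), all pairwise ρ are pooled,
and the 2.5 % / 97.5 % nearest-rank order statistics become the rejection
thresholds. Nearest-rank quantiles keep the thresholds deterministic.
On tie-free data the thresholds approach ±1.96/√(M−1); heavy zero-ties in
real count data shift them asymmetrically. Whether the null should
instead preserve within-promoter co-occurrence (shuffling whole
architectures) is an open modelling question; the per-column scheme was
chosen because a null of "no co-binding" is exactly what the correlation
table is tested against.

Variance inflation factors are 1/(1−R²) from OLS of each column on all
others plus an intercept; exact collinearity returns an infinite
sentinel. Pruning runs in two modes: a manual removal list (reproducing
curated one-per-antibody-pair choices) or greedy removal of the highest
VIF until all fall below the cutoff (default 10). The correlogram
ordering is complete-linkage agglomerative clustering on distance 1 − ρ.

## The model family

**Quasibinomial GLM.** IRLS on the binomial log-likelihood with logit
link. The dispersion φ is estimated as Pearson χ²/(M−N−1) from an
initial fit and then fixed, scaling standard errors by √φ; p-values use
the t reference with M−N−1 df. (The fit is computed via the
statsmodels GLM backend; its built-in `scale='X2'` option mis-handles
the two-column successes/failures response, so φ is computed from
`pearson_chi2` explicitly — verified ≈1 on data simulated without
overdispersion.) Coefficients with |θ| > 15 on the logit scale are
flagged as separation.

**Penalized paths.** Lasso (α=1), ridge (α=0), elastic net (α=0.5)
minimize the mean negative binomial log-likelihood plus
λ·(α‖θ‖₁ + (1−α)/2·‖θ‖₂²), intercept unpenalized, columns scaled to
unit variance internally and coefficients reported on the count scale.
The λ grid has 100 points by default (fewer in the scaled-down test
configurations), log-spaced from λ_max — the score bound at the
intercept-only fit, below which the first coefficient enters — down four
orders of magnitude, warm-starting each fit from the previous one.
λ_min minimizes the fold-averaged mean squared error of predicted versus
observed BoE proportions over seeded 10-fold splits; MSE on proportions
(rather than deviance) is the criterion because the cross-model
comparison table is defined in those units. As λ→0 the path converges to
the unpenalized GLM (asserted to 1e−3 in tests); the α=0 solution is
checked against an independent BFGS minimization of the same objective.

**Bayesian GLM.** Binomial-logit likelihood with independent N(0, 10)
priors on all parameters, sampled by adaptive random-walk Metropolis:
chains are preconditioned with the Laplace approximation at the
posterior mode (proposal covariance = inverse of the Hessian there) and
the global step size adapts during warm-up toward a 0.3 acceptance
rate. Four chains of 1000 iterations, split evenly between warm-up and
sampling; convergence is summarized by split-chain R̂ (a warning is
raised above 1.1, the fit still returned). Point estimates are posterior
medians, which match the MLE to <0.05 in the large-data checks.

**Interactions.** Product terms x_a·x_b are added for every TF pair
co-occurring in at least 10 promoters (fitting all ~9000 products of
~140 TFs jointly is ill-conditioned; the co-occurrence filter keeps the
design estimable) and fit in one joint quasibinomial model. Product
columns linearly dependent on the existing design are dropped and
reported. Adding terms can only decrease residual deviance (nested
models), which the tests assert.

**Binary recode.** The three transcript clusters are recoded as
housekeeping-versus-rest and fit with the same penalized machinery on
0/1 trials, standing in for multinomial regression.

## Tree, regulatory logic, clusters, forest

The regression tree greedily picks the (variable, threshold) split
maximizing the reduction in sum-of-squares deviance; thresholds are
midpoints between consecutive observed values, so presence/absence
predictors always split at 0.5. Ties go to the lowest column index, then
the lowest threshold. Splitting stops below 6 observations, at zero
deviance, when no split reduces deviance, or at a depth cap (default 6,
for readability; deviance-sum conservation root = leaves + reductions is
asserted). Rendered trees (n, deviance to 4 significant digits, mean BoE
per node) parse back losslessly.

Regulatory logic stratifies transcripts by a TF's exact site count (0–3,
higher counts pooled into 3; strata of ≤3 transcripts are ineligible).
Non-decreasing stratum means ⇒ activating; non-increasing with a drop
from 0 to 1 site ⇒ inhibitory; a rise from 0→1 followed by a
statistically significant drop (two-sided Wilcoxon rank-sum, exact for
small tie-free samples, normal approximation with tie and continuity
corrections otherwise) ⇒ saturating. A mean dip that fails the Wilcoxon
test does not override an activating call — only the saturating call
carries a significance requirement, since a noisy dip in a small stratum
should not reclassify an activator. Whether inhibitory calls should also
require a test is left open; monotone decreasing means were accepted
as-is.

k-means (k = 3, Forgy initialization, Lloyd iterations, best of 10
restarts by within-cluster sum of squares) partitions transcripts on raw
(architecture size, BoE) coordinates — no standardization by default,
since the plane is interpreted in those units; a flag enables it.
Clusters are named from their centroids: highest mean BoE ⇒
housekeeping; smaller mean size of the rest ⇒ tissue-specific; the
remainder (large architectures without broad expression) ⇒ atypical.
One-way ANOVA F statistics summarize per-variable separation.

The random forest grows bootstrap regression trees (features subsampled
per split, a third of variables) with a package-owned bootstrap so
out-of-bag indices are explicit; importance is the percent increase in
out-of-bag MSE when a variable's out-of-bag values are permuted.
Omission-refit importance would cost a refit per variable; OOB
permutation matches the intended "increase in MSE without the variable"
reading at ensemble cost. Uninformative variables can come out slightly
negative.

The dual-promoter enrichment is the cross-product odds ratio ad/bc of
the 2×2 table with an exact hypergeometric two-sided p-value, or a
Monte Carlo p over tables with fixed margins (the (1+count)/(reps+1)
estimator). The cross-product form is used because it is the ratio the
headline "enrichment" number corresponds to; a risk ratio does not
reproduce it.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with ground
truth retained:

- **Sparsity and empty architectures.** A fraction E of rows (default
  0.27) is empty by design; remaining rows draw iid Bernoulli cells
  *conditioned on at least one site*, at the cell rate solving
  E + (1−E)·(s−s^N)/(1−s^N) = S for overall zero fraction S (default
  0.95). Conditioning makes both targets exact for any feasible (S, E);
  combinations demanding a conditioned zero fraction above (N−1)/N are
  rejected as infeasible — at 148 TFs the full-scale defaults are
  comfortably feasible, but the same S and E cannot be realized with,
  say, 10 columns, which the validation reports rather than silently
  missing the target.
- **Counts.** Occupied cells hold 1 + Geometric counts with mass
  0.6/0.24/0.096 on 1/2/3 sites, keeping counts above three rare, which
  is what the 0–3 stratification of the logic classifier needs.
- **Correlated pairs.** The second column of a pair copies the first
  column's full cell value with probability equal to the target ρ, else
  keeps an independent same-marginal draw. The copy-mixture controls
  Spearman ρ directly (measured ρ ≈ target within ±0.1 at M ≥ 2000)
  without the attenuation a shared-presence-only latent would introduce
  at the count level.
- **Response.** η_i = θ0 + Σ f_j(x_ij), with f linear for activating and
  inhibitory TFs and θ·min(x,1) + penalty·max(x−1,0) for saturating
  ones; successes are Binomial(n, logit⁻¹(η)). Default class mix is 90 %
  activating (θ ∈ [0.1, 0.4]), 5 % inhibitory (θ ∈ [−0.6, −0.2]), 5 %
  saturating (θ ∈ [0.4, 0.7], penalty ∈ [−2, −1]), reflecting the
  dominance of activators among classified factors and the magnitude
  range of per-site log-odds effects on BoE.
- **Expression tables.** "On" cells are log-normal around 100 TPM
  shifted strictly above the cutoff, "off" cells log-normal around 1 TPM
  redrawn uniformly below it where the tail crosses — so thresholding the
  written table reproduces the target response exactly (asserted as a
  round-trip).
- **Files.** Transcripts are laid out on one synthetic chromosome with
  disjoint windows; planted sites become high-QS peaks with midpoints
  inside their window, plus low-QS decoys the filter must remove.

One master seed fans out to per-stage child generators (CRC32 of the
stage name into a `SeedSequence`), so each stage is individually
reproducible and identical configs give bitwise-identical outputs.

What the generator does **not** emulate: realistic peak length
distributions, genomic clustering of peaks, chromosome structure,
between-sample correlation in expression, or overdispersion beyond the
binomial (φ ≈ 1 by construction when effects are linear). Passing
recovery tests therefore demonstrate estimator correctness under the
assumed model, not robustness to the ways real promoter data violate it
— notably, real BoE shows overdispersion that the quasibinomial φ
absorbs but the generator does not produce.

## Problem sizes in the shipped checks

The test and acceptance configurations are scaled to what the analysis
needs rather than to the full 20 403 × 148 study: coefficient recovery
uses 50 (tests) or 20 (script) datasets of 5000 transcripts × 20 TFs at
n = 1660; logic recovery 20 (tests) or 10 (script) datasets of 20 000
transcripts × 15 TFs; permutation calibration 5000 × 40 tie-free
columns; the model-family comparison one 3000 × 15 dataset with a
30-point (tests) or 20-point (script) λ grid. At these sizes the
recovery coverage (~95 % within 2 SE), null rejection rate (~5 %), logic
accuracy (~100 %) and cross-model ρ (>0.99) are stable across seeds.

## Known limitations

- The permutation null's per-column scheme is one of two defensible
  readings of "transcriptome-wide permutation" (see above).
- The binary recode is a stand-in for true multinomial regression; the
  atypical/tissue-specific distinction is not modelled.
- The Metropolis sampler is adequate for the ≤ 150-parameter logistic
  posteriors it targets but has lower effective sample sizes than
  gradient-based samplers; R̂ is surfaced so poor mixing is visible.
- Greedy VIF pruning need not find the smallest removal set; the manual
  mode exists for curated choices.
- Tree tie-breaking (lowest column, lowest threshold) is a convention;
  other implementations may return different but equally-scoring trees.
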