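# Methods

This note records the models and procedures `milknet` implements, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

The input is a samples × proteins matrix of label-free quantification (LFQ)
intensities with a 2×2 design over maternal allergy (M±) and child allergy
(C±). Zeros and blanks in LFQ exports denote non-detection, not true zeros,
and are mapped to missing on read (`missing_policy="zero-as-missing"`; a
`"blank-only"` mode exists for exports where zeros are meaningful).

**Group-validity filter.** A protein is retained if it has at least
`min_valid` (default 25) observed values in *at least one* of the four
groups. The one-group rule deliberately keeps proteins expressed in a single
group — exactly the proteins a differential analysis cares about. "Valid"
means non-missing after zero-mapping; the filter runs before the log
transform. The filter is monotone in `min_valid` (raising it never adds a
protein), which the suite asserts.

**Left-censored MNAR imputation.** Missingness in LFQ data is assumed
informative: the probability of non-detection rises as the true abundance
falls below the instrument's effective limit (missing-not-at-random,
left-censored). The imputer works on the log10 scale, where the censoring
geometry is additive:

1. initialise each missing cell at `init_fraction` (default 0.9) of its
   protein's observed minimum;
2. per sweep, regress each incomplete protein on its `n_predictors`
   (default 40) most |correlation|-ranked peers over the current completed
   matrix, with closed-form ridge (`predictor_regularization`, default 1.0);
3. redraw the protein's missing cells from a normal centred at the
   prediction with the residual sd, truncated **above** at the protein's
   observed minimum — the left-censoring constraint;
4. stop after `sweeps` (default 20) or when the mean relative change of
   imputed cells drops below 1e-3; return the mean of the last
   `average_last` (default 5) sweeps.

Observed cells are never altered (exact equality, asserted), and every
imputed value respects the truncation bound. The truncation bound is the
per-protein observed minimum — the conventional choice for detection-limit
censoring; the scheme is a ridge-regularised simplification of elastic-net
Gibbs imputers used in metabolomics/proteomics. Imputation runs once on the
pooled matrix by default (all downstream stages consume the single completed
matrix); a `per_group` mode imputes inside each design group independently
for users who suspect group-specific censoring.

**Scaling.** Unit-variance scaling (mean 0, sample variance 1 per protein)
is applied only for PCA and Random Forest; correlations and networks use
the unscaled completed log10 matrix, to which rank-based statistics are
invariant anyway.

## Univariate screening

Kruskal–Wallis (tie-corrected H, chi-square reference on 3 df for four
groups) screens each protein, with Benjamini–Hochberg correction across
proteins. Complete ties are reported as H = 0, p = 1. Proteins passing an
**uncorrected** KW p < 0.05 gate — the workflow's explicit, if
unconventional, screening rule — enter Dunn's pairwise post-hoc tests:
z = (mean rank difference)/SE with the tie-corrected variance, ranks taken
over all groups jointly. Dunn p-values are BH-corrected over the pooled
family of all (protein, pair) tests, the conservative reading when the
correction family is ambiguous; a per-protein family mode is provided.
Trend direction is the difference of group means of log10 abundance (means,
not medians, to match how abundance trends are usually displayed).

## PCA and Random Forest

PCA runs on the scaled matrix with component signs canonicalised
(largest-|loading| entry positive) so output is reproducible. The Random
Forest classifiers use out-of-bag (OOB) votes as internal validation —
accuracy, sensitivity, specificity and AUROC from OOB class-probability
votes — avoiding the need to invent an external cross-validation protocol.
Significance is a label-permutation test: each permutation refits the full
forest with a derived seed, and p = (1 + #{permuted ≥ observed})/(B + 1),
which is bounded below by 1/(B + 1). Defaults are 500 trees, √p features
per split and B = 1000 permutations, all recorded in the run manifest.
Tests run at smaller B and tree counts; the p-value floor and null
calibration do not depend on scale.

## PCLRC association networks

For one group's samples × proteins block:

1. **Spearman matrix** with average-rank ties; constant proteins get zero
   correlation (with a warning) rather than NaN.
2. **CLR background correction** on M = |r| with the diagonal excluded from
   row statistics: z⁽ⁱ⁾ᵢⱼ = max(0, (Mᵢⱼ − μᵢ)/σᵢ) with the *population* sd
   σᵢ over the off-diagonal row, CLRᵢⱼ = √(z⁽ⁱ⁾² + z⁽ʲ⁾²); σᵢ = 0 rows
   contribute z = 0. CLR suppresses nonspecific correlation: an edge only
   scores high if it stands out against *both* partners' backgrounds.
3. **Resampling**: `n_iterations` = 1000 times, draw 75% of the samples
   without replacement, recompute Spearman + CLR, and mark the top
   `keep_fraction` = 0.30 of upper-triangle edges as retained. Ties in the
   top-k selection break deterministically by (score, protein-index pair)
   stable sort. The retention frequency is the edge probability pᵢⱼ; by
   construction the mean upper-triangle pᵢⱼ equals `keep_fraction` exactly
   whenever keep_fraction × #pairs is integral.
4. **Thresholding**: weights are the full-data signed Spearman values where
   pᵢⱼ ≥ τ (τ = 0.99), zero elsewhere; diagonal 1.

`keep_fraction` = 0.30 is the published default of the PCLRC method itself
(the protocol text fixes only the iteration count and subsample fraction);
it is exposed in config. The threshold comparison uses ≥ 0.99 (the
equation-form convention) rather than strictly greater; configurable. CLR
operates on unsigned correlations while retained weights keep their sign —
connectivity uses |weights|, so the sign convention does not affect χ.

**Connectivity and differential connectivity.** χᵢ = (Σⱼ |rᵢⱼ|) − 1 with
the unit diagonal cancelling the −1; on a binary network χ is the node
degree (cross-checked against an independent graph library). Δᵢ between two
group networks is the elementwise difference of χ profiles.

**Permutation inference for Δ.** No analytic null for Δ exists, and the
original workflow does not describe one; the test here is this package's
construction: pool the two groups' samples, permute the group assignment
preserving sizes, rebuild both networks with a reduced resampling budget
(`n_iterations` default 100 per permutation, for tractability) and recompute
Δ. The observed Δ uses the same reduced budget so observed and null
statistics are exchangeable. Two-sided raw p = (1 + #{|Δperm| ≥ |Δobs|})/(B+1),
BH across proteins. B ≥ 19 is enforced (below that p < 0.05 is unreachable).

**Candidate selection** takes |Δ| > `delta_threshold` (default 50, the
headline selection rule at study scale) per contrast against the reference
(double-negative) group, and reports the intersection across the three
contrasts. |Δ| is the default because rewiring in either direction is of
interest; a signed mode exists.

## COVSCA

The K group networks enter as matrices S_k; the model is
S_k ≈ Σ_l c_kl Z_l Z_lᵀ with c_kl ≥ 0 and unit-norm loading columns
(scale indeterminacy is folded into the weights). Networks are converted
with absolute weights and zero diagonal by default: absolute weights keep
the matrices near positive semidefinite, and a zero diagonal stops
self-edges (which carry no association information) from dominating the
Frobenius objective. Signed and unit-diagonal modes are options.

Fitting alternates two exactly optimal steps, so the objective
Σ_k ‖S_k − Ŝ_k‖²_F is monotonically non-increasing (asserted to 1e-12
relative slack):

- **weights**: per k, non-negative least squares over the prototype Gram
  (Cholesky-factored, NNLS);
- **loadings**: per l, the top-R_l eigenvectors of the weighted residual
  Σ_k c_kl (S_k − Σ_{m≠l} c_km Z_m Z_mᵀ), which maximise the trace term
  exactly under orthonormal columns.

Local minima are handled by multi-start: `n_starts` (default 20) random
orthonormal starts plus one spectral start (top eigenvectors of the mean
matrix); the best final objective wins. Component signs are canonicalised
(largest-|loading| entry positive). Defaults fit two rank-1 prototypes —
the configuration that balances fit against model complexity for four
networks; ranks > 1 are supported. Goodness of fit is
100 · (1 − Σ‖S − Ŝ‖²_F / Σ‖S‖²_F). Loadings are standardised to z-scores
per component and proteins with |z| > 2 flagged as drivers.

The study-scale GOF of a fit to real cohort networks is not a reproduction
target here: it depends on the exact adjacency convention (binarised or
weighted, diagonal handling) of the original analysis, which is not
recoverable from the text.

## Overrepresentation

Two-list mode: for a term annotating K of N background proteins and a
target of n proteins with overlap k, the p-value is the upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n), BH-corrected across terms. Terms
are flat labels from the annotation table; ontology hierarchy propagation
is out of scope, so externally supplied GO terms are tested as given.
Ranked-list (minimum-hypergeometric) modes are not implemented because the
two-list reduction is exact for a fixed target set.

## Synthetic data generator

The generator emulates the study conditions: four groups × 75 samples, 687
proteins, per-protein baselines μ_p ~ N(6.0, 0.5) on the log10 scale with
within-protein sd 0.8 — values typical of LFQ intensity distributions —
and left-censored logistic missingness. Structure is planted through a
per-group Gaussian copula on the log10 values:

- **blocks**: uniform within-block correlation ρ, active in named groups;
- **hubs**: a one-factor star — hub↔neighbor correlation ρ (default 0.9),
  neighbor↔neighbor ρ² — with group-specific neighbor counts, giving direct
  control of per-group connectivity ground truth;
- **shifted sets**: a keyword-tagged protein set with a log10 mean shift in
  one group.

Censoring is probabilistic rather than hard truncation: the per-protein
bound is the `censor_quantile` of its pooled true values, and a cell goes
missing with probability 1/(1 + exp((x − bound)/softness)) (softness 0.15
log10 units). This matches the MNAR/left-censored assumption while leaving
some low values observed — which the imputer needs to estimate the censoring
region. Because the censoring uniforms come from a dedicated stream, raising
`censor_quantile` with a fixed seed produces nested, strictly growing
missing sets.

Randomness is one master seed with a fixed stream layout (protein baselines,
censoring, one stream per group), so a configuration + seed is
bit-reproducible. The generator writes the exact input dialects the pipeline
reads (proteinGroups-style TSV with "LFQ intensity <sample>" columns, design
CSV, annotation CSV) plus a truth JSON.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: peptide-level evidence and rollup, technical
replicates and batch effects, heavy-tailed or multimodal abundance
distributions, the real cohort's (uncharacterised) correlation spectrum,
and annotation structure beyond flat keywords. Block/hub defaults are chosen
for testability, not biological realism.

## Problem sizes and numerical choices

The test suite and acceptance script run scaled-down problems chosen as the
smallest sizes at which each property is statistically meaningful: planted
structure recovery and hub inference at n = 75/group with 25 proteins (the
per-group sample size of the study design), type-I suites at 15–20 proteins
and 20 samples/group over 20 replicates, classifier nulls over 200
replicates, and pipeline determinism on a 4 × 20 × 40 dataset. Generator
defaults remain at study scale. Other numerical conventions: CLR uses the
population sd; Spearman ties use average ranks; BH is the standard step-up
with cumulative minimum; NNLS Gram matrices get a 1e-12-relative jitter
before Cholesky; imputation draws use scipy's truncated normal; the
pipeline writes TSVs with a fixed "%.10g" float format so identical
config + seed reproduces byte-identical files.

## Known limitations

- The Δ permutation null assumes exchangeability of samples across groups
  under the null; covariate-stratified subsampling is not implemented.
- The reduced per-permutation resampling budget trades p_ij precision for
  tractability; with τ = 0.99 a budget below ~100 iterations makes edge
  retention coarser and Δ noisier under the null as well as the
  observation, which the add-one permutation p absorbs but does not remove.
- COVSCA's alternating fit is monotone but not guaranteed to find the
  global optimum; multi-start mitigates, and the exact-model recovery tests
  bound the practical risk at small K and L.
- OOB metrics at very small tree counts can leave samples never out of bag;
  such samples receive an uninformative 0.5 vote (rare at the 500-tree
  default).
- The imputer assumes an approximately linear dependence among log10
  abundances; strongly nonlinear co-regulation would be under-exploited.
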