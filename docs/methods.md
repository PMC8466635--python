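# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `morphoprofile`, at the level of detail a user needs
to judge what the results do and do not mean.

## Data model

A study is a replicate-level table: rows are (strain, replicate experiment)
pairs, columns are morphological parameters plus the number of detected
cells per experiment. Only experiments with at least `min_cells = 200`
detected cells enter the analysis; if the wild type loses all replicates the
run aborts (there is no null distribution), while a mutant losing all
replicates silently drops out of downstream tests (with a logged warning).

Each parameter has a data type with its own admissible families:

| data type  | support      | candidate families                         | link     |
|------------|--------------|--------------------------------------------|----------|
| nonneg     | (0, ∞)       | gamma, inverse gamma, Weibull              | log      |
| ratio      | (0, 1)       | beta, logit-normal                         | logit    |
| noise      | ℝ            | Gaussian, logistic, reverse Gumbel         | identity |
| proportion | {0..trials}  | binomial, beta-binomial                    | logit    |

Proportions are carried as integer (successes, trials) pairs — the
likelihoods need counts — with trials supplied by a named column (the
detected-cell count of the relevant cell-cycle class). The logit-normal is
a Gaussian on logit-transformed values *with* the change-of-variables
Jacobian added to its log-likelihood, so its AIC is comparable to the beta's
on the original scale. "Reverse Gumbel" is the Gumbel distribution for
minima (left-skewed). Missing values are allowed per cell and excluded per
parameter at fit time.

## Family selection

The best family per parameter is the minimum-AIC maximum-likelihood fit
among the type's candidates (AIC = −2ℓ + 2k; ties under 10⁻⁹ go to the
family with fewer parameters, then to a fixed order). By default selection
uses wild-type data only — the null defines the model — with an `all`
option to pool strains.

Fitting is exact-profile maximum likelihood rather than a generic
black-box optimizer: group locations are closed-form (Gaussian, logit-normal,
binomial, gamma, Gumbel location) or monotone one-dimensional Newton solves
(beta mean, beta-binomial mean), and each remaining nuisance (shape, scale,
precision, overdispersion) is solved on its one-dimensional profile score by
a safeguarded Illinois root search with moment-based starting brackets. The
inverse-gamma fit reuses the gamma solver through the exact identity
InvGamma(α, β) on y ⇔ Gamma(α, 1/β) on 1/y. All solvers are vectorized over
a batch axis, which is what makes the permutation stage feasible: one numpy
program refits thousands of two-group models at once. Unit tests pin the
fits against scipy's and against grid-search profile-likelihood oracles.

## CV → noise

CV parameters are regressed on their paired mean with LOESS: local linear
regression, tricube kernel, no robustness iterations, span grid
f = 0.10, 0.11, …, 0.99. The span is chosen by an AIC for linear smoothers
with effective dimension tr(L) (L the smoother matrix); we use the
small-sample AICc form of Hurvich–Simonoff–Tsai,

    AICc(f) = n log(RSS/n) + n + 2n(tr(L) + 1)/(n − tr(L) − 2),

because the uncorrected penalty undersmooths badly at these sample sizes
(on pure noise it happily selects the smallest span). The noise value is
the residual, observed − predicted, evaluated at the row's own mean value;
outside the fitted range the curve continues linearly. By default the curve
is fitted on all rows pooled (`loess_on="all"`), so mutant means beyond the
wild-type range are interpolated rather than extrapolated; `"wt"` restricts
the fit to the wild type.

A consequence worth knowing: a strong perturbation of a *mean* parameter
moves its paired CV's prediction into a region where the smoother is less
accurate, which can surface as a genuine induced signal in the paired noise
parameter. This is a property of the CV-decoupling construction, not a bug;
simulation fixtures that need clean false-positive bookkeeping plant effects
only on parameters that are not CV partners.

## Wald Z and permutation FDR

For each (mutant, parameter): a joint two-group fit with location
η = β₀ + β₁·1{mutant} on the link scale and shared scale/shape;
Z = β̂₁/SE(β̂₁), positive when the mutant sits above the wild type on the
link scale. The SE comes from the inverse observed information, computed
*analytically* at the MLE in (η₀, η₁, nuisance) coordinates — the two group
locations share no observations, so that block is exactly zero — and
validated against central-difference Hessians in the test suite. Preconditions:
≥ 5 wild-type and ≥ 2 mutant replicates (the leave-one-out wild-type
profiles used by the similarity screen deliberately relax the mutant bound
to 1).

Significance is calibrated by permutation: for each of `n_perm` rounds
(default 2000), n_mut pseudo-mutant replicates are drawn from the wild-type
pool without replacement, the remainder serving as pseudo-wild-type, and the
full Z profile is recomputed with the same machinery. The same row subsets
are used across parameters, so each round is a coherent pseudo-mutant
profile. For thresholds t on the sorted observed |Z| grid,

    FDR(t) = mean_perm #{|Z_perm| ≥ t} × n_strains / #{|Z_obs| ≥ t},

clipped to [0, 1] and monotonized (running minimum toward larger t); the
global threshold t* is the smallest t with FDR(t) ≤ α (default 0.05). One
global threshold across strains and parameters mirrors a single FDR
statement; monotonization guarantees that raising α never shrinks the
flagged set. With zero rejections everywhere, t* = +∞ is recorded and
nothing is flagged.

## PCA and model-based clustering

The mutants × significant-parameters Z matrix (parameters flagged in at
least one strain; missing Z imputed as 0 = "no detected change") is reduced
by SVD after column centering, without scaling. The cumulative contribution
ratio (CCR) is the cumulative explained-variance fraction; the retained k is
the smallest with CCR ≥ the target (0.80 for clustering, 0.99 for the
similarity axes), with explicit override.

Clustering is EM for Gaussian mixtures under six covariance
parameterizations — EII λI, VII λₖI, EEI diag(λ), VVI diag(λₖ), EEE Σ,
VVV Σₖ — with k-means++ initialization (20 restarts, seeded), convergence at
relative log-likelihood change < 10⁻⁸, and a variance floor of 10⁻⁶.
A fit whose converged covariance has any eigenvalue at or below the floor is
rejected as degenerate: a near-singleton component's quasi-singular
covariance would otherwise inflate the likelihood and corrupt the BIC
contest (this mirrors the NA entries the reference R implementation reports
for singular fits). Selection minimizes BIC = −2ℓ + df·log(n) over the
(component count, code) grid; the full selection table is retained.
Per-strain assignments report the maximum posterior probability, flagging
values below 0.7 as uncertain. Clustering is skipped, with a recorded
reason, when fewer than two parameters are significant.

## Similarity and fitness screens

Wild-type PC axes are fitted on leave-one-out replicate Z-profiles: each
wild-type replicate is tested as a single-replicate pseudo-mutant against
the remaining replicates, avoiding self-inclusion bias. Query profiles are
centered with the wild-type mean, projected onto the loadings, and compared
by Pearson correlation over the first k scores (k at CCR ≥ 0.99). Note the
geometric caveat: the axes span at most (replicates − 1) dimensions, so with
fewer wild-type replicates than parameters the projection keeps only the
component of a query profile inside that subspace; similarity claims are
sharpest when replicates ≳ parameters, and the simulation fixtures are sized
accordingly.

Fitness values (e.g. logarithmic strain growth coefficients) get one-tailed
lower p-values under N(wt_mean, wt_sd²) and Storey q-values: π̂₀ is the
cubic least-squares smooth of #{p > λ}/(m(1 − λ)) over λ = 0.05…0.95 (step
0.05) evaluated at λ = 0.95, clipped to (0, 1]; q-values are the usual
step-up with the π̂₀ factor.

## Synthetic data

The generator emulates the structure the analysis assumes, at replicate
level (it does not simulate single cells or images):

* 490 unimodal parameters by default, split 220 nonneg / 110 ratio /
  110 CV / 50 proportion, categories drawn ~27/48/25% actin/cell/nucleus;
* per-parameter families drawn uniformly from the type's legal set, with
  natural parameters from realistic ranges (e.g. gamma shapes 8–120,
  beta precisions 30–300, beta-binomial overdispersion 0.003–0.03);
* CV columns generated as a·(mean/m₀)^(−1/2) + b times multiplicative
  Gaussian noise (a = 0.18, b = 0.02, noise SD 0.08), so LOESS has a real
  nonlinear dependency to remove;
* proportions as integer successes out of per-replicate class counts
  (three cell-cycle classes at 55/30/15% of detected cells);
* detected cell counts uniform in [200, 600]; an optional dropout rate
  produces sub-200 rows to exercise the filter;
* 5 replicates per mutant and a 100-replicate wild-type pool by default
  (the pool size is a free choice; a larger pool stabilizes the null).

Effects are expressed on the link scale in units of the wild-type link-scale
SD (delta-method approximations for beta and the count families), so one
effect-size knob is comparable across families. Each (parameter, strain)
block draws from its own seeded substream; with a fixed seed the wild type
and every unperturbed block are bit-identical whether or not effects are
planted elsewhere, which makes paired null/perturbed experiments exactly
counterfactual. `plant_clusters` partitions strains into k groups sharing
random unit directions over a common affected-parameter set, scaled by a
separation parameter, and returns truth labels.

What passing tests on these data do *not* show: real CalMorph parameters
are correlated across columns (the generator draws parameters
independently, except for the built-in CV–mean coupling), the
within-replicate/between-replicate variance split of real data is unknown,
and real morphological covariance structure shapes PCA axes in ways
independent columns cannot reproduce. Results about FDR calibration,
family recovery and cluster recovery are statements about the method's
mechanics, not about any particular organism.

## Simulation sizes used by the test suite

The acceptance-style checks run at the study's shape where that is what is
being tested (32 mutants × 490 parameters for FDR control, with 500
permutation rounds and 20 seeds; 32 points in 5 dimensions with 7 planted
clusters for model selection), and at reduced sizes where the property is
scale-free (pipeline determinism at ~76 parameters; similarity screens at
60 parameters with an 80-replicate wild type so the PC axes are full-rank).
In the paired FDR studies the wild-type pool is identical between the null
and planted datasets by construction, so the null model, LOESS curves
(fitted on the wild type) and permutation profiles are computed once per
seed and shared.

## Known limitations

* The Wald SE uses asymptotic observed information; with 5 mutant
  replicates the null Z is mildly heavy-tailed for shape-estimated families
  (notably Weibull), which the permutation calibration largely — not
  perfectly — absorbs.
* The permutation scheme resamples the wild-type pool only (the scheme the
  analysis defines); it cannot see variance components specific to fresh
  mutant draws.
* LOESS prediction error propagates mean effects into paired noise
  parameters (see above).
* The 14-code mclust family is deliberately reduced to 6 codes covering
  spherical/diagonal/full × equal/varying.
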