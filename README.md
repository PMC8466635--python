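# morphoprofile

High-dimensional morphological phenotyping of yeast deletion mutants, from
replicate-level tables of image-derived parameters (CalMorph-style: up to
~500 named parameters per experiment, annotated by biological category and
data type) to per-mutant statistical profiles, significance calls, clusters
and similarity screens.

The pipeline implements, stage by stage:

1. **Unimodal GLM families.** Each morphological parameter is one of four
   data types and is modeled by the best of a small set of unimodal
   distributions, chosen by AIC: gamma / inverse gamma / Weibull for
   non-negative parameters; beta / logit-normal for ratios in (0,1);
   Gaussian / logistic / reverse Gumbel for noise parameters; binomial /
   beta-binomial for proportions with trial counts.
2. **CV → noise decoupling.** Coefficient-of-variation parameters depend
   nonlinearly on their paired means; LOESS regression (tricube, local
   linear) with an AICc-selected span f ∈ [0.10, 0.99] removes the
   dependency, and the residual ("noise") replaces the CV.
3. **Wald Z-profiles.** For every (mutant, parameter) a two-group GLM is
   fitted jointly to the wild-type replicate pool and the mutant replicates
   — location on the family's link scale is `β₀ + β₁·1{mutant}`, scale and
   shape shared — and `Z = β̂₁ / SE(β̂₁)` with the standard error from the
   inverse observed information.
4. **Permutation FDR.** Pseudo-mutants drawn from the wild-type pool
   recalibrate the |Z| threshold: `FDR(t) = E_perm[#{|Z| ≥ t}]·S / #{obs ≥ t}`,
   with one global threshold at FDR 0.05 (2000 permutations by default).
5. **PCA + Gaussian-mixture clustering.** Significant-parameter Z-profiles
   are reduced by PCA (centered, unscaled; retained components by the
   cumulative contribution ratio, CCR) and clustered with EM under
   mclust-style covariance codes (EII, VII, EEI, VVI, EEE, VVV), the model
   and component count chosen by BIC.
6. **Similarity & fitness screens.** Query profiles (mutants or drug
   treatments) are projected onto PC axes of the wild-type replicate
   profiles (CCR ≥ 99%) and compared by Pearson correlation of the first k
   scores; fitness values get one-tailed Gaussian p-values against the
   wild-type distribution and Storey q-values.

Because raw CalMorph measurement tables for published studies are typically
not deposited, the package ships a first-class synthetic-data generator
(`morphoprofile.synthetic`) that reproduces the statistical structure the
analysis assumes — per-type generative families, the nonlinear CV–mean
coupling, integer (successes, trials) proportions, a wild-type replicate
pool, and planted mutant effects / cluster structure with truth tables — so
every stage is testable end to end.

## Worked example

```python
from morphoprofile import (GeneratorConfig, PipelineConfig, generate_dataset,
                           plant_clusters, run_pipeline)

cfg = GeneratorConfig(seed=9, n_mutants=15, n_wt_replicates=40,
                      n_params={"nonneg": 30, "ratio": 14, "cv": 10,
                                "proportion": 6})

# plant cluster effects on parameters that are not CV mean-partners
# (perturbing a partner also induces a real signal in its paired noise
# parameter; see docs/methods.md)
probe, _ = generate_dataset(cfg)
partners = {probe.meta[p].mean_partner for p in probe.param_ids
            if probe.meta[p].data_type == "cv"}
plantable = [p for p in probe.param_ids if p not in partners
             and probe.meta[p].data_type in ("nonneg", "ratio")]

effects, labels = plant_clusters(k=3, n_strains=15, separation=8.0,
                                 n_sig_params=24, seed=9, param_ids=plantable)
ds, truth = generate_dataset(cfg, effects)
res = run_pipeline(ds, PipelineConfig(n_perm=150, seed=9,
                                      c_range=(1, 2, 3, 4, 5)))
for line in res.stage_log:
    print(line)
```

prints (timings vary):

```
filter_min_cells: 115 rows, 16 strains (0.03s)
noise: 10 cv parameters decoupled (0.65s)
families: 60 parameters modeled (0.24s)
z_matrix: 15x60 grid (0.32s)
permutation_fdr: t*=2.98, 27 significant parameters (actin/cell/nucleus = 5/15/7) (0.57s)
pca: k=2 PCs, CCR=90.38% (0.00s)
gmm: c=3, model=EEE, BIC=135.2 (1.33s)
```

Reading: of 60 analyzable parameters, 27 are perturbed in at least one
mutant at permutation FDR 0.05 (global |Z| threshold 2.98), split 5/15/7
across the actin / cell / nucleus categories; two principal components
carry 90.4% of the profile variance, and BIC selects a three-component
mixture — recovering the three planted mutant clusters exactly
(`adjusted_rand_score(labels, res.assignments["cluster"]) == 1.0`).

The same stages are available from the shell:

```bash
morphoprofile simulate --seed 7 --clusters 3 --out sim/
morphoprofile run --table sim/morph_table.tsv --meta sim/meta_table.tsv \
    --n-perm 500 --seed 7 --out out/
morphoprofile fitness --values lsc.tsv --wt-mean 0.0 --wt-sd 0.05 --out q.tsv
```

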