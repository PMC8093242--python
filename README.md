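# cvsem — latent-factor multi-trait GWAS for symptom questionnaires

`cvsem` is a Python toolkit for genome-wide association analysis of
syndromes that are measured only indirectly, through batteries of
correlated symptom ratings.  The motivating application is computer vision
syndrome (CVS): 14 Likert items covering four symptom categories
(asthenopic, ocular-surface-related, visual, extra-ocular), each rated
under a "before eye use" and an "after eye use" condition, with the
per-item delta carrying the signal.  Rather than scanning each symptom
separately, the package assumes one common latent severity factor behind
the four category scores and tests each genetic variant for an effect on
that factor.

## The model

For subject *i* with category scores *y*<sub>*i*</sub> ∈ ℝ⁴, dosage
*g*<sub>*i*</sub> ∈ {0,1,2} and covariates *c*<sub>*i*</sub> (age, sex,
ancestry PCs):

```
F_i  = β g_i + b' c_i + ζ_i          ζ_i ~ N(0, 1)      (structural part)
y_ik = γ_k F_i + ε_ik                ε_ik ~ N(0, δ_k)    (measurement part)
```

The latent residual variance is fixed to 1 for identification, so the
loadings γ<sub>k</sub> and the per-variant path coefficient β are on the
latent-residual-SD scale.  Everything is estimated by maximum likelihood
on the conditional multivariate-normal likelihood; the per-variant Wald
test *z* = β̂/SE(β̂) yields the GWAS p-value, subsequently adjusted by
median-based genomic control (λ<sub>GC</sub>).

Around that core the package provides the full working pipeline:

- **synthetic data** — HWE genotypes with block-AR(1) LD, Likert
  questionnaires generated forward through the factor model, and paired
  eQTL summary statistics with a shared / distinct / absent causal
  variant, all with a ground-truth sidecar;
- **genotype QC** — call rate ≥ 0.95, MAF ≥ 0.01, Hardy–Weinberg exact
  test p > 1e-6 (Wigginton-style), PLINK-style method-of-moments PI_HAT
  relatedness (< 0.1875), reference-anchored stratification PCA;
- **model specification** — delta scores, category aggregation, pairwise
  partial correlations, Gaussian-graphical-model covariance selection by
  backward AIC search (IPF refits), item PCA;
- **scan post-processing** — genomic control, LD-based locus definition
  (leads at p < 1e-5, members at r² > 0.6), Manhattan/Q–Q exports;
- **colocalization** — Wakefield log-ABFs and the five-hypothesis
  posterior (PPH0…PPH4) between GWAS and eQTL signals in ±100 kb regions.

## Worked example

```python
from cvsem import (SimulationConfig, simulate_genotypes, simulate_covariates,
                   simulate_phenotypes, delta_scores, category_scores,
                   OneFactorModel, fit_variant_model)

cfg = SimulationConfig(n_samples=1998, n_variants=500,
                       causal_variants=[(250, 0.132)], seed=42)
geno = simulate_genotypes(cfg)
cov = simulate_covariates(cfg)
questionnaire, truth = simulate_phenotypes(geno, cfg, cov)

cats = category_scores(delta_scores(questionnaire))
print(OneFactorModel(cats).fit().summary())
```

```
One-factor measurement model (ML, latent variance fixed to 1)
  n_obs = 1998, indicators = 4
  chi-square = 0.379  df = 2  p = 0.827
  RMSEA = 0.000  (90% CI 0.000-0.026)
  loglik = -11296.858   converged = True

  indicator          loading       SE   resid var       SE
  asthenopic          0.8799   0.0254      0.5404   0.0292
  ocular_surface      0.6402   0.0255      0.8065   0.0297
  visual              0.7366   0.0268      0.8452   0.0327
  extra_ocular        0.7947   0.0243      0.5534   0.0263
```

The fitted loadings are close to the generating values (0.842, 0.657,
0.787, 0.823) up to the attenuation introduced by Likert discretisation
and the before/after differencing.  Testing the causal variant:

```python
g = geno.dosages[:, 250]
z = (g - g.mean()) / g.std()
beta, se, zval, p = fit_variant_model(cats, z, covariates=cov).effect("dosage")
# beta=0.104 se=0.025 z=4.08 p=4.43e-05
```

β̂ ≈ 0.10 versus the generating 0.132 — again attenuated by the ordinal
measurement; fitting on the continuous category scores
(`simulate_category_scores`) recovers 0.132 without bias.

## Command line

```
cvsem run --config pipeline.yaml
```

chains simulate → qc → prep → fit → gwas → coloc and writes per-stage
TSV/JSON artefacts plus a `manifest.json` (seed, λ_GC, loci, coloc hits).
Individual stages are available as `cvsem simulate|qc|prep|fit|gwas|coloc`,
and `cvsem gwas --geno in.vcf --pheno pheno.tsv --covar covar.tsv --out dir`
runs a scan directly from files.  The YAML config surfaces every
threshold (QC cut-offs, suggestive/genome-wide p, locus r², coloc flank
and priors); unknown keys are rejected.

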