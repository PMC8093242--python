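# Methods

## The measurement model

Four symptom-category scores (asthenopic, ocular-surface-related, visual,
extra-ocular — each the mean of its member items' after-minus-before
deltas) are modelled as indicators of a single latent severity factor:

Σ(θ) = γγ′ + diag(δ),   latent variance fixed to 1.

`OneFactorModel` minimises the Wishart ML discrepancy
F = log|Σ| + tr(SΣ⁻¹) − log|S| − p with the sample covariance S computed
with denominator N−1, so the fit statistic is χ² = (N−1)·F with
df = p(p+1)/2 − 2p = 2 for p = 4.  Standard errors come from the inverse
expected information ½(N−1)·tr(Ω Σᵢ Ω Σⱼ).  RMSEA is
√(max(χ²−df,0)/(df(N−1))); its confidence interval inverts the noncentral
chi-square at the (1±confidence)/2 tails (default confidence 0.90) and is
clamped at zero below.  The factor's sign indeterminacy is resolved by
reporting γ₁ ≥ 0.

Identification notes.  Fixing the latent variance (rather than one
loading) matches loadings reported on a standardised scale.  The df of 2
is what the 4-indicator covariance-only model implies; when exogenous
predictors are present the fit statistic is a likelihood ratio against
the saturated conditional Gaussian model (unrestricted multivariate
regression plus free covariance), giving df = pk + p(p+1)/2 − (2p+k).

## The per-variant model

`LatentRegressionModel` adds exogenous predictors x (dosage first, then
covariates) to the structural equation F = b′x + ζ with Var(ζ) = 1, so
y | x ~ N(γ(b′x), γγ′ + diag(δ)).  Both sides are mean-centred, which
saturates the mean structure; the likelihood then depends on the data
only through Y′Y, Y′X, X′X, making each evaluation O(p³ + p²k)
independent of N — this is what makes a genome-wide scan of SEM fits
affordable.  Estimation is quasi-Newton (L-BFGS-B) with the analytic
gradient of the negative log-likelihood, gradient tolerance 1e-8, bounds
δ ≥ 1e-6 (a solution at this floor is flagged as a Heywood case), and up
to five jittered restarts.  A solution whose projected gradient is below
1e-6·N is accepted even when the line search terminates abnormally.
Per-variant scans warm-start every fit from the variant-free model with
the dosage effect at zero.

Standard errors are taken from the observed information, computed as
central differences of the analytic gradient (step 1e-5, symmetrised);
with γ appearing in both the mean and the covariance this is simpler and
more robust than assembling the expected information blockwise.  The
GWAS test is the Wald z = β̂/SE with p = 2Φ(−|z|).

Because the latent residual SD is the unit, β is comparable across
variants and directly against the generator's effects when the dosage is
standardised.  Missing data are handled by complete-case analysis (counts
recorded); monomorphic variants are skipped and counted.

## Genome scan post-processing

λ_GC = median(z²)/0.4549364 (the χ²₁ median).  Statistics are deflated
(z²/λ, p from χ²₁) only when λ > 1, the usual one-sided convention;
otherwise adjusted p equals raw p.  Loci: every variant with adjusted
p < 1e-5 (suggestive threshold; genome-wide 5e-8 is also exported) is a
lead candidate, processed best-p-first; the locus spans the min/max
positions of panel variants within ±500 kb whose composite-LD r²
(squared Pearson correlation of dosages) with the lead exceeds 0.6, and
leads falling inside an earlier locus are absorbed.  A lead with no
correlated partner forms a single-position locus.  The LD panel defaults
to the study genotypes; an external panel can be supplied.

## Model specification tools

Partial correlations are −Ω_ij/√(Ω_ii Ω_jj) with Ω the inverse
correlation matrix; an optional ridge (1e-6 on the diagonal) guards
singularity and is logged when used.  Covariance selection starts from
the saturated Gaussian graphical model and greedily removes the edge
with the smallest |partial correlation| in the current fit, refitting
the constrained MLE by iterative proportional fitting over maximal
cliques (convergence 1e-8 relative, cap 10 000 sweeps) and accepting the
removal only if AIC = −2ℓ + 2(p + #edges) decreases; the first
non-improving removal stops the search and the AIC trace of accepted
models is returned.

A property of this criterion worth knowing: AIC is not
selection-consistent.  Removing a truly absent edge is accepted iff its
likelihood-ratio statistic (asymptotically χ²₁) is below 2, so each null
edge is retained with probability ≈ 0.157 *regardless of sample size*.
Exact recovery of a sparse truth therefore plateaus — for a 5-node chain
at ≈ 0.84⁶ ≈ 0.36 — even though true edges are essentially never lost.
The package implements the AIC rule as specified and reports the trace;
users wanting consistent selection can screen the returned partial
correlations with their own penalty.  The clique diagnostic
(Bron–Kerbosch on edges with |partial r| > 0.2) is reported, not used as
a gate.

Likert deltas (ordinal −6…+6) are treated as continuous throughout
(Pearson machinery, ML on normal likelihoods); polychoric alternatives
are out of scope.  Partial correlations condition only on the other
items, not on age/sex.

## Genotype QC

Variant filters run in the fixed order call rate → MAF → HWE, each
recording its removal count (order matters for the counts, not the
surviving set).  The HWE test is the Wigginton-style two-sided exact
test (no mid-p), summing probabilities of heterozygote counts no more
probable than observed, conditional on allele counts.  Relatedness uses
the PLINK-convention method-of-moments estimator: observed IBS counts
compared with expectations under IBD 0/1/2 given in-sample allele
frequencies, PI_HAT = P(IBD=2) + P(IBD=1)/2 clamped to [0,1], cut-off
0.1875 (halfway between second- and third-degree relatives).
Stratification PCA standardises dosages by reference allele frequency,
takes eigenvectors from the reference panel and projects study samples;
the number of components is an explicit input (eigenvalues are returned
for scree inspection), and outlier exclusion is a radius rule — beyond
k·SD (default 6) of the target reference cluster's centroid in
component-standardised units.

## Colocalization

Wakefield's approximation per variant: with V = se², W = prior_sd²
(default 0.15 for a standardised quantitative trait), r = W/(V+W) and
z = β/se, lABF = ½(log(1−r) + r z²).  When only (p, MAF, N) are
available, |z| is recovered from the two-sided p and V ≈ 1/(2N·maf(1−maf)).
The five hypothesis sums use priors p1 = p2 = 1e-4, p12 = 1e-5 and are
accumulated in log space (log-sum-exp; the H3 term uses a log-difference),
so regions with lABF up to several hundred stay finite and the
posteriors sum to 1 within 1e-12.  Variants are matched between studies
by id; regions are locus bounds ± 100 kb (clamped at position 1).  Batch
mode evaluates loci × eQTL panels and flags PPH4 > 0.5 (reported) and
> 0.75 (strong).

## The synthetic-data generator

The generator runs the model of this package forward, which is exactly
what makes it a ground-truth surface for recovery tests — and exactly
what it must be understood as: data simulated *from the fitted model
family*, not a portrait of real questionnaires or real genomes.

- Genotypes: per-variant MAF uniform in `maf_range` (default 0.05–0.5);
  two independent haplotypes per subject from a block-wise AR(1)
  Gaussian copula (block size 20, ρ = 0.8 by default) thresholded at
  Φ⁻¹(MAF), so HWE holds by construction and within-block r² decays
  with distance.  Real LD maps, chip manifests and imputation error are
  deliberately not emulated.
- Latent and categories: F = Σβ_v·z_v + effects·(standardised age, sex) +
  ζ with ζ ~ N(0,1).  The *residual-standardised* convention mirrors the
  SEM identification, so generator β and γ are directly comparable to
  estimates; with the small effects studied here total latent variance
  is ≈ 1.  Default loadings (0.842, 0.657, 0.787, 0.823); default
  covariate effects 0.10 (age) and 0.05 (sex) — modest values chosen
  once, as the study design reports covariate adjustment but no effect
  sizes.  Category scores are γ_k F plus N(0, 1−γ_k²) noise.
- Likert items: each item's "after" score is its category score plus
  item noise (SD 0.5) shifted by +0.7; "before" is baseline noise
  (SD 0.8) shifted by −1.95; both are cut at the six thresholds
  (−2.5…+2.5 spaced 1.0) onto the 1–7 scale.  The shifts were chosen so
  the marginal before/after means (≈ 2.1 / 4.7) match the reported
  survey marginals; they are free parameters of the generator.
  Discretisation plus differencing attenuates loadings and β — recovery
  tests against exact generating values therefore use the continuous
  category surface (`simulate_category_scores`), while the end-to-end
  pipeline exercises the full Likert path.
- Covariates: age uniform on 20–79 years, sex Bernoulli(0.505) — the
  study's range and balance, with the exact age distribution left free.
- eQTL studies: an independent cohort (default N = 500) is regenerated
  from the same variant panel (seed offset), expression is the causal
  variant's standardised dosage times `eqtl_beta` (default 0.8) plus
  unit noise, and per-variant marginal OLS gives β/SE/p.  "shared" uses
  the GWAS causal variant, "distinct" one two LD blocks away (so the two
  signals are uncorrelated), "null" none.
- Ground truth (latent scores, causal map, loadings, item-graph) is
  exported as sidecar TSVs; recovery tests read those, never generator
  internals.  All randomness flows from a single integer seed through
  per-stage `SeedSequence` streams, so identical configurations are
  byte-identical.

## Problem sizes and statistical checks

Replicate counts and scan sizes used by the test-suite and acceptance
script are the package's own choices: loading/effect recovery uses 100
replicates at N ≈ 2000 (the survey scale); null calibration uses
2000-variant scans at N = 1000 with independent variants, asserting the
mean λ_GC over three scans in [0.95, 1.05] — the sampling SD of a
median-based λ on 2000 variants is ≈ 0.05, so a single scan is too noisy
to test a ±0.05 band — plus a KS uniformity check on pooled p-values;
covariance-selection recovery uses 50 replicates at N = 5000;
colocalization scenarios use 200-variant regions, GWAS N = 800, eQTL
N = 500.  What passing these tests shows is internal consistency —
estimators recover the generating model and are calibrated under its
null; it does not certify behaviour under model misspecification
(ordinal severity, non-normal noise, real LD, population structure).

## Numerical conventions

Positions are 1-based inclusive (VCF convention) throughout.  VCF output
is uncompressed 4.2 with a GT field; missing calls are `./.` and NaN in
memory.  Persisted tables are written with `%.17g` and read with
round-trip float parsing so re-running a stage from its artefacts is
byte-identical.  Ties in the greedy edge elimination and lead
deduplication are broken by array order, which is deterministic given
sorted inputs.

## Known limitations

Phasing/imputation, X-chromosome handling, variant annotation, mixed
models and multi-causal (SuSiE-style) colocalization are out of scope.
The measurement model is strictly one-factor with covariates acting on
the latent only; item-level (14-indicator) GWAS models are not
implemented.  eQTL panels are matched by variant id only unless
chromosome/position columns are supplied; allele harmonisation beyond
strand-simple flips is the caller's responsibility.
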