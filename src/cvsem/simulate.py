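"""Synthetic genotype / questionnaire / eQTL data with known ground truth.

The generator runs the latent-factor model forward: HWE genotypes with
block-wise LD, a latent symptom severity driven by causal variants and
covariates, four category scores loading on that latent, 14 Likert items per
recall condition obtained by thresholding, and paired eQTL summary
statistics with a shared, distinct or absent causal variant.  Every dataset
carries a ground-truth sidecar so recovery tests never reach into generator
internals.

Scale conventions: causal effects ``beta`` act on standardised dosages and
the latent noise term is standard normal, matching the SEM identification
(latent residual variance fixed to 1) — generator betas and loadings are
therefore directly comparable to the fitted estimates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import (
    CATEGORY_ORDER,
    ITEM_CATEGORIES,
    ITEMS,
    GenotypeDataset,
    QuestionnaireData,
    write_tsv,
    write_vcf,
)

EQTL_SCENARIOS = ("shared", "distinct", "null")


class ConfigurationError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the forward model; defaults mirror the study design.

    ``loadings`` are the four category loadings on the latent factor,
    ``causal_variants`` maps variant indices to effects of the standardised
    dosage on the latent, ``covariate_effects`` are latent effects of
    standardised age and sex.  ``likert_thresholds`` are six ordered cut
    points applied to a standardised continuous item score.
    """

    n_samples: int = 1998
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.8
    causal_variants: list[tuple[int, float]] = field(default_factory=list)
    loadings: tuple[float, float, float, float] = (0.842, 0.657, 0.787, 0.823)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.10, "sex": 0.05}
    )
    likert_thresholds: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    before_shift: float = -1.95
    before_sd: float = 0.8
    after_shift: float = 0.7
    item_noise_sd: float = 0.5
    eqtl_n_samples: int = 500
    eqtl_beta: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(f"maf_range {self.maf_range} not within (0,1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must lie in [0,1)")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if len(self.loadings) != 4:
            raise ConfigurationError("exactly 4 loadings required")
        if not all(0.0 < g < 1.0 for g in self.loadings):
            raise ConfigurationError(
                "loadings must lie in (0,1) on the standardized scale"
            )
        t = np.asarray(self.likert_thresholds, dtype=float)
        if t.size != 6 or np.any(np.diff(t) <= 0):
            raise ConfigurationError("need 6 strictly increasing Likert thresholds")
        for idx, _ in self.causal_variants:
            if not (0 <= idx < self.n_variants):
                raise ConfigurationError(f"causal variant index {idx} out of range")


@dataclass
class GroundTruth:
    """Simulation truth kept beside the generated data for recovery tests."""

    latent_scores: np.ndarray
    causal_map: dict[int, float]
    true_loadings: tuple[float, ...]
    true_graph: pd.DataFrame  # item x item adjacency used for the network

    def __post_init__(self) -> None:
        for idx in self.causal_map:
            if idx < 0:
                raise ConfigurationError("causal_map keys must be variant indices")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


# ---------------------------------------------------------------------------
# genotypes


def _simulate_haplotypes(
    rng: np.random.Generator, config: SimulationConfig, n_samples: int
) -> np.ndarray:
    """Two haplotypes per sample from a block AR(1) Gaussian copula."""
    m = config.n_variants
    mafs = rng.uniform(*config.maf_range, size=m)
    cuts = stats.norm.ppf(mafs)
    rho = config.ld_rho
    z = np.empty((2 * n_samples, m))
    eps = rng.standard_normal((2 * n_samples, m))
    for j in range(m):
        if j % config.ld_block_size == 0:
            z[:, j] = eps[:, j]  # block start: fresh draw
        else:
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho**2) * eps[:, j]
    alleles = (z < cuts).astype(np.int8)  # ALT = minor allele
    dosages = alleles[:n_samples] + alleles[n_samples:]
    return dosages.astype(float)


def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """HWE genotypes in {0,1,2} with within-block LD decaying in distance."""
    if config.n_samples < 2 or config.n_variants < 1:
        raise ConfigurationError("need n_samples >= 2 and n_variants >= 1")
    rng = _rng(config, 1)
    dosages = _simulate_haplotypes(rng, config, config.n_samples)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1 + 1000 * np.arange(config.n_variants),
            "id": [f"var{j:06d}" for j in range(config.n_variants)],
            "ref": "A",
            "alt": "G",
        }
    )
    ds = GenotypeDataset(dosages, variants)
    ds.variants["maf"] = ds.maf()
    return ds


# ---------------------------------------------------------------------------
# phenotypes


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Age (20-79 years) and sex (1 = male, ~50%) for each subject."""
    rng = _rng(config, 2)
    age = rng.integers(20, 80, size=config.n_samples)
    sex = (rng.random(config.n_samples) < 0.505).astype(int)
    return pd.DataFrame(
        {"age": age, "sex": sex},
        index=[f"S{i:05d}" for i in range(config.n_samples)],
    )


def _item_adjacency() -> pd.DataFrame:
    adj = pd.DataFrame(0, index=ITEMS, columns=ITEMS, dtype=int)
    for a, b in itertools.combinations(ITEMS, 2):
        if ITEM_CATEGORIES[a] == ITEM_CATEGORIES[b]:
            adj.loc[a, b] = adj.loc[b, a] = 1
    return adj


def simulate_phenotypes(
    genotypes: GenotypeDataset,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
) -> tuple[QuestionnaireData, GroundTruth]:
    """Run the latent-factor model forward to Likert questionnaire data.

    latent F = sum(beta_v * standardized dosage) + covariate effects + e,
    e ~ N(0,1); category score y_k = gamma_k * F + sqrt(1-gamma_k^2) * eps;
    items are the category score plus item noise, shifted and thresholded
    separately for the "before" (baseline) and "after" (exposed) recall
    conditions, so the per-item delta recovers the category signal.
    """
    rng = _rng(config, 3)
    n = genotypes.n_samples
    if covariates is None:
        covariates = simulate_covariates(config)
    gamma = np.asarray(config.loadings)

    latent = rng.standard_normal(n)  # residual-standardised latent noise
    for idx, beta in config.causal_variants:
        if not (0 <= idx < genotypes.n_variants):
            raise ConfigurationError(f"causal variant index {idx} out of range")
        g = genotypes.dosages[:, idx]
        if np.nanstd(g) > 0:
            latent = latent + beta * _standardize(np.nan_to_num(g))
    for name, effect in config.covariate_effects.items():
        if effect != 0.0 and name in covariates.columns:
            latent = latent + effect * _standardize(
                covariates[name].to_numpy(dtype=float)
            )

    cat_noise = rng.standard_normal((n, 4))
    y = latent[:, None] * gamma + cat_noise * np.sqrt(1.0 - gamma**2)
    cat_index = {c: k for k, c in enumerate(CATEGORY_ORDER)}

    cuts = np.asarray(config.likert_thresholds)
    data = {}
    for item in ITEMS:
        yk = y[:, cat_index[ITEM_CATEGORIES[item]]]
        after_score = (
            config.after_shift + yk + config.item_noise_sd * rng.standard_normal(n)
        )
        before_score = config.before_shift + config.before_sd * rng.standard_normal(n)
        data[f"{item}_before"] = 1 + (before_score[:, None] > cuts).sum(axis=1)
        data[f"{item}_after"] = 1 + (after_score[:, None] > cuts).sum(axis=1)
    responses = pd.DataFrame(data, index=list(genotypes.samples))
    responses = responses[
        [f"{q}_before" for q in ITEMS] + [f"{q}_after" for q in ITEMS]
    ]
    truth = GroundTruth(
        latent_scores=latent,
        causal_map=dict(config.causal_variants),
        true_loadings=tuple(config.loadings),
        true_graph=_item_adjacency(),
    )
    return QuestionnaireData(responses), truth


def simulate_category_scores(
    genotypes: GenotypeDataset,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Continuous category-score table from the same forward model.

    Bypasses Likert discretisation — the surface the SEM recovery checks
    use, since thresholding attenuates loadings by construction.
    """
    questionnaire, truth = simulate_phenotypes(genotypes, config, covariates)
    # regenerate the continuous y from the stored latent (same model, no cuts)
    rng = _rng(config, 4)
    gamma = np.asarray(config.loadings)
    n = genotypes.n_samples
    y = truth.latent_scores[:, None] * gamma + rng.standard_normal(
        (n, 4)
    ) * np.sqrt(1.0 - gamma**2)
    table = pd.DataFrame(y, columns=CATEGORY_ORDER, index=list(genotypes.samples))
    return table, truth


# ---------------------------------------------------------------------------
# eQTL summary statistics


def marginal_ols_scan(
    dosages: np.ndarray, trait: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-variant simple-regression (beta, se) of trait on dosage."""
    n = trait.size
    gc = dosages - dosages.mean(axis=0)
    yc = trait - trait.mean()
    sxx = (gc**2).sum(axis=0)
    sxx = np.where(sxx > 0, sxx, np.nan)
    beta = gc.T @ yc / sxx
    rss = (yc**2).sum() - beta**2 * sxx
    se = np.sqrt(np.clip(rss, 0, None) / (n - 2) / sxx)
    return beta, se


def simulate_eqtl_summary(
    genotypes: GenotypeDataset,
    scenario: str,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Summary statistics of a simulated expression trait in an independent
    cohort genotyped at the same variants.

    scenario: "shared" places the eQTL causal variant at the GWAS causal
    variant, "distinct" two LD blocks away, "null" nowhere.
    """
    if scenario not in EQTL_SCENARIOS:
        raise ConfigurationError(
            f"unknown eQTL scenario {scenario!r}; expected one of {EQTL_SCENARIOS}"
        )
    rng = _rng(config, 5 + EQTL_SCENARIOS.index(scenario))
    n = config.eqtl_n_samples
    dosages = _simulate_haplotypes(rng, config, n)

    expression = rng.standard_normal(n)
    causal_idx: int | None = None
    if scenario != "null":
        if not config.causal_variants:
            raise ConfigurationError(
                "shared/distinct scenarios need config.causal_variants"
            )
        gwas_idx = config.causal_variants[0][0]
        causal_idx = gwas_idx
        if scenario == "distinct":
            causal_idx = (gwas_idx + 2 * config.ld_block_size) % config.n_variants
        g = dosages[:, causal_idx]
        if g.std() > 0:
            expression = expression + config.eqtl_beta * _standardize(g)

    beta, se = marginal_ols_scan(dosages, expression)
    z = beta / se
    table = genotypes.variants[["chrom", "pos", "id"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["z"] = z
    table["p"] = 2.0 * stats.norm.sf(np.abs(z))
    p_alt = dosages.mean(axis=0) / 2.0
    table["maf"] = np.minimum(p_alt, 1 - p_alt)
    table["n"] = n
    table["gene"] = "GENE1"
    table["tissue"] = "synthetic"
    table.attrs["causal_index"] = causal_idx
    return table


# ---------------------------------------------------------------------------
# export


def export_dataset(
    out_dir,
    genotypes: GenotypeDataset,
    questionnaire: QuestionnaireData | None = None,
    covariates: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
) -> dict[str, str]:
    """Write VCF + TSV artefacts; returns the mapping of outputs to paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    vcf_path = os.path.join(out_dir, "genotypes.vcf")
    write_vcf(genotypes, vcf_path)
    paths["genotypes"] = vcf_path
    if questionnaire is not None:
        p = os.path.join(out_dir, "questionnaire.tsv")
        write_tsv(questionnaire.responses, p)
        paths["questionnaire"] = p
    if covariates is not None:
        p = os.path.join(out_dir, "covariates.tsv")
        write_tsv(covariates, p)
        paths["covariates"] = p
    if truth is not None:
        p = os.path.join(out_dir, "truth_latent.tsv")
        write_tsv(
            pd.DataFrame(
                {"latent": truth.latent_scores}, index=list(genotypes.samples)
            ),
            p,
        )
        paths["truth_latent"] = p
        p2 = os.path.join(out_dir, "truth_causal.tsv")
        write_tsv(
            pd.DataFrame(
                {
                    "variant_index": list(truth.causal_map),
                    "variant_id": [
                        genotypes.variants["id"].iloc[i] for i in truth.causal_map
                    ],
                    "beta": list(truth.causal_map.values()),
                }
            ),
            p2,
            index=False,
        )
        paths["truth_causal"] = p2
    return paths
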