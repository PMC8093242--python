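"""Configuration, logging and the end-to-end pipeline driver.

Chains simulate -> qc -> prep (questionnaire preprocessing and model
specification) -> fit (measurement model) -> gwas -> coloc and emits a
machine-readable run manifest.  Every stage reads its inputs from and
persists its outputs to the configured output directory, so any stage can
be re-run from the persisted artefacts of the previous one.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (
    GenotypeDataset,
    QuestionnaireData,
    read_covariates,
    read_questionnaire,
    read_tsv,
    read_vcf,
    write_tsv,
    write_vcf,
)
from .coloc import DEFAULT_PRIOR_SD, DEFAULT_PRIORS, coloc_batch
from .gwas import (
    GENOMEWIDE_P,
    SUGGESTIVE_P,
    define_loci,
    export_plots_data,
    genomic_control,
    loci_table,
    run_scan,
)
from .phenotype import (
    category_scores,
    covariance_selection,
    delta_scores,
    find_cliques_above,
    item_pca,
    partial_correlation_matrix,
)
from .qc import QcThresholds, variant_qc
from .sem import OneFactorModel
from .simulate import (
    SimulationConfig,
    export_dataset,
    simulate_covariates,
    simulate_eqtl_summary,
    simulate_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger("cvsem")


class ConfigError(ValueError):
    pass


@dataclass
class ScanThresholds:
    suggestive_p: float = SUGGESTIVE_P
    genomewide_p: float = GENOMEWIDE_P
    r2: float = 0.6
    window_kb: float = 500.0
    flank_kb: float = 100.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigError(f"scan threshold {f.name} must be positive")


@dataclass
class ColocPriors:
    p1: float = DEFAULT_PRIORS[0]
    p2: float = DEFAULT_PRIORS[1]
    p12: float = DEFAULT_PRIORS[2]
    prior_sd: float = DEFAULT_PRIOR_SD

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigError(f"coloc prior {f.name} must be positive")


@dataclass
class PipelineConfig:
    """Validated pipeline settings with the study's thresholds as defaults."""

    out_dir: str = "cvsem_run"
    seed: int = 0
    genotypes: str | None = None
    questionnaire: str | None = None
    covariates: str | None = None
    eqtl: dict[str, str] = field(default_factory=dict)
    n_components: int = 2
    qc: QcThresholds = field(default_factory=QcThresholds)
    scan: ScanThresholds = field(default_factory=ScanThresholds)
    coloc: ColocPriors = field(default_factory=ColocPriors)
    simulate: SimulationConfig | None = None

    def require(self, attr: str) -> str:
        path = getattr(self, attr)
        if path is None or not os.path.exists(path):
            raise ConfigError(f"input '{attr}' missing or not found: {path}")
        return path


_SECTIONS = {"qc": QcThresholds, "scan": ScanThresholds,
             "coloc": ColocPriors, "simulate": SimulationConfig}


def _build_section(cls, payload: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    if cls is SimulationConfig:
        if "maf_range" in payload:
            payload["maf_range"] = tuple(payload["maf_range"])
        if "causal_variants" in payload:
            payload["causal_variants"] = [
                (int(i), float(b)) for i, b in payload["causal_variants"]
            ]
        if "loadings" in payload:
            payload["loadings"] = tuple(payload["loadings"])
        if "likert_thresholds" in payload:
            payload["likert_thresholds"] = tuple(payload["likert_thresholds"])
    try:
        return cls(**payload)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    top_allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            payload = raw.pop(name)
            if payload is None:
                continue
            if not isinstance(payload, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, payload, name)
    kwargs.update(raw)
    try:
        return PipelineConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    return config_from_dict(raw)


def dump_config(config: PipelineConfig, path: str) -> None:
    payload = asdict(config)
    if payload.get("simulate") and payload["simulate"].get("causal_variants"):
        payload["simulate"]["causal_variants"] = [
            [int(i), float(b)] for i, b in payload["simulate"]["causal_variants"]
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# pipeline stages


class Pipeline:
    """Stage-wise driver; each stage logs its parameters and artefacts."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        os.makedirs(config.out_dir, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "stages": [],
        }

    def _path(self, *parts: str) -> str:
        return os.path.join(self.config.out_dir, *parts)

    def _record(self, stage: str, **info) -> None:
        logger.info("stage %s: %s", stage, info)
        self.manifest["stages"].append({"stage": stage, **info})

    # -- simulate --------------------------------------------------------

    def stage_simulate(self) -> dict[str, str]:
        cfg = self.config.simulate
        if cfg is None:
            cfg = SimulationConfig(seed=self.config.seed)
        genotypes = simulate_genotypes(cfg)
        covariates = simulate_covariates(cfg)
        questionnaire, truth = simulate_phenotypes(genotypes, cfg, covariates)
        data_dir = self._path("data")
        paths = export_dataset(
            data_dir, genotypes, questionnaire, covariates, truth
        )
        for scenario in ("shared", "distinct", "null"):
            if cfg.causal_variants or scenario == "null":
                table = simulate_eqtl_summary(genotypes, scenario, cfg)
                p = os.path.join(data_dir, f"eqtl_{scenario}.tsv")
                table.to_csv(p, sep="\t", index=False)
                paths[f"eqtl_{scenario}"] = p
        self.config.genotypes = paths["genotypes"]
        self.config.questionnaire = paths["questionnaire"]
        self.config.covariates = paths["covariates"]
        if not self.config.eqtl:
            self.config.eqtl = {
                s: paths[f"eqtl_{s}"]
                for s in ("shared", "distinct", "null")
                if f"eqtl_{s}" in paths
            }
        self._record(
            "simulate",
            n_samples=genotypes.n_samples,
            n_variants=genotypes.n_variants,
            n_causal=len(cfg.causal_variants),
            **{k: str(v) for k, v in paths.items()},
        )
        return paths

    # -- qc --------------------------------------------------------------

    def stage_qc(self) -> GenotypeDataset:
        genotypes = read_vcf(self.config.require("genotypes"))
        filtered, report = variant_qc(genotypes, self.config.qc)
        out_vcf = self._path("genotypes.qc.vcf")
        write_vcf(filtered, out_vcf)
        write_tsv(report.to_frame(), self._path("qc_report.tsv"), index=False)
        self._record(
            "qc",
            variants_in=report.variants_in,
            variants_out=report.variants_out,
            removed=report.removed,
            output=out_vcf,
        )
        return filtered

    # -- prep ------------------------------------------------------------

    def stage_prep(self) -> pd.DataFrame:
        questionnaire = read_questionnaire(self.config.require("questionnaire"))
        deltas = delta_scores(questionnaire)
        categories = category_scores(deltas)
        write_tsv(deltas, self._path("deltas.tsv"))
        write_tsv(categories, self._path("categories.tsv"))

        network = partial_correlation_matrix(deltas)
        write_tsv(network.partial_corr, self._path("partial_corr.tsv"))
        sample_cov = np.cov(deltas.to_numpy(dtype=float), rowvar=False)
        selected = covariance_selection(
            pd.DataFrame(sample_cov, index=deltas.columns, columns=deltas.columns),
            n=len(deltas),
        )
        write_tsv(selected.edge_list(), self._path("network_edges.tsv"), index=False)
        cliques = find_cliques_above(selected, threshold=0.2)
        vals, coords, shares = item_pca(network.partial_corr)
        write_tsv(coords.assign(), self._path("item_pca.tsv"))
        self._record(
            "prep",
            n_subjects=len(categories),
            n_edges=int(selected.adjacency.to_numpy().sum() // 2),
            aic_steps=len(selected.aic_trace) - 1,
            cliques_above_0_2=len(cliques),
            pc1_share=float(shares[0]),
        )
        return categories

    # -- fit -------------------------------------------------------------

    def stage_fit(self, categories: pd.DataFrame | None = None) -> dict:
        if categories is None:
            categories = read_tsv(self._path("categories.tsv"))
        results = OneFactorModel(categories).fit()
        rmsea, lo, hi = results.rmsea()
        payload = {
            "loadings": results.loadings.tolist(),
            "loadings_se": results.loadings_se.tolist(),
            "residual_variances": results.residual_variances.tolist(),
            "chi_square": results.chi_square,
            "df": results.df,
            "p_value": results.pvalue,
            "rmsea": rmsea,
            "rmsea_ci": [lo, hi],
            "loglik": results.loglik,
            "n_obs": results.n_obs,
            "heywood": results.heywood,
        }
        with open(self._path("measurement_model.json"), "w") as fh:
            json.dump(payload, fh, indent=2)
        self._record("fit", chi_square=results.chi_square, rmsea=rmsea,
                     n_obs=results.n_obs)
        return payload

    # -- gwas ------------------------------------------------------------

    def stage_gwas(
        self,
        genotypes: GenotypeDataset | None = None,
        categories: pd.DataFrame | None = None,
    ) -> tuple[pd.DataFrame, list]:
        if genotypes is None:
            qc_path = self._path("genotypes.qc.vcf")
            genotypes = read_vcf(
                qc_path if os.path.exists(qc_path)
                else self.config.require("genotypes")
            )
        if categories is None:
            categories = read_tsv(self._path("categories.tsv"))
        covariates = None
        if self.config.covariates and os.path.exists(self.config.covariates):
            covariates = read_covariates(self.config.covariates)
            covariates = covariates.loc[categories.index]
        table = run_scan(genotypes, categories, covariates)
        table = genomic_control(table)
        table.to_csv(self._path("gwas_summary.tsv"), sep="\t", index=False)
        loci = define_loci(
            table,
            genotypes,
            p_threshold=self.config.scan.suggestive_p,
            r2_threshold=self.config.scan.r2,
            window_kb=self.config.scan.window_kb,
        )
        export_plots_data(table, loci, self._path("gwas"), p_column="p_gc")
        self._record(
            "gwas",
            n_variants=len(table),
            lambda_gc=table.attrs["lambda_gc"],
            n_monomorphic=table.attrs.get("n_monomorphic", 0),
            n_failed=table.attrs.get("n_failed", 0),
            n_loci=len(loci),
        )
        self.manifest["lambda_gc"] = table.attrs["lambda_gc"]
        self.manifest["n_loci"] = len(loci)
        return table, loci

    # -- coloc -----------------------------------------------------------

    def stage_coloc(
        self,
        table: pd.DataFrame | None = None,
        loci: list | None = None,
    ) -> pd.DataFrame:
        if table is None:
            table = read_tsv(self._path("gwas_summary.tsv"), index_col=None)
        if loci is None:
            raw = pd.read_csv(self._path("gwas.loci.tsv"), sep="\t")
            from .gwas import Locus

            loci = [
                Locus(
                    lead_id=str(r.lead_id), chrom=str(r.chrom),
                    start=int(r.start), end=int(r.end), lead_p=float(r.lead_p),
                    member_ids=[str(r.lead_id)], member_r2={str(r.lead_id): 1.0},
                )
                for r in raw.itertuples()
            ]
        eqtl_tables = {
            label: read_tsv(path, index_col=None)
            for label, path in self.config.eqtl.items()
            if os.path.exists(path)
        }
        pri = self.config.coloc
        results = coloc_batch(
            table, eqtl_tables, loci,
            flank_kb=self.config.scan.flank_kb,
            p1=pri.p1, p2=pri.p2, p12=pri.p12, prior_sd=pri.prior_sd,
        )
        results.to_csv(self._path("coloc_results.tsv"), sep="\t", index=False)
        hits = results[results["reported"]]
        self._record(
            "coloc",
            n_tests=len(results),
            n_reported=int(results["reported"].sum()),
            n_strong=int(results["strong"].sum()),
            max_pph4=float(results["pph4"].max()) if len(results) else None,
        )
        self.manifest["coloc_hits"] = [
            {"locus": r.locus, "panel": r.panel, "pph4": float(r.pph4)}
            for r in hits.itertuples()
        ]
        return results

    # -- driver ----------------------------------------------------------

    def run(self) -> dict:
        stage = "simulate"
        try:
            if self.config.simulate is not None or self.config.genotypes is None:
                self.stage_simulate()
            stage = "qc"
            genotypes = self.stage_qc()
            stage = "prep"
            categories = self.stage_prep()
            stage = "fit"
            self.stage_fit(categories)
            stage = "gwas"
            table, loci = self.stage_gwas(genotypes, categories)
            stage = "coloc"
            if self.config.eqtl:
                self.stage_coloc(table, loci)
        except Exception as exc:
            self.manifest["failed_stage"] = stage
            self._write_manifest()
            raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
        self._write_manifest()
        return self.manifest

    def _write_manifest(self) -> None:
        with open(self._path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest."""
    return Pipeline(config).run()
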