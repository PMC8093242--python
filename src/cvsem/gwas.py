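"""Genome-wide association driver for the latent-factor model.

Runs the per-variant SEM (dosage and covariates predicting the latent
symptom factor) across a genotype matrix, applies median-based genomic
control, performs single-trait OLS comparison scans, defines loci by LD
with lead variants below the suggestive threshold, and exports
Manhattan/Q-Q data with basic renderings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GenotypeDataset
from .sem import (
    EstimationError,
    LatentRegressionModel,
    MonomorphicVariantError,
)

#: median of the chi-square(1) distribution
CHI2_1_MEDIAN = 0.45493642311957174

SUGGESTIVE_P = 1.0e-5
GENOMEWIDE_P = 5.0e-8

TABLE_COLUMNS = [
    "chrom", "pos", "id", "ref", "alt", "maf", "n",
    "beta", "se", "z", "p_raw",
]


class ScanError(RuntimeError):
    pass


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    def key(c: str):
        c = str(c)
        return (0, int(c)) if c.isdigit() else (1, c)

    return chrom.map(key)


def _sort_table(table: pd.DataFrame) -> pd.DataFrame:
    return (
        table.assign(_ck=_chrom_sort_key(table["chrom"]))
        .sort_values(["_ck", "pos"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# multi-trait scan


def run_scan(
    genotypes: GenotypeDataset,
    categories: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Latent-mediated association test for every polymorphic variant.

    Each variant is fitted with ``LatentRegressionModel`` warm-started from
    the no-SNP fit; monomorphic or non-converged variants are excluded and
    counted in ``table.attrs``.  Deterministic given identical inputs.
    """
    if genotypes.n_samples != len(categories):
        raise ValueError("genotypes and categories cover different subjects")
    # warm start from the variant-free model
    if covariates is not None:
        base = LatentRegressionModel(categories, covariates).fit(compute_se=False)
        theta_base = base.params_vector()
        p = len(base.loadings)
        k_cov = covariates.shape[1]
        start = np.concatenate(
            [theta_base[: 2 * p], [0.0], theta_base[2 * p:]]
        )
    else:
        from .sem import OneFactorModel

        base = OneFactorModel(categories).fit()
        start = np.concatenate([base.params_vector(), [0.0]])

    cat_np = categories
    rows = []
    n_mono = 0
    n_failed = 0
    iterator = range(genotypes.n_variants)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="scan")
    for j in iterator:
        g = genotypes.dosages[:, j]
        meta = genotypes.variants.iloc[j]
        if np.nanstd(g) == 0:
            n_mono += 1
            continue
        exog = pd.DataFrame({"dosage": g}, index=categories.index)
        if covariates is not None:
            exog = pd.concat([exog, covariates], axis=1)
        try:
            res = LatentRegressionModel(cat_np, exog).fit(start_params=start)
        except (EstimationError, MonomorphicVariantError):
            n_failed += 1
            continue
        beta, se, z, pval = res.effect("dosage")
        if not res.converged:
            n_failed += 1
            beta = se = z = pval = np.nan
        p_alt = np.nanmean(g) / 2.0
        rows.append(
            {
                "chrom": meta["chrom"],
                "pos": int(meta["pos"]),
                "id": meta["id"],
                "ref": meta["ref"],
                "alt": meta["alt"],
                "maf": min(p_alt, 1 - p_alt),
                "n": int(res.n_obs),
                "beta": beta,
                "se": se,
                "z": z,
                "p_raw": pval,
            }
        )
    if not rows:
        raise ScanError("no variants passed the scan")
    table = _sort_table(pd.DataFrame(rows, columns=TABLE_COLUMNS))
    table.attrs["n_monomorphic"] = n_mono
    table.attrs["n_failed"] = n_failed
    return table


def genomic_control(table: pd.DataFrame) -> pd.DataFrame:
    """Median-based genomic control.

    lambda_GC = median(z^2) / 0.4549364; when lambda > 1 every statistic is
    deflated (z^2 / lambda, p from chi-square df=1), otherwise p_gc = p_raw.
    """
    z2 = table["z"].to_numpy() ** 2
    valid = np.isfinite(z2)
    if valid.sum() < 100:
        raise ScanError(
            f"genomic control needs >= 100 valid statistics, got {int(valid.sum())}"
        )
    lam = float(np.median(z2[valid]) / CHI2_1_MEDIAN)
    out = table.copy()
    if lam > 1.0:
        out["p_gc"] = stats.chi2.sf(z2 / lam, df=1)
    else:
        out["p_gc"] = out["p_raw"]
    out.attrs = dict(table.attrs)
    out.attrs["lambda_gc"] = lam
    return out


# ---------------------------------------------------------------------------
# LD and loci


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages (composite LD), pairwise
    complete."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 2:
        raise ValueError("need >= 2 complete dosage pairs")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD undefined for a monomorphic variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class Locus:
    lead_id: str
    chrom: str
    start: int
    end: int
    lead_p: float
    member_ids: list[str] = field(default_factory=list)
    member_r2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.start <= self.end
        assert self.lead_id in self.member_ids


def define_loci(
    table: pd.DataFrame,
    panel: GenotypeDataset,
    p_threshold: float = SUGGESTIVE_P,
    r2_threshold: float = 0.6,
    window_kb: float = 500.0,
    p_column: str = "p_gc",
) -> list[Locus]:
    """LD-defined loci around lead variants below the significance threshold.

    Leads are processed best-p-first; a candidate already belonging to an
    earlier locus is absorbed.  Locus bounds are the min/max positions of
    panel variants within +/- window_kb whose r^2 with the lead exceeds
    r2_threshold (the lead itself always included); a lead missing from the
    panel degenerates to a single-position locus with a warning.
    """
    if p_column not in table.columns:
        raise ValueError(f"table lacks column {p_column!r}")
    hits = table[table[p_column] < p_threshold].sort_values(p_column)
    panel_key = {
        (str(r.chrom), int(r.pos), r.ref, r.alt): i
        for i, r in panel.variants.iterrows()
    }
    loci: list[Locus] = []
    absorbed: set[tuple[str, int]] = set()
    for _, hit in hits.iterrows():
        coord = (str(hit["chrom"]), int(hit["pos"]))
        if coord in absorbed:
            continue
        key = (str(hit["chrom"]), int(hit["pos"]), hit["ref"], hit["alt"])
        idx = panel_key.get(key)
        if idx is None:
            warnings.warn(
                f"lead {hit['id']} absent from LD panel; single-position locus"
            )
            loci.append(
                Locus(
                    lead_id=str(hit["id"]),
                    chrom=str(hit["chrom"]),
                    start=int(hit["pos"]),
                    end=int(hit["pos"]),
                    lead_p=float(hit[p_column]),
                    member_ids=[str(hit["id"])],
                    member_r2={str(hit["id"]): 1.0},
                )
            )
            absorbed.add(coord)
            continue
        lead_g = panel.dosages[:, idx]
        v = panel.variants
        near = (
            (v["chrom"].astype(str) == str(hit["chrom"]))
            & ((v["pos"] - int(hit["pos"])).abs() <= window_kb * 1000)
        )
        member_ids, member_r2, positions = [], {}, []
        for i in np.flatnonzero(near.to_numpy()):
            g = panel.dosages[:, i]
            try:
                r2 = ld_r2(lead_g, g) if i != idx else 1.0
            except ValueError:
                continue
            if r2 > r2_threshold:
                vid = str(v["id"].iloc[i])
                member_ids.append(vid)
                member_r2[vid] = r2
                positions.append(int(v["pos"].iloc[i]))
                absorbed.add((str(v["chrom"].iloc[i]), int(v["pos"].iloc[i])))
        loci.append(
            Locus(
                lead_id=str(hit["id"]),
                chrom=str(hit["chrom"]),
                start=min(positions),
                end=max(positions),
                lead_p=float(hit[p_column]),
                member_ids=member_ids,
                member_r2=member_r2,
            )
        )
    return loci


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lead_id": lc.lead_id,
                "chrom": lc.chrom,
                "start": lc.start,
                "end": lc.end,
                "n_members": len(lc.member_ids),
                "lead_p": lc.lead_p,
            }
            for lc in loci
        ],
        columns=["lead_id", "chrom", "start", "end", "n_members", "lead_p"],
    )


# ---------------------------------------------------------------------------
# single-trait comparison scan


def single_trait_scan(
    genotypes: GenotypeDataset,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS regression of one category score on dosage + covariates,
    Frisch-Waugh residualised for speed; same table format as run_scan."""
    y = trait.to_numpy(dtype=float)
    n = y.size
    if genotypes.n_samples != n:
        raise ValueError("genotypes and trait cover different subjects")
    C = np.ones((n, 1))
    if covariates is not None:
        C = np.column_stack([C, covariates.to_numpy(dtype=float)])
    # residualise y and every dosage on the covariates
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    rows = []
    n_mono = 0
    dfree = n - C.shape[1] - 1
    for j in range(genotypes.n_variants):
        g = np.nan_to_num(genotypes.dosages[:, j])
        meta = genotypes.variants.iloc[j]
        if g.std() == 0:
            n_mono += 1
            continue
        g_r = g - Q @ (Q.T @ g)
        sxx = float(g_r @ g_r)
        if sxx <= 0:
            n_mono += 1
            continue
        beta = float(g_r @ y_r) / sxx
        rss = float(y_r @ y_r) - beta**2 * sxx
        se = np.sqrt(max(rss, 0.0) / dfree / sxx)
        t = beta / se if se > 0 else np.inf
        pval = 2.0 * stats.t.sf(abs(t), dfree) if np.isfinite(t) else 0.0
        p_alt = np.nanmean(genotypes.dosages[:, j]) / 2.0
        rows.append(
            {
                "chrom": meta["chrom"], "pos": int(meta["pos"]),
                "id": meta["id"], "ref": meta["ref"], "alt": meta["alt"],
                "maf": min(p_alt, 1 - p_alt), "n": n,
                "beta": beta, "se": se, "z": t, "p_raw": pval,
            }
        )
    if not rows:
        raise ScanError("no variants passed the scan")
    table = _sort_table(pd.DataFrame(rows, columns=TABLE_COLUMNS))
    table.attrs["n_monomorphic"] = n_mono
    return table


# ---------------------------------------------------------------------------
# exports


def export_plots_data(
    table: pd.DataFrame,
    loci: list[Locus] | None,
    out_prefix: str,
    p_column: str = "p_raw",
    render: bool = True,
) -> dict[str, str]:
    """Write Manhattan and Q-Q data tables (plus PNG renderings) and a
    metadata JSON echoing the significance thresholds."""
    if table.empty:
        raise ValueError("association table is empty")
    table = _sort_table(table)
    p = table[p_column].to_numpy()

    # cumulative positions across chromosomes
    cum = np.zeros(len(table), dtype=float)
    offset = 0
    for chrom in table["chrom"].unique():
        m = (table["chrom"] == chrom).to_numpy()
        cum[m] = table.loc[m, "pos"].to_numpy() + offset
        offset = cum[m].max() + 1
    man = table[["chrom", "pos", "id"]].copy()
    man["cum_pos"] = cum
    man["p"] = p
    with np.errstate(divide="ignore"):
        man["neglog10_p"] = -np.log10(p)
    man_path = f"{out_prefix}.manhattan.tsv"
    man.to_csv(man_path, sep="\t", index=False)

    valid = np.isfinite(p)
    obs = np.sort(p[valid])
    exp = (np.arange(1, obs.size + 1) - 0.5) / obs.size
    qq = pd.DataFrame(
        {
            "expected_neglog10": -np.log10(exp),
            "observed_neglog10": -np.log10(obs),
        }
    )
    qq_path = f"{out_prefix}.qq.tsv"
    qq.to_csv(qq_path, sep="\t", index=False)

    meta = {
        "genomewide_threshold": GENOMEWIDE_P,
        "suggestive_threshold": SUGGESTIVE_P,
        "p_column": p_column,
        "n_variants": int(valid.sum()),
        "lambda_gc": table.attrs.get("lambda_gc"),
    }
    meta_path = f"{out_prefix}.plot_meta.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    paths = {"manhattan": man_path, "qq": qq_path, "meta": meta_path}

    if loci is not None:
        loci_path = f"{out_prefix}.loci.tsv"
        loci_table(loci).to_csv(loci_path, sep="\t", index=False)
        paths["loci"] = loci_path

    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 3))
        for i, chrom in enumerate(man["chrom"].unique()):
            m = man["chrom"] == chrom
            ax.scatter(
                man.loc[m, "cum_pos"], man.loc[m, "neglog10_p"],
                s=4, color=["#4477aa", "#aa7744"][i % 2],
            )
        ax.axhline(-np.log10(GENOMEWIDE_P), color="red", lw=0.8)
        ax.axhline(-np.log10(SUGGESTIVE_P), color="blue", lw=0.8)
        ax.set_xlabel("cumulative position")
        ax.set_ylabel("-log10 p")
        fig.tight_layout()
        fig.savefig(f"{out_prefix}.manhattan.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(3.5, 3.5))
        ax.scatter(qq["expected_neglog10"], qq["observed_neglog10"], s=4)
        lim = max(qq["expected_neglog10"].max(), qq["observed_neglog10"].max())
        ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        fig.tight_layout()
        fig.savefig(f"{out_prefix}.qq.png", dpi=120)
        plt.close(fig)
        paths["manhattan_png"] = f"{out_prefix}.manhattan.png"
        paths["qq_png"] = f"{out_prefix}.qq.png"
    return paths
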