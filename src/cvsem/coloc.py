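"""Bayesian colocalization of GWAS and eQTL signals in a genomic region.

Per-variant Wakefield approximate Bayes factors are combined under the
five-hypothesis framework (H0 no association, H1 GWAS only, H2 eQTL only,
H3 two distinct causal variants, H4 one shared causal variant) into the
posterior probabilities PPH0..PPH4.  All sums run in log space, so regions
with log-ABFs of several hundred remain finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .gwas import Locus

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12
DEFAULT_PRIOR_SD = 0.15  # sqrt(W) for a standardised quantitative trait


class RegionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# approximate Bayes factors


def wakefield_labf(
    beta: np.ndarray | float,
    se: np.ndarray | float,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> np.ndarray | float:
    """Log approximate Bayes factor for association at one variant.

    With V = se^2, W = prior_sd^2, r = W/(V+W) and z = beta/se:
    lABF = 0.5 * (log(1-r) + r z^2).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    labf = 0.5 * (np.log1p(-r) + r * z**2)
    return labf if labf.ndim else float(labf)


def labf_from_pvalues(
    p: np.ndarray | float,
    maf: np.ndarray | float,
    n: np.ndarray | int,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> np.ndarray | float:
    """lABF from (p, MAF, N) when beta/se are unavailable.

    |z| is recovered from the two-sided p-value and the sampling variance
    approximated as V = 1 / (2 N maf (1-maf)) for a standardised
    quantitative trait.
    """
    p = np.asarray(p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        tiny = np.finfo(float).tiny
        if np.any(p <= 0):
            warnings.warn("p-value of 0 clamped to the smallest positive float")
        p = np.clip(p, tiny, 1.0)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("MAF must lie in (0, 0.5]")
    if np.any(n < 2):
        raise ValueError("sample size must be >= 2")
    z = stats.norm.isf(p / 2.0)  # sign unknown; only z^2 enters
    V = 1.0 / (2.0 * n * maf * (1.0 - maf))
    se = np.sqrt(V)
    return wakefield_labf(z * se, se, prior_sd)


def region_labf(
    region: pd.DataFrame, prior_sd: float = DEFAULT_PRIOR_SD
) -> np.ndarray:
    """Per-variant lABF from a summary table, preferring (beta, se) and
    falling back to (p, maf, n)."""
    if {"beta", "se"}.issubset(region.columns) and region["se"].notna().all():
        return np.asarray(wakefield_labf(region["beta"], region["se"], prior_sd))
    needed = {"p", "maf", "n"}
    if not needed.issubset(region.columns):
        raise RegionError(
            "region needs either (beta, se) or (p, maf, n) columns"
        )
    return np.asarray(
        labf_from_pvalues(region["p"], region["maf"], region["n"], prior_sd)
    )


# ---------------------------------------------------------------------------
# posteriors


@dataclass
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    priors: tuple[float, float, float]

    def __post_init__(self) -> None:
        total = self.pph0 + self.pph1 + self.pph2 + self.pph3 + self.pph4
        assert abs(total - 1.0) < 1e-12

    def as_dict(self) -> dict[str, float]:
        return {
            "pph0": self.pph0, "pph1": self.pph1, "pph2": self.pph2,
            "pph3": self.pph3, "pph4": self.pph4, "n_snps": self.n_snps,
        }


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> ColocResult:
    """PPH0..PPH4 over the variants shared between two summary tables.

    Tables are matched on the ``id`` column; unmatched variants are dropped
    (counts recorded via a warning when any are lost).  Hypothesis sums:
    S0 = 1, S1 = p1 * sum(ABF_g), S2 = p2 * sum(ABF_e),
    S3 = p1 p2 * (sum_g * sum_e - sum(ABF_g ABF_e)), S4 = p12 * sum(ABF_g ABF_e),
    accumulated with log-sum-exp.
    """
    for name, df in (("gwas", gwas), ("eqtl", eqtl)):
        if "id" not in df.columns:
            raise RegionError(f"{name} table lacks an 'id' column")
        if df["id"].duplicated().any():
            raise RegionError(f"{name} table has duplicate variant ids")
    shared = pd.Index(gwas["id"]).intersection(pd.Index(eqtl["id"]))
    if len(shared) == 0:
        raise RegionError(
            "no shared variants between GWAS and eQTL tables; "
            f"gwas has {len(gwas)}, eqtl has {len(eqtl)} ids"
        )
    lost = max(len(gwas), len(eqtl)) - len(shared)
    if lost:
        warnings.warn(f"{lost} unmatched variants dropped from colocalization")
    g = gwas.set_index("id").loc[shared]
    e = eqtl.set_index("id").loc[shared]
    labf_g = region_labf(g.reset_index(), prior_sd)
    labf_e = region_labf(e.reset_index(), prior_sd)

    lse_g = logsumexp(labf_g)
    lse_e = logsumexp(labf_e)
    lse_ge = logsumexp(labf_g + labf_e)

    log_s = np.array(
        [
            0.0,
            np.log(p1) + lse_g,
            np.log(p2) + lse_e,
            np.log(p1) + np.log(p2) + _logdiff(lse_g + lse_e, lse_ge),
            np.log(p12) + lse_ge,
        ]
    )
    post = np.exp(log_s - logsumexp(log_s))
    post = post / post.sum()
    return ColocResult(*post.tolist(), n_snps=len(shared), priors=(p1, p2, p12))


# ---------------------------------------------------------------------------
# region extraction and batch evaluation


def extract_region(
    summary: pd.DataFrame, locus: Locus, flank_kb: float = 100.0
) -> pd.DataFrame:
    """Variants within locus bounds +/- flank_kb (1-based inclusive,
    clamped at position 1)."""
    lo = max(locus.start - int(flank_kb * 1000), 1)
    hi = locus.end + int(flank_kb * 1000)
    sel = summary[
        (summary["chrom"].astype(str) == str(locus.chrom))
        & (summary["pos"] >= lo)
        & (summary["pos"] <= hi)
    ]
    if sel.empty:
        raise RegionError(
            f"no variants in region {locus.chrom}:{lo}-{hi} for locus "
            f"{locus.lead_id}"
        )
    return sel.reset_index(drop=True)


def coloc_batch(
    gwas_summary: pd.DataFrame,
    eqtl_tables: dict[str, pd.DataFrame],
    loci: list[Locus],
    flank_kb: float = 100.0,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    prior_sd: float = DEFAULT_PRIOR_SD,
    report_threshold: float = 0.5,
    strong_threshold: float = 0.75,
) -> pd.DataFrame:
    """Evaluate every locus against every eQTL panel.

    ``eqtl_tables`` maps "gene/tissue" labels to summary tables.  Rows with
    PPH4 above ``report_threshold`` are flagged ``reported``; above
    ``strong_threshold`` additionally ``strong``.
    """
    p_gwas = "p_gc" if "p_gc" in gwas_summary.columns else "p_raw"
    rows = []
    for locus in loci:
        try:
            g_region = extract_region(gwas_summary, locus, flank_kb)
        except RegionError:
            continue
        g_region = g_region.rename(columns={p_gwas: "p"})
        for label, eqtl in eqtl_tables.items():
            try:
                e_region = extract_region(eqtl, locus, flank_kb)
                res = coloc_posteriors(
                    g_region, e_region, p1=p1, p2=p2, p12=p12, prior_sd=prior_sd
                )
            except RegionError:
                continue
            rows.append(
                {
                    "locus": locus.lead_id,
                    "chrom": locus.chrom,
                    "start": locus.start,
                    "end": locus.end,
                    "panel": label,
                    **res.as_dict(),
                    "reported": res.pph4 > report_threshold,
                    "strong": res.pph4 > strong_threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus", "chrom", "start", "end", "panel",
            "pph0", "pph1", "pph2", "pph3", "pph4", "n_snps",
            "reported", "strong",
        ],
    )
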