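"""Variant- and sample-level genotype quality control.

Implements the standard GWAS QC battery: per-variant call rate, minor
allele frequency and Hardy-Weinberg exact-test filters (applied in that
fixed order), PLINK-style method-of-moments identity-by-descent (PI_HAT)
for relatedness, and reference-anchored PCA for population stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset


class InsufficientDataError(ValueError):
    pass


@dataclass
class QcThresholds:
    """QC cut-offs; defaults are the conventional stringent GWAS settings."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    max_ibd: float = 0.1875
    min_hwe_p: float = 1.0e-6

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "max_ibd", "min_hwe_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QcReport:
    variants_in: int
    variants_out: int
    samples_in: int
    samples_out: int
    removed: dict[str, int] = field(default_factory=dict)
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        assert self.variants_out <= self.variants_in
        assert self.samples_out <= self.samples_in

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("variants_in", self.variants_in),
            ("variants_out", self.variants_out),
            ("samples_in", self.samples_in),
            ("samples_out", self.samples_out),
        ] + [(f"removed_{k}", v) for k, v in self.removed.items()]
        return pd.DataFrame(rows, columns=["metric", "value"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE test (Wigginton-style, no mid-p).

    Sums, conditional on the observed allele counts, the probabilities of
    all heterozygote counts no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("all genotype counts are zero")
    rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele copies
    obs_het = n_Aa

    # probability over het counts with the parity of `rare`
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downwards from the mode
    het, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het >= 2:
        probs[het - 2] = probs[het] * het * (het - 1) / (
            4.0 * (hom_r + 1) * (hom_c + 1)
        )
        het -= 2
        hom_r += 1
        hom_c += 1
    # upwards from the mode
    het, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het <= rare - 2 and hom_c >= 1:
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / (
            (het + 2.0) * (het + 1.0)
        )
        het += 2
        hom_r -= 1
        hom_c -= 1
    total = sum(probs.values())
    p_obs = probs.get(obs_het, 0.0)
    p = sum(v for v in probs.values() if v <= p_obs * (1.0 + 1e-12)) / total
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# variant filters


def variant_qc(
    genotypes: GenotypeDataset, thresholds: QcThresholds | None = None
) -> tuple[GenotypeDataset, QcReport]:
    """Sequential call-rate -> MAF -> HWE variant filters with counts."""
    thresholds = thresholds or QcThresholds()
    removed: dict[str, int] = {}

    keep = genotypes.call_rate() >= thresholds.min_call_rate
    removed["call_rate"] = int((~keep).sum())
    ds = genotypes.subset_variants(keep)

    keep = ds.maf() >= thresholds.min_maf
    removed["maf"] = int((~keep).sum())
    ds = ds.subset_variants(keep)

    counts = ds.genotype_counts()
    hwe_p = np.array(
        [
            hwe_exact_test(*row) if row.sum() > 0 else 1.0
            for row in counts
        ]
    )
    keep = hwe_p > thresholds.min_hwe_p
    removed["hwe"] = int((~keep).sum())
    ds = ds.subset_variants(keep)

    report = QcReport(
        variants_in=genotypes.n_variants,
        variants_out=ds.n_variants,
        samples_in=genotypes.n_samples,
        samples_out=ds.n_samples,
        removed=removed,
    )
    return ds, report


# ---------------------------------------------------------------------------
# identity by descent


def ibd_pi_hat(
    g1: np.ndarray, g2: np.ndarray, allele_freqs: np.ndarray
) -> float:
    """PLINK-style method-of-moments PI_HAT for one sample pair.

    IBS counts are compared with their expectations under IBD states 0/1/2
    given allele frequencies; PI_HAT = P(IBD=2) + P(IBD=1)/2, clamped to
    [0, 1].  Requires >= 100 pairwise-complete polymorphic variants.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    if not (g1.shape == g2.shape == p.shape):
        raise ValueError("g1, g2 and allele_freqs must have equal length")
    ok = ~(np.isnan(g1) | np.isnan(g2)) & (p > 0) & (p < 1)
    if ok.sum() < 100:
        raise InsufficientDataError(
            f"only {int(ok.sum())} informative variants; need >= 100"
        )
    g1, g2, p = g1[ok], g2[ok], p[ok]
    q = 1.0 - p

    ibs = 2.0 - np.abs(g1 - g2)
    # IBS0 requires opposite homozygotes
    ibs0 = (np.abs(g1 - g2) == 2).sum()
    ibs1 = (np.abs(g1 - g2) == 1).sum()
    ibs2 = (np.abs(g1 - g2) == 0).sum()
    del ibs

    # expectations per variant under each IBD state
    e0_ibs0 = 2.0 * p**2 * q**2
    e0_ibs1 = 4.0 * p**3 * q + 4.0 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4.0 * p**2 * q**2
    e1_ibs1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e1_ibs2 = 1.0 - e1_ibs1

    p0 = ibs0 / e0_ibs0.sum()
    p1 = (ibs1 - p0 * e0_ibs1.sum()) / e1_ibs1.sum()
    p2 = (ibs2 - p0 * e0_ibs2.sum() - p1 * e1_ibs2.sum()) / len(p)
    p0, p1, p2 = (float(np.clip(x, 0.0, 1.0)) for x in (p0, p1, p2))
    pi_hat = p2 + 0.5 * p1
    return float(np.clip(pi_hat, 0.0, 1.0))


def relatedness_filter(
    genotypes: GenotypeDataset,
    max_ibd: float = 0.1875,
    max_pairs_variants: int | None = None,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Drop one sample of every pair with PI_HAT >= max_ibd (second kept out).

    Returns the filtered dataset and the table of flagged pairs.  O(n^2)
    pairs — intended for the modest cohort sizes this package simulates.
    """
    p_alt = np.nanmean(genotypes.dosages, axis=0) / 2.0
    flagged = []
    drop: set[int] = set()
    n = genotypes.n_samples
    dos = genotypes.dosages
    if max_pairs_variants is not None:
        dos = dos[:, :max_pairs_variants]
        p_alt = p_alt[:max_pairs_variants]
    for i in range(n):
        if i in drop:
            continue
        for j in range(i + 1, n):
            if j in drop:
                continue
            pi = ibd_pi_hat(dos[i], dos[j], p_alt)
            if pi >= max_ibd:
                flagged.append(
                    {
                        "sample_i": genotypes.samples[i],
                        "sample_j": genotypes.samples[j],
                        "pi_hat": pi,
                    }
                )
                drop.add(j)
    keep = np.array([i not in drop for i in range(n)])
    return genotypes.subset_samples(keep), pd.DataFrame(
        flagged, columns=["sample_i", "sample_j", "pi_hat"]
    )


# ---------------------------------------------------------------------------
# stratification PCA


@dataclass
class PcaProjection:
    reference_scores: np.ndarray
    study_scores: np.ndarray
    eigenvalues: np.ndarray


def _as_matrix(x) -> np.ndarray:
    return x.dosages if isinstance(x, GenotypeDataset) else np.asarray(x, float)


def pca_stratify(
    reference, study, n_components: int = 2
) -> PcaProjection:
    """PCA on a reference panel; study samples projected onto its axes.

    Dosages are standardised by the reference allele frequency,
    (g - 2p) / sqrt(2 p (1-p)).  When both arguments are GenotypeDatasets
    the variant sets are intersected on (chrom, pos, ref, alt) first.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if isinstance(reference, GenotypeDataset) and isinstance(study, GenotypeDataset):
        key = ["chrom", "pos", "ref", "alt"]
        ref_keys = reference.variants[key].apply(tuple, axis=1)
        stu_keys = study.variants[key].apply(tuple, axis=1)
        shared = set(ref_keys) & set(stu_keys)
        if not shared:
            raise ValueError("no overlapping variants between panels")
        ref_mask = ref_keys.isin(shared).to_numpy()
        stu_mask = stu_keys.isin(shared).to_numpy()
        ref_mat = reference.dosages[:, ref_mask]
        stu_mat = study.dosages[:, stu_mask]
        # align column order by key
        ref_order = np.argsort(ref_keys[ref_mask].astype(str).to_numpy())
        stu_order = np.argsort(stu_keys[stu_mask].astype(str).to_numpy())
        ref_mat = ref_mat[:, ref_order]
        stu_mat = stu_mat[:, stu_order]
    else:
        ref_mat = _as_matrix(reference)
        stu_mat = _as_matrix(study)
        if ref_mat.shape[1] != stu_mat.shape[1]:
            raise ValueError("reference and study must share the variant set")
    p = np.nanmean(ref_mat, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic shared variants")
    p = p[poly]
    scale = np.sqrt(2.0 * p * (1.0 - p))
    Xr = (np.nan_to_num(ref_mat[:, poly]) - 2.0 * p) / scale
    Xs = (np.nan_to_num(stu_mat[:, poly]) - 2.0 * p) / scale
    U, s, Vt = np.linalg.svd(Xr, full_matrices=False)
    k = min(n_components, s.size)
    V = Vt[:k].T
    return PcaProjection(
        reference_scores=Xr @ V,
        study_scores=Xs @ V,
        eigenvalues=s**2 / (ref_mat.shape[0] - 1),
    )


def flag_pc_outliers(
    projection: PcaProjection,
    k_sd: float = 6.0,
    cluster: np.ndarray | None = None,
) -> np.ndarray:
    """Study samples beyond k_sd (component-standardised radius) of the
    reference cluster centroid; True marks an outlier to exclude.

    ``cluster`` optionally restricts the reference to the target ancestry
    cluster (boolean mask over reference rows) when the panel mixes
    populations.
    """
    ref = projection.reference_scores
    if cluster is not None:
        ref = ref[np.asarray(cluster, bool)]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (projection.study_scores - mu) / sd
    return np.sqrt((z**2).sum(axis=1)) > k_sd
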