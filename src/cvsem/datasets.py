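"""In-memory containers and file I/O for genotype and questionnaire data.

Genotypes are held as an additively coded dosage matrix (count of the ALT
allele, 0/1/2, NaN for missing) with a variant table carrying chromosome,
1-based position and alleles — the layout every downstream stage (QC,
association scan, LD) consumes directly.  Plain uncompressed VCF 4.2 with a
GT field is the on-disk interchange format; questionnaires and covariates
travel as tab-delimited tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

#: Fixed mapping of the 14 questionnaire items onto the four symptom
#: categories (asthenopic, ocular-surface-related, visual, extra-ocular).
ITEM_CATEGORIES: dict[str, str] = {
    "q1": "asthenopic",
    "q2": "asthenopic",
    "q3": "asthenopic",
    "q4": "ocular_surface",
    "q5": "ocular_surface",
    "q6": "ocular_surface",
    "q7": "ocular_surface",
    "q8": "visual",
    "q9": "visual",
    "q10": "extra_ocular",
    "q11": "extra_ocular",
    "q12": "extra_ocular",
    "q13": "extra_ocular",
    "q14": "extra_ocular",
}

CATEGORY_ORDER = ["asthenopic", "ocular_surface", "visual", "extra_ocular"]

ITEMS = list(ITEM_CATEGORIES)


class DataValidationError(ValueError):
    """Raised when an input table violates its declared contract."""


@dataclass
class GenotypeDataset:
    """Sample-by-variant dosage matrix plus variant and sample metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_variants)
        ALT-allele counts in {0, 1, 2}; missing calls are NaN.
    variants : DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt``
        (``pos`` 1-based) plus any derived columns such as ``maf``.
    samples : list of str
        Sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataValidationError("dosages must be a 2-D matrix")
        if len(self.variants) != self.dosages.shape[1]:
            raise DataValidationError(
                f"variant table has {len(self.variants)} rows but dosage "
                f"matrix has {self.dosages.shape[1]} columns"
            )
        if not self.samples:
            self.samples = [f"S{i:05d}" for i in range(self.dosages.shape[0])]
        if len(self.samples) != self.dosages.shape[0]:
            raise DataValidationError("sample list does not match dosage rows")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise DataValidationError(f"variant table lacks columns {missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per variant (missing-aware)."""
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p_alt, 1.0 - p_alt)

    def genotype_counts(self) -> np.ndarray:
        """Hard genotype counts per variant: columns (n_AA, n_Aa, n_aa).

        AA denotes the REF homozygote (dosage 0), aa the ALT homozygote.
        """
        counts = np.zeros((self.n_variants, 3), dtype=int)
        for g in (0, 1, 2):
            counts[:, g] = np.nansum(self.dosages == g, axis=0)
        return counts

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            self.dosages[:, mask],
            self.variants.loc[mask].reset_index(drop=True),
            list(self.samples),
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            self.dosages[mask],
            self.variants.copy(),
            [s for s, keep in zip(self.samples, mask) if keep],
        )


@dataclass
class QuestionnaireData:
    """Per-subject 14-item Likert responses under two recall conditions.

    ``responses`` has columns ``q1_before .. q14_before, q1_after .. q14_after``
    with integer values on the 1–7 scale, indexed by subject id.
    """

    responses: pd.DataFrame

    def __post_init__(self) -> None:
        expected = [f"{q}_{c}" for c in ("before", "after") for q in ITEMS]
        missing = [c for c in expected if c not in self.responses.columns]
        if missing:
            raise DataValidationError(f"questionnaire lacks columns {missing}")

    @property
    def n_subjects(self) -> int:
        return len(self.responses)


# ---------------------------------------------------------------------------
# VCF I/O

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=cvsem
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(dataset: GenotypeDataset, path: str | os.PathLike) -> None:
    """Write hard-call genotypes as an uncompressed VCF 4.2 with GT only."""
    v = dataset.variants
    contigs = list(dict.fromkeys(v["chrom"].astype(str)))
    try:
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(dataset.samples)
                + "\n"
            )
            dos = dataset.dosages
            for j in range(dataset.n_variants):
                row = v.iloc[j]
                gts = "\t".join(
                    "./." if np.isnan(d) else _GT_CODES[int(d)] for d in dos[:, j]
                )
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                    f"\t.\t.\t.\tGT\t{gts}\n"
                )
    except OSError as exc:
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc


def read_vcf(path: str | os.PathLike) -> GenotypeDataset:
    """Read a VCF into a GenotypeDataset (ALT-dosage coding, NaN missing)."""
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for var in vcf:
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID if var.ID is not None else f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan  # gts012: 3 encodes unknown
        dosage_cols.append(gt)
    vcf.close()
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(samples), 0))
    )
    return GenotypeDataset(dosages, variants, samples)


# ---------------------------------------------------------------------------
# TSV I/O

def write_tsv(frame: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    try:
        # %.17g guarantees binary round-trip of float64 through text
        frame.to_csv(path, sep="\t", index=index, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"failed writing table to {path}: {exc}") from exc


def read_tsv(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    # round_trip parsing so persisted floats reload bit-identically
    return pd.read_csv(
        path, sep="\t", index_col=index_col, float_precision="round_trip"
    )


def read_questionnaire(path: str | os.PathLike) -> QuestionnaireData:
    return QuestionnaireData(read_tsv(path))


def read_covariates(path: str | os.PathLike) -> pd.DataFrame:
    cov = read_tsv(path)
    for col in ("age", "sex"):
        if col not in cov.columns:
            raise DataValidationError(f"covariate table lacks column '{col}'")
    return cov
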