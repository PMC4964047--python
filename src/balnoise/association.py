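"""Genotype-expression association and transcriptional responsiveness.

A regulatory SNP's expression effect is estimated by ordinary least
squares of the target gene's expression on the additive genotype dosage
(0/1/2), reporting R^2, the regression p-value and its Bonferroni
adjustment over the number of SNP-gene pairs tested.  When a focal SNP
is absent from a genotyping array, the closest array SNP within 500 kb
in strong LD (r^2 > 0.9) serves as its tag.  Responsiveness of a gene
is the maximum absolute expression change from baseline across
conditions, computed on sample-wise mean-centered expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import ld_r2

__all__ = [
    "AssocResult",
    "genotype_expression_regression",
    "find_tag_snp",
    "responsiveness",
    "samplewise_center",
]


@dataclass
class AssocResult:
    snp_id: str
    gene_id: str
    r2: float
    p_raw: float
    p_adjusted: float
    n_samples: int
    defined: bool = True


def genotype_expression_regression(
    genotypes,
    expression,
    m_tests: int = 1,
    snp_id: str = "",
    gene_id: str = "",
) -> AssocResult:
    """OLS of expression on allele dosage; R^2, p, Bonferroni-adjusted p."""
    g = np.asarray(genotypes, dtype=float)
    e = np.asarray(expression, dtype=float)
    if g.shape != e.shape:
        raise ValueError("genotype and expression vectors must match")
    if g.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.unique(g).size < 2:
        return AssocResult(snp_id, gene_id, np.nan, np.nan, np.nan, g.size, defined=False)
    fit = stats.linregress(g, e)
    r2 = float(fit.rvalue**2)
    p = float(fit.pvalue)
    return AssocResult(snp_id, gene_id, r2, p, min(1.0, p * m_tests), g.size)


def find_tag_snp(
    focal: pd.Series,
    array_snps: pd.DataFrame,
    genotypes: dict[str, np.ndarray],
    r2_min: float = 0.9,
    max_dist_bp: int = 500_000,
) -> str | None:
    """Closest array SNP within ``max_dist_bp`` at r^2 > ``r2_min``.

    ``focal`` needs ``snp_id``, ``chrom``, ``pos``; ``array_snps`` one
    row per array SNP with the same columns.  Returns the tag's snp_id
    or None.  The focal SNP itself (distance 0), if on the array,
    trivially qualifies.
    """
    gf = genotypes[focal["snp_id"]]
    cands = array_snps[
        (array_snps["chrom"] == focal["chrom"])
        & (np.abs(array_snps["pos"] - focal["pos"]) <= max_dist_bp)
    ].copy()
    if not len(cands):
        return None
    cands["dist"] = np.abs(cands["pos"] - focal["pos"])
    for row in cands.sort_values(["dist", "snp_id"]).itertuples():
        r2 = ld_r2(gf, genotypes[row.snp_id])
        if not np.isnan(r2) and r2 > r2_min:
            return row.snp_id
    return None


def responsiveness(
    expression_by_condition: pd.DataFrame, baseline_condition: str
) -> pd.Series:
    """Max absolute change from baseline per gene (rows=genes, cols=conditions)."""
    if baseline_condition not in expression_by_condition.columns:
        raise ValueError("baseline condition missing from the matrix")
    if expression_by_condition.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    base = expression_by_condition[baseline_condition]
    others = expression_by_condition.drop(columns=[baseline_condition])
    return others.sub(base, axis=0).abs().max(axis=1).rename("max_abs_change")


def samplewise_center(expression: pd.DataFrame) -> pd.DataFrame:
    """Set the mean expression of all genes in each sample (column) to zero."""
    return expression - expression.mean(axis=0)
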