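"""Cell-type/TF overlap enrichment and gene-set testing for balanced SNPs.

The enrichment score of a track (DHS of one cell type, one TF's binding
regions, ...) is the ratio of the overlap *rates* of the balanced and
control SNP sets — rate-normalized because the two sets differ ~80-fold
in size; raw counts are also reported.  Target genes of a SNP set are
read off an enhancer/promoter-to-gene map, and gene-set enrichment uses
the one-sided hypergeometric upper tail with Benjamini-Hochberg
correction across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pipeline import build_interval_trees

__all__ = [
    "EnrichmentResult",
    "overlap_enrichment",
    "map_targets",
    "geneset_test",
]


@dataclass
class EnrichmentResult:
    track_id: str
    n_balanced_overlap: int
    n_control_overlap: int
    frac_balanced: float
    frac_control: float
    score: float  # ratio of overlap rates; NaN when undefined
    raw_count_ratio: float


def _overlap_count(positions: pd.DataFrame, trees) -> int:
    hits = 0
    for chrom, pos in zip(positions["chrom"], positions["pos"]):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(pos, pos + 1):
            hits += 1
    return hits


def overlap_enrichment(
    balanced: pd.DataFrame, control: pd.DataFrame, tracks: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-track enrichment of balanced vs control SNP overlap rates.

    ``balanced``/``control`` need ``chrom`` and ``pos`` columns; a SNP
    overlapping any interval of a track counts once.  A zero control
    overlap leaves the score undefined (NaN) — no pseudocount.
    Returns a DataFrame sorted by descending score, with the mean score
    across tracks attached as ``mean_score_reference``.
    """
    if not len(balanced) or not len(control):
        raise ValueError("both SNP sets must be non-empty")
    rows = []
    for track_id, track in tracks.items():
        trees = build_interval_trees(track.sort_values(["chrom", "start"]))
        nb = _overlap_count(balanced, trees)
        nc = _overlap_count(control, trees)
        fb = nb / len(balanced)
        fc = nc / len(control)
        rows.append(
            EnrichmentResult(
                track_id=track_id,
                n_balanced_overlap=nb,
                n_control_overlap=nc,
                frac_balanced=fb,
                frac_control=fc,
                score=fb / fc if nc > 0 else np.nan,
                raw_count_ratio=nb / nc if nc > 0 else np.nan,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        "score", ascending=False, ignore_index=True
    )
    df["mean_score_reference"] = df["score"].mean()
    return df


def map_targets(
    snps: pd.DataFrame, elements: pd.DataFrame, ep_map: pd.DataFrame
) -> list[str]:
    """Genes whose promoter is linked to an element containing a SNP.

    ``elements``: regulatory intervals (chrom, start, end, element_id) —
    enhancers and promoters (a promoter is the 500 bp upstream of the
    TSS and is mapped to its own gene in ``ep_map``).  ``ep_map``:
    (element_id, gene) links; one element may target several genes.
    Returns the deduplicated, sorted target gene list.
    """
    if not len(ep_map):
        return []
    hit_elements: set = set()
    for chrom, sub in elements.groupby("chrom"):
        pos = snps.loc[snps["chrom"] == chrom, "pos"].to_numpy()
        if not pos.size:
            continue
        for row in sub.itertuples():
            if np.any((pos >= row.start) & (pos < row.end)):
                hit_elements.add(row.element_id)
    genes = ep_map.loc[ep_map["element_id"].isin(hit_elements), "gene"]
    return sorted(set(genes))


def geneset_test(
    target_genes, term_memberships: pd.DataFrame, background
) -> pd.DataFrame:
    """Hypergeometric upper-tail test per term with BH correction.

    ``term_memberships``: (gene, term) long table; ``background``: the
    gene universe (targets must be a subset).  For a term with K
    members, n targets and k hits, p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  Terms with no background members are
    skipped.  ``significant`` marks BH-adjusted p < 0.05.
    """
    background = set(background)
    targets = set(target_genes)
    if not targets <= background:
        raise ValueError("target genes must be a subset of the background")
    N, n = len(background), len(targets)
    rows = []
    members = term_memberships[term_memberships["gene"].isin(background)]
    for term, sub in members.groupby("term"):
        genes = set(sub["gene"])
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p_hyper": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = multipletests(df["p_hyper"], method="fdr_bh")[1]
        df["significant"] = df["p_bh"] < 0.05
        df = df.sort_values("p_hyper", ignore_index=True)
    return df
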