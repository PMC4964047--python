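"""Artifact filtering and selection-based classification of candidate SNPs.

The workflow mirrors a genome scan for balanced cis-regulatory variants:
flag (never drop) SNPs failing artifact filters — proximity to
exceptionally high mapping depth, non-unique 50-mer mappability,
segmental duplications, low minor-allele frequency, Hardy-Weinberg
violation — then classify the surviving footprint SNPs by a selection
statistic: the top 1% of Tajima's D are called balanced and the middle
80% are the control set.  Finally, balanced regulatory SNPs whose signal
may be hitch-hiking on a linked nonsynonymous variant (r^2 > 0.9 within
500 kb with a higher D) are excluded.

SNP sets travel as pandas DataFrames with one row per SNP; interval
tracks as DataFrames with 0-based half-open ``start``/``end`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .popgen import hwe_exact_test, ld_r2

__all__ = [
    "SnpRecord",
    "FilterConfig",
    "build_interval_trees",
    "apply_artifact_filters",
    "classify_by_selection",
    "nonsynonymous_ld_exclusion",
]

FILTER_NAMES = ("depth", "mappability", "segdup", "maf", "hwe")


@dataclass
class SnpRecord:
    """One candidate variant with its annotations."""

    id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"
    maf: float = np.nan
    in_footprint: bool = True
    filter_flags: frozenset = frozenset()
    tajima_d: float = np.nan
    hka_k: float = np.nan
    fst: float = np.nan
    class_label: str = "other"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the artifact filters and the selection quantiles."""

    depth_top_fraction: float = 0.001
    depth_flank_bp: int = 50_000
    mappability_kmer: int = 50
    segdup_min_len: int = 1000
    segdup_min_identity: float = 0.90
    maf_min: float = 0.01
    hwe_alpha: float = 0.05
    ld_r2_min: float = 0.9
    ld_max_dist_bp: int = 500_000
    balanced_quantile: float = 0.99
    control_quantiles: tuple[float, float] = (0.10, 0.90)

    def __post_init__(self) -> None:
        if not self.balanced_quantile > self.control_quantiles[1]:
            raise ValueError("balanced quantile must exceed the control upper bound")


def build_interval_trees(track: pd.DataFrame) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees from a BED-like DataFrame."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in track.groupby("chrom"):
        starts = sub["start"].to_numpy()
        if not (np.diff(starts) >= 0).all():
            raise ValueError("track intervals must be sorted by start")
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]) if e > s
        )
    return trees


def _overlaps(trees, chrom, start, end) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(start, end))


def apply_artifact_filters(
    snps: pd.DataFrame,
    depth_track: pd.DataFrame | None = None,
    mappability_track: pd.DataFrame | None = None,
    segdup_track: pd.DataFrame | None = None,
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Flag SNPs failing each artifact filter; returns a copy with flags.

    depth_track
        BED with a ``score`` column (mapping depth); the top
        ``depth_top_fraction`` of intervals by score define the
        high-depth regions, and a SNP is flagged when its
        ``depth_flank_bp`` flank intersects one.  A track already
        reduced to high-depth regions (no score column) is used as is.
    mappability_track
        Regions of non-unique mappability; a SNP is flagged when any
        k-mer overlapping the site intersects one.
    segdup_track
        Segmental-duplication regions (optionally with ``length`` and
        ``identity`` columns, filtered by the config minima); a SNP is
        flagged when it lies inside one.

    A missing track skips that filter with a warning.  MAF and HWE
    filters use the ``maf`` and genotype-count columns (``n_aa``,
    ``n_ab``, ``n_bb``); HWE p-values are Bonferroni-adjusted across all
    SNPs entering the test.
    """
    out = snps.copy()
    for name in FILTER_NAMES:
        out[f"flag_{name}"] = False

    if depth_track is not None and len(depth_track):
        if "score" in depth_track.columns:
            cutoff = depth_track["score"].quantile(1.0 - config.depth_top_fraction)
            high = depth_track[depth_track["score"] >= cutoff]
        else:
            high = depth_track
        trees = build_interval_trees(high)
        fl = config.depth_flank_bp
        out["flag_depth"] = [
            _overlaps(trees, c, p - fl, p + fl + 1)
            for c, p in zip(out["chrom"], out["pos"])
        ]
    else:
        warnings.warn("no depth track given; depth filter skipped")

    if mappability_track is not None and len(mappability_track):
        trees = build_interval_trees(mappability_track)
        k = config.mappability_kmer
        out["flag_mappability"] = [
            _overlaps(trees, c, p - (k - 1), p + k)
            for c, p in zip(out["chrom"], out["pos"])
        ]
    else:
        warnings.warn("no mappability track given; mappability filter skipped")

    if segdup_track is not None and len(segdup_track):
        sd = segdup_track
        if "length" in sd.columns or "identity" in sd.columns:
            length = sd.get("length", sd["end"] - sd["start"])
            identity = sd.get("identity", pd.Series(1.0, index=sd.index))
            sd = sd[(length >= config.segdup_min_len) & (identity >= config.segdup_min_identity)]
        trees = build_interval_trees(sd)
        out["flag_segdup"] = [
            _overlaps(trees, c, p, p + 1) for c, p in zip(out["chrom"], out["pos"])
        ]
    else:
        warnings.warn("no segdup track given; segdup filter skipped")

    if "maf" in out.columns:
        out["flag_maf"] = out["maf"] < config.maf_min

    if {"n_aa", "n_ab", "n_bb"}.issubset(out.columns):
        tested = ~out["flag_maf"]
        m = int(tested.sum())
        if m:
            pvals = np.array(
                [
                    hwe_exact_test(int(r.n_aa), int(r.n_ab), int(r.n_bb))
                    for r in out.loc[tested].itertuples()
                ]
            )
            out.loc[tested, "hwe_p"] = pvals
            out.loc[tested, "flag_hwe"] = np.minimum(pvals * m, 1.0) < config.hwe_alpha

    out["filter_flags"] = [
        ";".join(sorted(n for n in FILTER_NAMES if row[f"flag_{n}"]))
        for _, row in out.iterrows()
    ]
    return out


def classify_by_selection(
    snps: pd.DataFrame,
    statistic: str = "tajima_d",
    config: FilterConfig = FilterConfig(),
    population: str | None = None,
) -> pd.DataFrame:
    """Assign balanced / control / other labels by statistic quantiles.

    Only unflagged footprint SNPs enter the quantile computation (done
    per population when a ``population`` column name is given).
    ``balanced``: statistic >= its empirical ``balanced_quantile``
    (ties at the boundary included); ``control``: within the
    half-open control-quantile band.  Everything else is ``other``;
    flagged or off-footprint SNPs are ``excluded``.
    """
    out = snps.copy()
    eligible = (out["filter_flags"] == "") & out.get("in_footprint", True)
    out["class_label"] = np.where(eligible, "other", "excluded")

    groups = [(None, out.index[eligible])]
    if population is not None:
        groups = list(
            out.index[eligible].groupby(out.loc[eligible, population]).items()
        )
    for _, idx in groups:
        vals = out.loc[idx, statistic].to_numpy(dtype=float)
        if vals.size < 100:
            warnings.warn("fewer than 100 SNPs; selection quantiles are unstable")
        if vals.size == 0:
            continue
        q_bal = np.quantile(vals, config.balanced_quantile)
        q_lo, q_hi = np.quantile(vals, config.control_quantiles)
        lab = np.where(
            vals >= q_bal,
            "balanced",
            np.where((vals >= q_lo) & (vals < q_hi), "control", "other"),
        )
        out.loc[idx, "class_label"] = lab
    return out


def nonsynonymous_ld_exclusion(
    balanced: pd.DataFrame,
    nonsyn: pd.DataFrame,
    genotypes: dict[str, np.ndarray],
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Drop balanced SNPs hitch-hiking on a linked nonsynonymous SNP.

    A balanced SNP is excluded iff some nonsynonymous SNP within
    ``ld_max_dist_bp`` on the same chromosome has r^2 > ``ld_r2_min``
    with it and a strictly higher value of the selection statistic.
    Returns a copy with an ``excluded_nonsyn_ld`` column.
    """
    out = balanced.copy()
    excl = []
    for row in out.itertuples():
        flag = False
        cands = nonsyn[
            (nonsyn["chrom"] == row.chrom)
            & (np.abs(nonsyn["pos"] - row.pos) < config.ld_max_dist_bp)
        ]
        ga = genotypes[row.snp_id]
        for nrow in cands.itertuples():
            r2 = ld_r2(ga, genotypes[nrow.snp_id])
            if np.isnan(r2) or r2 <= config.ld_r2_min:
                continue
            if nrow.tajima_d > row.tajima_d:
                flag = True
                break
        excl.append(flag)
    out["excluded_nonsyn_ld"] = excl
    return out
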