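"""Empirical noise quantification from single-cell matrices.

Expression noise per gene is the squared coefficient of variation CV^2
of depth-normalized counts, fitted against the mean with the standard
two-parameter form CV^2 = a0 + a1/mu (a0: mean-independent noise floor,
a1: Poisson-like 1/mu component).  Low-expression genes (mean below a
cutoff) are excluded, as their CV saturates.  "Noise strength" is the
Fano-like sigma^2/mu.  Cell-to-cell chromatin-accessibility variability
of a peak group is the standard deviation across cells of the
depth-standardized group deviation, with a cell bootstrap for its
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SingleCellMatrix",
    "NoiseFit",
    "ChromatinVariability",
    "normalize_depth",
    "gene_cv2",
    "fit_cv2_mean",
    "noise_strength",
    "chromatin_variability",
    "bin_by_selection",
]


@dataclass
class SingleCellMatrix:
    """features (genes or peaks) x cells values with optional metadata."""

    values: np.ndarray
    feature_ids: list = None
    cell_ids: list = None
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be features x cells")
        if self.feature_ids is None:
            self.feature_ids = [f"f{i}" for i in range(self.values.shape[0])]
        if self.cell_ids is None:
            self.cell_ids = [f"c{j}" for j in range(self.values.shape[1])]

    @property
    def depths(self) -> np.ndarray:
        return self.values.sum(axis=0)


def normalize_depth(values: np.ndarray) -> np.ndarray:
    """Scale each cell's counts to the mean per-cell total."""
    depths = values.sum(axis=0)
    if np.any(depths <= 0):
        raise ValueError("every cell must have positive depth")
    return values * (depths.mean() / depths)


def gene_cv2(
    matrix: SingleCellMatrix | np.ndarray,
    min_mean: float = 100.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-gene mean, CV and CV^2 of (depth-normalized) counts.

    Genes with normalized mean < ``min_mean`` are excluded (saturated
    CV at low expression); zero-mean genes are excluded with their own
    reason.  Returns a DataFrame indexed like the features with an
    ``included`` flag and ``exclude_reason``.
    """
    if isinstance(matrix, SingleCellMatrix):
        vals, ids = matrix.values, matrix.feature_ids
    else:
        vals = np.asarray(matrix, dtype=float)
        ids = [f"f{i}" for i in range(vals.shape[0])]
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    x = normalize_depth(vals) if normalize else vals
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu > 0, sd / mu, np.nan)
    df = pd.DataFrame(
        {"feature_id": ids, "mean": mu, "cv": cv, "cv2": cv**2}
    )
    df["exclude_reason"] = np.where(
        mu <= 0, "zero_mean", np.where(mu < min_mean, "low_mean", "")
    )
    df["included"] = df["exclude_reason"] == ""
    return df


@dataclass
class NoiseFit:
    """Least-squares fit of CV^2 = a0 + a1/mu, per group."""

    a0: float
    a1: float
    n_genes: int
    residual_ss: float
    group: str = ""


def fit_cv2_mean(per_gene: pd.DataFrame, group_col: str | None = None) -> list[NoiseFit]:
    """Fit CV^2 = a0 + a1/mu by OLS, per group when ``group_col`` given.

    Uses only rows with ``included`` True (if the column exists).  A
    group needs >= 3 genes and >= 2 distinct means; a negative a1 on
    count-like data triggers a warning flag via ``NoiseFit.a1``.
    """
    df = per_gene
    if "included" in df.columns:
        df = df[df["included"]]
    groups = [("", df)] if group_col is None else list(df.groupby(group_col))
    fits = []
    for name, sub in groups:
        if len(sub) < 3:
            raise ValueError(f"group {name!r}: need >= 3 genes to fit")
        x = 1.0 / sub["mean"].to_numpy()
        y = sub["cv2"].to_numpy()
        if np.unique(x).size < 2:
            raise ValueError(f"group {name!r}: degenerate design (single mean)")
        a1, a0 = np.polyfit(x, y, 1)
        resid = y - (a0 + a1 * x)
        fits.append(NoiseFit(float(a0), float(a1), len(sub), float(resid @ resid), str(name)))
    return fits


def noise_strength(
    per_gene_or_matrix,
    statistic: np.ndarray | None = None,
    log_transform: bool = True,
    method: str = "pearson",
):
    """Per-gene sigma^2/mu, and its correlation with a selection statistic.

    With a raw matrix input, computes the Fano-like noise strength per
    gene on the raw counts (Poisson data gives ~1 at any mean).  When a
    per-gene ``statistic`` (e.g. the linked regulatory SNP's Tajima's D
    or HKA k) is provided, returns (noise_strength, r, p) with the
    correlation computed on log noise strength by default.
    """
    if isinstance(per_gene_or_matrix, pd.DataFrame):
        df = per_gene_or_matrix
        ns = (df["cv2"] * df["mean"]).to_numpy()
    else:
        vals = np.asarray(per_gene_or_matrix, dtype=float)
        mu = vals.mean(axis=1)
        var = vals.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ns = np.where(mu > 0, var / mu, np.nan)
    if statistic is None:
        return ns
    stat = np.asarray(statistic, dtype=float)
    ok = np.isfinite(ns) & np.isfinite(stat) & (ns > 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 genes for a correlation")
    y = np.log(ns[ok]) if log_transform else ns[ok]
    if method == "pearson":
        r, p = stats.pearsonr(stat[ok], y)
    elif method == "spearman":
        r, p = stats.spearmanr(stat[ok], y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return ns, float(r), float(p)


@dataclass
class ChromatinVariability:
    group: str
    variability: float
    bootstrap_sd: float
    n_peaks: int
    n_cells: int


def _group_variability(group_counts: np.ndarray, depths: np.ndarray) -> float:
    """SD across cells of the depth-standardized group deviation.

    Per cell: deviation = (observed - expected)/sqrt(expected), with
    expected = cell depth x the group's overall accessibility fraction.
    """
    obs = group_counts.sum(axis=0)
    frac = obs.sum() / depths.sum()
    expected = depths * frac
    dev = (obs - expected) / np.sqrt(expected)
    return float(dev.std(ddof=1))


def chromatin_variability(
    counts: np.ndarray,
    peak_groups,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Cell-to-cell accessibility variability per peak group, with bootstrap SD.

    ``counts``: peaks x cells fragment counts; ``peak_groups``: group
    label per peak.  The bootstrap resamples cells with replacement
    (``n_boot`` times, seeded) and reports the SD of the recomputed
    variability.  Groups with < 2 peaks are flagged NaN.
    """
    counts = np.asarray(counts, dtype=float)
    peak_groups = np.asarray(peak_groups)
    depths = counts.sum(axis=0)
    if np.any(depths <= 0):
        raise ValueError("every cell must have positive depth")
    rng = np.random.default_rng(seed)
    n_cells = counts.shape[1]
    rows = []
    for g in pd.unique(peak_groups):
        sel = peak_groups == g
        if sel.sum() < 2:
            rows.append(ChromatinVariability(str(g), np.nan, np.nan, int(sel.sum()), n_cells))
            continue
        sub = counts[sel]
        v = _group_variability(sub, depths)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(n_cells, size=n_cells)
            boots[b] = _group_variability(sub[:, idx], depths[idx])
        rows.append(
            ChromatinVariability(str(g), v, float(boots.std(ddof=1)), int(sel.sum()), n_cells)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def bin_by_selection(
    features: pd.DataFrame,
    statistic: str = "tajima_d",
    zygosity_col: str = "zygosity",
    bin_edges=(-np.inf, 0.0, 1.5, np.inf),
) -> pd.Series:
    """Partition features into hom vs het, the latter binned by statistic.

    Homozygous features form one group; heterozygous features are
    assigned to half-open bins [edge_i, edge_{i+1}) of the statistic
    (so a value exactly on an edge goes to the upper bin).  Features
    lacking zygosity or statistic become "unassigned".
    """
    edges = np.asarray(bin_edges, dtype=float)
    labels = []
    for _, row in features.iterrows():
        z = row.get(zygosity_col)
        v = row.get(statistic)
        if z == "hom":
            labels.append("hom")
        elif z == "het" and pd.notna(v):
            i = int(np.searchsorted(edges, v, side="right")) - 1
            i = min(max(i, 0), edges.size - 2)
            labels.append(f"het_[{edges[i]:g},{edges[i+1]:g})")
        else:
            labels.append("unassigned")
    return pd.Series(labels, index=features.index, name="selection_bin")
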