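"""Synthetic-data generators for every input the analyses consume.

The haplotype generators implement Hudson's neutral coalescent under the
infinite-sites model (no recombination; mutations Poisson at rate
theta/2 per unit of coalescent branch length, time in units of 2N
generations).  A balanced polymorphism is emulated with a two-class
structured genealogy: haplotypes carrying different focal alleles may
only coalesce with their own class until ``class_split_time``, after
which the surviving lineages coalesce freely.  An old split leaves each
allelic class with its own set of neutral mutations and inflates
intermediate-frequency polymorphism, which is exactly the pattern the
Tajima's D scan targets.

Read-count and single-cell generators provide allele-biased ATAC/DNase
reads at heterozygous sites, gamma-mixed Poisson single-cell expression
(shared TF draw per cell; the heterozygote applies its two dissociation
constants to the same draw), and per-cell ATAC fragment counts with a
group-shared extrinsic factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeMatrix
from . import noise_model as nm
from .popgen import tajima_d_from_counts

__all__ = [
    "SimConfig",
    "simulate_neutral_haplotypes",
    "simulate_balanced_haplotypes",
    "neutral_d_values",
    "balanced_d_values",
    "simulate_d_scan",
    "simulate_allelic_reads",
    "simulate_single_cell_expression",
    "simulate_single_cell_atac",
]


@dataclass
class SimConfig:
    """Knobs of every generator; defaults are the study conditions.

    theta is the scaled mutation rate for the whole simulated window
    (human-like ~0.001/bp over 5 kb); class_split_time is in units of 2N
    generations, far beyond the typical neutral TMRCA of ~2 so planted
    balanced loci are clearly old.
    """

    seed: int = 0
    n_haplotypes: int = 100
    window_bp: int = 5000
    theta: float = 5.0
    balanced_fraction: float = 0.01
    class_split_time: float = 6.0
    balanced_freq: float = 0.5
    allele_bias: float = 1.0
    gamma_shape: float = 1.0
    gamma_scale: float = 1.0
    n_cells: int = 200
    depth_mean: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.balanced_fraction <= 1.0:
            raise ValueError("balanced_fraction must lie in [0, 1]")
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _coalesce(lineages, t0, rng, t_stop=None):
    """Coalesce (mask, size, birth) lineages from time t0.

    Returns (closed branches [(length, size, mask)], surviving lineages,
    stop time).  When ``t_stop`` is given, open branch segments are
    closed there and the surviving lineages restart at ``t_stop``.
    """
    branches = []
    lineages = list(lineages)
    t = t0
    while len(lineages) > 1:
        k = len(lineages)
        t_next = t + rng.exponential(2.0 / (k * (k - 1)))
        if t_stop is not None and t_next >= t_stop:
            break
        t = t_next
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        mi, si, bi = lineages[i]
        mj, sj, bj = lineages[j]
        branches.append((t - bi, si, mi))
        branches.append((t - bj, sj, mj))
        merged = (mi | mj, si + sj, t)
        lineages[min(i, j)] = merged
        del lineages[max(i, j)]
    if t_stop is not None:
        out = []
        for m, s, b in lineages:
            branches.append((t_stop - b, s, m))
            out.append((m, s, t_stop))
        return branches, out, t_stop
    return branches, lineages, t


def _neutral_branches(n: int, rng) -> list:
    start = [(1 << i, 1, 0.0) for i in range(n)]
    branches, _, _ = _coalesce(start, 0.0, rng)
    return branches


def _balanced_branches(n: int, freq: float, split_time: float, rng):
    """Two-class structured genealogy; returns (branches, class-B mask)."""
    n_b = int(round(freq * n))
    n_a = n - n_b
    if n_a < 1 or n_b < 1:
        raise ValueError("focal-class frequencies must lie strictly in (0, 1)")
    lin_a = [(1 << i, 1, 0.0) for i in range(n_a)]
    lin_b = [(1 << i, 1, 0.0) for i in range(n_a, n)]
    br_a, surv_a, _ = _coalesce(lin_a, 0.0, rng, t_stop=split_time)
    br_b, surv_b, _ = _coalesce(lin_b, 0.0, rng, t_stop=split_time)
    br_anc, _, _ = _coalesce(surv_a + surv_b, split_time, rng)
    mask_b = 0
    for i in range(n_a, n):
        mask_b |= 1 << i
    return br_a + br_b + br_anc, mask_b


def _mutate_branches(branches, theta: float, rng):
    """Poisson mutations per branch -> (derived counts, masks)."""
    lengths = np.array([b[0] for b in branches])
    muts = rng.poisson(theta / 2.0 * lengths)
    counts, masks = [], []
    for (length, size, mask), m in zip(branches, muts):
        for _ in range(int(m)):
            counts.append(size)
            masks.append(mask)
    return counts, masks


def _masks_to_matrix(
    n: int, masks, window_bp: int, rng, focal_mask=None
) -> HaplotypeMatrix:
    """Lay mutation masks onto uniform unique positions in the window."""
    s = len(masks)
    n_extra = 1 if focal_mask is not None else 0
    center = window_bp // 2
    pool = np.delete(np.arange(window_bp), center) if n_extra else np.arange(window_bp)
    pos = rng.choice(pool, size=min(s, pool.size), replace=False)
    masks = list(masks[: pos.size])
    pos = list(pos)
    if focal_mask is not None:
        pos.append(center)
        masks.append(focal_mask)
    if not masks:
        return HaplotypeMatrix(
            np.zeros((n, 0), dtype=np.int8), np.empty(0, dtype=np.int64), chrom="sim"
        )
    order = np.argsort(pos)
    pos = np.array(pos)[order]
    cols = []
    for m in np.array(masks, dtype=object)[order]:
        col = np.frombuffer(
            int(m).to_bytes((n + 7) // 8, "little"), dtype=np.uint8
        )
        cols.append(np.unpackbits(col, bitorder="little", count=n))
    alleles = np.array(cols, dtype=np.int8).T
    focal_index = None
    if focal_mask is not None:
        focal_index = int(np.searchsorted(pos, center))
    return HaplotypeMatrix(alleles, pos, chrom="sim", focal_index=focal_index)


def simulate_neutral_haplotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> HaplotypeMatrix:
    """Infinite-sites haplotypes from a standard neutral coalescent."""
    if config.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if config.theta < 0:
        raise ValueError("theta must be >= 0")
    rng = config.rng() if rng is None else rng
    n = config.n_haplotypes
    branches = _neutral_branches(n, rng)
    _, masks = _mutate_branches(branches, config.theta, rng)
    return _masks_to_matrix(n, masks, config.window_bp, rng)


def simulate_balanced_haplotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> HaplotypeMatrix:
    """Haplotypes carrying an old balanced polymorphism at the window center.

    The focal-SNP column (flagged via ``focal_index``) separates the two
    allelic classes; their lineages coalesce only deeper than
    ``class_split_time``.
    """
    if config.class_split_time <= 0:
        raise ValueError("class_split_time must be positive")
    rng = config.rng() if rng is None else rng
    n = config.n_haplotypes
    branches, mask_b = _balanced_branches(
        n, config.balanced_freq, config.class_split_time, rng
    )
    _, masks = _mutate_branches(branches, config.theta, rng)
    return _masks_to_matrix(n, masks, config.window_bp, rng, focal_mask=mask_b)


def _summary_counts(branches, theta, rng):
    lengths = np.array([b[0] for b in branches])
    sizes = np.array([b[1] for b in branches])
    muts = rng.poisson(theta / 2.0 * lengths)
    return np.repeat(sizes, muts)


def neutral_d_values(config: SimConfig, reps: int, rng=None) -> np.ndarray:
    """Tajima's D for ``reps`` neutral replicates (summary-level, fast)."""
    rng = config.rng() if rng is None else rng
    n = config.n_haplotypes
    start = [(0, 1, 0.0) for _ in range(n)]
    out = np.empty(reps)
    for r in range(reps):
        branches, _, _ = _coalesce(start, 0.0, rng)
        counts = _summary_counts(branches, config.theta, rng)
        out[r] = tajima_d_from_counts(n, counts).D
    return out


def balanced_d_values(config: SimConfig, reps: int, rng=None) -> np.ndarray:
    """Tajima's D for replicates carrying a planted balanced polymorphism."""
    rng = config.rng() if rng is None else rng
    n = config.n_haplotypes
    out = np.empty(reps)
    for r in range(reps):
        branches, mask_b = _balanced_branches(
            n, config.balanced_freq, config.class_split_time, rng
        )
        counts = _summary_counts(branches, config.theta, rng)
        n_b = int(round(config.balanced_freq * n))
        counts = np.append(counts, n_b)  # the focal site itself
        out[r] = tajima_d_from_counts(n, counts).D
    return out


def simulate_d_scan(
    config: SimConfig, n_neutral: int, n_balanced: int, rng=None
) -> pd.DataFrame:
    """A mixed scan: D per locus with the planted-balanced truth label."""
    rng = config.rng() if rng is None else rng
    d_n = neutral_d_values(config, n_neutral, rng)
    d_b = balanced_d_values(config, n_balanced, rng)
    return pd.DataFrame(
        {
            "tajima_d": np.concatenate([d_n, d_b]),
            "is_balanced_truth": np.concatenate(
                [np.zeros(n_neutral, bool), np.ones(n_balanced, bool)]
            ),
        }
    )


def simulate_allelic_reads(
    het_sites, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Allele-resolved read counts at heterozygous sites.

    Per-site depth ~ Poisson(depth_mean); the reference-allele count is
    binomial with success probability allele_bias/(1 + allele_bias), so
    allele_bias is the expected ref/alt read ratio.
    """
    if config.allele_bias <= 0:
        raise ValueError("allele_bias must be positive")
    rng = config.rng() if rng is None else rng
    ids = list(het_sites)
    depth = rng.poisson(config.depth_mean, size=len(ids))
    p = config.allele_bias / (1.0 + config.allele_bias)
    ref = rng.binomial(depth, p)
    return pd.DataFrame(
        {"snp_id": ids, "ref_reads": ref, "alt_reads": depth - ref}
    )


def simulate_single_cell_expression(
    params: nm.NoiseModelParams,
    zygosity: str,
    n_cells: int,
    rng: np.random.Generator | int | None = None,
    n_genes: int = 1,
    uncoupled: bool = False,
):
    """Gamma-mixed Poisson mRNA counts per cell for one zygosity.

    Each cell draws a TF level T ~ Gamma(a, b).  A homozygote
    transcribes at f(T/lambda_bar) with lambda_bar mean-matched to the
    heterozygote; a heterozygote applies its two dissociation constants
    to the same draw, at g_lambda(T).  Counts are Poisson with mean
    (alpha_m/gamma_m) * rate.  ``uncoupled=True`` instead gives the two
    heterozygote alleles independent TF draws (a stronger-buffering
    variant kept as an exploratory knob).

    Returns an (n_genes, n_cells) integer array.
    """
    rng = np.random.default_rng(rng)
    rate = nm.rate_f(params)
    T = rng.gamma(params.a, params.b, size=(n_genes, n_cells))
    if zygosity == "het":
        if uncoupled:
            T2 = rng.gamma(params.a, params.b, size=(n_genes, n_cells))
            g = 0.5 * (rate(T) + rate(T2 / params.lam))
        else:
            g = rate.g(T, params.lam)
    elif zygosity == "hom":
        lam_bar = nm.match_mean(rate, params.lam, params.a, params.b)
        g = rate(T / lam_bar)
    else:
        raise ValueError("zygosity must be 'het' or 'hom'")
    mean = params.alpha_m / params.gamma_m * g
    if np.any(mean <= 0):
        raise ValueError("non-positive transcription rates")
    return rng.poisson(mean)


def simulate_single_cell_atac(
    config: SimConfig,
    n_peaks: int = 200,
    peak_groups=None,
    group_extrinsic_var=None,
    rng: np.random.Generator | None = None,
):
    """Peaks x cells ATAC fragment counts with group-shared extrinsic noise.

    Per-cell depth is gamma-heterogeneous around ``depth_mean * n_peaks
    fraction``; each peak group gets one gamma extrinsic factor per cell
    (mean 1, variance per ``group_extrinsic_var``), shared by all its
    peaks, so cell-to-cell variability in group accessibility exceeds
    the depth-only Poisson baseline in proportion to that variance.

    Returns (counts [n_peaks x n_cells], peak_groups, cell_depth_factor).
    """
    rng = config.rng() if rng is None else rng
    if peak_groups is None:
        peak_groups = np.zeros(n_peaks, dtype=int)
    peak_groups = np.asarray(peak_groups)
    n_groups = int(peak_groups.max()) + 1
    if group_extrinsic_var is None:
        group_extrinsic_var = np.zeros(n_groups)
    group_extrinsic_var = np.asarray(group_extrinsic_var, dtype=float)
    n_cells = config.n_cells
    depth_factor = rng.gamma(4.0, 0.25, size=n_cells)  # mean 1
    weights = rng.uniform(0.5, 1.5, size=n_peaks)
    weights /= weights.sum()
    extr = np.ones((n_groups, n_cells))
    for g in range(n_groups):
        v = group_extrinsic_var[g]
        if v > 0:
            extr[g] = rng.gamma(1.0 / v, v, size=n_cells)
    lam = (
        config.depth_mean
        * n_peaks
        * weights[:, None]
        * depth_factor[None, :]
        * extr[peak_groups, :]
    )
    counts = rng.poisson(lam)
    return counts, peak_groups, depth_factor
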