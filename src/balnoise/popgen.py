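"""Core diversity and differentiation statistics.

Implements the window statistics used by the balancing-selection scan:
nucleotide diversity pi, Watterson's theta_s, Tajima's D, haplogroup pi
profiles around a focal SNP, Fst = 1 - Hs/Ht, LD r^2 and the exact
Hardy-Weinberg test.

pi follows the frequency form ``pi = n/(n-1) * sum_i 2 p_i q_i`` where
``p_i`` is the derived-allele frequency at segregating site i; this is
identical to the mean pairwise Hamming distance over all C(n, 2)
haplotype pairs.  Tajima's D uses the standard 1989 normalizing
constants with ``Var(pi - theta_s) = e1*S + e2*S*(S-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .haplotypes import HaplotypeMatrix

__all__ = [
    "TajimaResult",
    "FstResult",
    "HaplogroupProfile",
    "site_diversity",
    "tajimas_d",
    "tajima_d_from_counts",
    "haplogroup_pi_profile",
    "fst",
    "ld_r2",
    "hwe_exact_test",
]


@dataclass
class TajimaResult:
    pi: float
    theta_s: float
    D: float
    S: int
    window: tuple[int, int] | None = None
    defined: bool = True


@dataclass
class FstResult:
    Hs: float
    Ht: float
    fst: float
    defined: bool = True


@dataclass
class HaplogroupProfile:
    """pi within and between focal-allele haplogroups in sliding windows."""

    window_centers: np.ndarray
    pi_between: np.ndarray
    pi_within: np.ndarray
    window_bp: int = 500


@lru_cache(maxsize=1024)
def tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) of the D variance Var = e1*S + e2*S*(S-1)."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return tajima_constants(n)[0]


def site_diversity(matrix: HaplotypeMatrix) -> tuple[float, float]:
    """Return (pi, theta_s) for all segregating sites of the matrix."""
    n = matrix.n
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    if matrix.n_sites == 0:
        return 0.0, 0.0
    p = matrix.derived_freqs()
    pi = n / (n - 1.0) * float(np.sum(2.0 * p * (1.0 - p)))
    theta_s = matrix.n_sites / harmonic(n)
    return pi, theta_s


def tajima_d_from_counts(
    n: int, derived_counts: np.ndarray, window: tuple[int, int] | None = None
) -> TajimaResult:
    """Tajima's D from the per-site derived-allele counts of a sample of n."""
    counts = np.asarray(derived_counts)
    counts = counts[(counts > 0) & (counts < n)]
    S = int(counts.size)
    a1, e1, e2 = tajima_constants(n)
    if S == 0:
        return TajimaResult(0.0, 0.0, np.nan, 0, window, defined=False)
    p = counts / n
    pi = n / (n - 1.0) * float(np.sum(2.0 * p * (1.0 - p)))
    theta_s = S / a1
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return TajimaResult(pi, theta_s, np.nan, S, window, defined=False)
    return TajimaResult(pi, theta_s, (pi - theta_s) / np.sqrt(var), S, window)


def tajimas_d(
    matrix: HaplotypeMatrix, window: tuple[int, int] | None = None
) -> TajimaResult:
    """Tajima's D over the sites of ``matrix`` (optionally a sub-window).

    D = (pi - theta_s) / sqrt(e1*S + e2*S*(S-1)).  Positive D reflects an
    excess of intermediate-frequency variants (balancing-selection-like);
    negative D an excess of rare variants.
    """
    m = matrix if window is None else matrix.window(*window)
    if m is None:
        return TajimaResult(0.0, 0.0, np.nan, 0, window, defined=False)
    return tajima_d_from_counts(m.n, m.derived_counts(), window)


def _pairwise_pi_between(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Mean pairwise difference count between two haplotype classes."""
    return float(np.sum(freq_a * (1 - freq_b) + freq_b * (1 - freq_a)))


def _pairwise_pi_within(freq: np.ndarray, n: int) -> float:
    return n / (n - 1.0) * float(np.sum(2.0 * freq * (1.0 - freq)))


def haplogroup_pi_profile(
    matrix: HaplotypeMatrix,
    focal_index: int | None = None,
    window_bp: int = 500,
    step: int = 100,
) -> HaplogroupProfile:
    """pi within and between haplogroups defined by the focal-SNP allele.

    Haplotypes are partitioned by the allele they carry at the focal
    site.  In sliding windows, ``pi_between`` is the mean pairwise
    difference count over all cross-class pairs and ``pi_within`` the
    pair-count-weighted mean over the two within-class pair sets.
    Elevated between- relative to within-haplogroup diversity around the
    focal SNP is the hallmark of an old balanced polymorphism whose
    allelic classes accumulated their own neutral mutations.
    """
    if focal_index is None:
        focal_index = matrix.focal_index
    if focal_index is None:
        raise ValueError("no focal site given")
    focal_col = matrix.alleles[:, focal_index]
    in_b = focal_col == 1
    n_a, n_b = int((~in_b).sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both haplogroups must be non-empty")

    lo = int(matrix.positions.min())
    hi = int(matrix.positions.max())
    centers = np.arange(lo + window_bp // 2, max(hi - window_bp // 2, lo + window_bp // 2) + 1, step)
    pi_between = np.zeros(centers.size)
    pi_within = np.zeros(centers.size)
    alleles_a = matrix.alleles[~in_b]
    alleles_b = matrix.alleles[in_b]
    pairs_a = n_a * (n_a - 1) / 2.0
    pairs_b = n_b * (n_b - 1) / 2.0
    for j, c in enumerate(centers):
        sl = matrix.site_window_slice(c - window_bp // 2, c + window_bp // 2)
        if sl.stop <= sl.start:
            continue
        fa = alleles_a[:, sl].mean(axis=0)
        fb = alleles_b[:, sl].mean(axis=0)
        pi_between[j] = _pairwise_pi_between(fa, fb)
        w_sum = 0.0
        p_sum = 0.0
        if n_a >= 2:
            w_sum += pairs_a * _pairwise_pi_within(fa, n_a)
            p_sum += pairs_a
        if n_b >= 2:
            w_sum += pairs_b * _pairwise_pi_within(fb, n_b)
            p_sum += pairs_b
        pi_within[j] = w_sum / p_sum if p_sum > 0 else np.nan
    return HaplogroupProfile(centers, pi_between, pi_within, window_bp)


def fst(frequencies, weights=None) -> FstResult:
    """Fst = 1 - Hs/Ht from per-population derived-allele frequencies.

    Hs is the (weighted) mean subpopulation expected heterozygosity
    2*p*q; Ht = 2*pbar*qbar with pbar the weighted mean frequency.
    """
    p = np.asarray(frequencies, dtype=float)
    if p.size < 2:
        raise ValueError("need >= 2 populations")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    hs = float(np.sum(w * 2.0 * p * (1.0 - p)))
    pbar = float(np.sum(w * p))
    ht = 2.0 * pbar * (1.0 - pbar)
    if ht == 0.0:
        return FstResult(hs, ht, np.nan, defined=False)
    return FstResult(hs, ht, 1.0 - hs / ht)


def ld_r2(genotypes_a, genotypes_b) -> float:
    """Squared correlation of allele dosages between two sites.

    Accepts diploid dosages (0/1/2) or phased haploid alleles (0/1) for
    the same individuals/chromosomes; for phased data the dosage
    correlation coincides with the haplotype-frequency r^2
    D^2/(p1 q1 p2 q2).  Returns NaN for monomorphic input.
    """
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have the same length")
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _log_het_probs(n_aa: int, n_ab: int, n_bb: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional log-probabilities of every possible heterozygote count.

    Conditions on the sample size and the minor-allele count; possible
    heterozygote counts share the parity of the minor-allele count.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_minor = min(n_a, 2 * n - n_a)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_homr = (n_minor - hets) // 2
    n_homc = n - hets - n_homr
    # P(het | n, n_minor) via the standard hypergeometric-type formula
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_homr + 1)
        - gammaln(n_homc + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(2 * n - n_minor + 1))
    )
    logp = logp - np.max(logp)
    probs = np.exp(logp)
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the probabilities no greater than that of the
    observed configuration.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one individual")
    hets, probs = _log_het_probs(n_aa, n_ab, n_bb)
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))
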