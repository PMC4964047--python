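"""Position weight matrices with exact p-value thresholds, and allele scanning.

A PFM (count matrix) becomes a log-odds PWM against a background
nucleotide model with a pseudocount of 0.25 per cell.  Scores are
quantized on a fixed lattice (1e-3 score units), which makes the null
score distribution of a random background word exactly computable by
dynamic programming: the per-position score distributions are convolved
and the threshold for a tail probability p is the smallest achievable
score s with P(score >= s) <= p.  Because the discrete null has finite
granularity, a short or weak motif may admit no threshold at small p —
the scanner then returns no hits, matching an exhaustive-enumeration
definition of the p-value.

Allele scanning slides every window of the motif width over the +/-20bp
flank of each allele, on both strands; a TF "binds" an allele when any
window reaches the threshold.  The motif-divergence score of a SNP is
(#TFs specific to allele 1 + #TFs specific to allele 2) / #TFs common
to both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PWM", "MotifDivergence", "pwm_threshold", "scan_sequence", "scan_alleles"]

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

LATTICE = 1e-3  # score quantum of the log-odds matrices


class PWM:
    """Log-odds position weight matrix over {A, C, G, T}.

    Parameters
    ----------
    counts
        PFM of shape (4, width), rows in A, C, G, T order.
    name
        Motif / TF identifier.
    background
        Background nucleotide frequencies (must sum to 1).
    pseudocount
        Added to every PFM cell before normalization.
    """

    def __init__(self, counts, name: str = "", background=None, pseudocount: float = 0.25):
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A, C, G, T)")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if abs(background.sum() - 1.0) > 1e-9 or np.any(background <= 0):
            raise ValueError("background frequencies must be positive and sum to 1")
        self.name = name
        self.counts = counts
        self.background = background
        probs = counts + pseudocount
        probs /= probs.sum(axis=0, keepdims=True)
        logodds = np.log2(probs / background[:, None])
        # quantize on the lattice so DP p-values are exact for the
        # matrix actually used in scanning
        self.int_matrix = np.round(logodds / LATTICE).astype(np.int64)
        self.matrix = self.int_matrix * LATTICE
        self._threshold_cache: dict[float, float] = {}

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.int_matrix.max(axis=0).sum() * LATTICE)

    @property
    def min_score(self) -> float:
        return float(self.int_matrix.min(axis=0).sum() * LATTICE)

    def score(self, word: str) -> float:
        """Log-odds score of one width-length word (no ambiguity codes)."""
        if len(word) != self.width:
            raise ValueError("word length must equal motif width")
        idx = [_INDEX[c] for c in word.upper()]
        return float(self.int_matrix[idx, range(self.width)].sum() * LATTICE)

    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores, probabilities) of a background word, exactly.

        Convolves per-position distributions on the integer lattice.
        """
        offset = int(self.int_matrix.min(axis=0).sum())
        dist = np.array([1.0])
        for j in range(self.width):
            col = self.int_matrix[:, j]
            lo = col.min()
            vec = np.zeros(col.max() - lo + 1)
            for base in range(4):
                vec[col[base] - lo] += self.background[base]
            dist = np.convolve(dist, vec)
        scores = (np.arange(dist.size) + offset) * LATTICE
        return scores, dist

    def threshold(self, p: float = 1e-4) -> float:
        """Smallest achievable score s with P(score >= s | background) <= p.

        Returns +inf when even the best word is more probable than p
        (no window can then be called a hit at this stringency).
        """
        if not 0.0 < p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if p in self._threshold_cache:
            return self._threshold_cache[p]
        scores, probs = self.score_distribution()
        tail = np.cumsum(probs[::-1])[::-1]
        ok = np.flatnonzero((tail <= p * (1.0 + 1e-12)) & (probs > 0))
        thr = float(scores[ok[0]]) if ok.size else np.inf
        self._threshold_cache[p] = thr
        return thr


def pwm_threshold(pwm: PWM, p: float = 1e-4) -> float:
    return pwm.threshold(p)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_sequence(seq: str, pwm: PWM, p: float = 1e-4, both_strands: bool = True):
    """Best score over all valid windows (and strands); None if no window.

    Windows containing non-ACGT characters are skipped.
    """
    thr = pwm.threshold(p)
    w = pwm.width
    best = None
    strands = [seq.upper()]
    if both_strands:
        strands.append(reverse_complement(seq.upper()))
    for s in strands:
        for i in range(len(s) - w + 1):
            word = s[i : i + w]
            if any(c not in _INDEX for c in word):
                continue
            sc = pwm.score(word)
            if best is None or sc > best:
                best = sc
    hit = best is not None and best >= thr
    return hit, best


@dataclass
class MotifDivergence:
    """Allele-specific vs shared TF binding at one SNP."""

    snp_id: str
    tfs_allele1_only: frozenset
    tfs_allele2_only: frozenset
    tfs_common: frozenset

    @property
    def score(self) -> float:
        """(#specific TFs)/(#common TFs); NaN when no TF binds both alleles."""
        n_spec = len(self.tfs_allele1_only) + len(self.tfs_allele2_only)
        if not self.tfs_common:
            return np.nan
        return n_spec / len(self.tfs_common)


def scan_alleles(
    snp_id: str, seq_allele1: str, seq_allele2: str, pwms, p: float = 1e-4
) -> MotifDivergence:
    """Scan both allele flanks with every PWM; classify TFs by binding.

    The two sequences must be equal-length flanks differing only at the
    variant position.  A PWM binds an allele when any window on either
    strand reaches its exact p-value threshold.
    """
    if len(seq_allele1) != len(seq_allele2):
        raise ValueError("allele flanks must have equal length")
    only1, only2, common = set(), set(), set()
    for pwm in pwms:
        h1, _ = scan_sequence(seq_allele1, pwm, p)
        h2, _ = scan_sequence(seq_allele2, pwm, p)
        if h1 and h2:
            common.add(pwm.name)
        elif h1:
            only1.add(pwm.name)
        elif h2:
            only2.add(pwm.name)
    return MotifDivergence(
        snp_id, frozenset(only1), frozenset(only2), frozenset(common)
    )
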