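"""Phased haplotype matrices: the substrate for all diversity statistics.

A :class:`HaplotypeMatrix` holds ``n`` phased haplotypes typed at ``S``
biallelic segregating sites.  Alleles are encoded 0 (ancestral) / 1
(derived); positions are 0-based and strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeMatrix"]


@dataclass
class HaplotypeMatrix:
    """n x S binary matrix of phased haplotypes at segregating sites.

    Parameters
    ----------
    alleles
        Array of shape ``(n, S)`` with entries in {0, 1}; 0 is the
        ancestral allele.
    positions
        Strictly increasing 0-based site coordinates, length ``S``.
    chrom
        Chromosome / contig identifier.
    focal_index
        Optional column index of a focal SNP (e.g. the planted balanced
        polymorphism); tracked through the non-segregating-site drop.

    Non-segregating columns are removed on construction.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "chr1"
    focal_index: int | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (n x S) matrix")
        if self.alleles.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match number of sites")
        counts = self.alleles.sum(axis=0)
        seg = (counts > 0) & (counts < self.alleles.shape[0])
        if not seg.all():
            keep = np.flatnonzero(seg)
            if self.focal_index is not None:
                if not seg[self.focal_index]:
                    raise ValueError("focal site is not segregating")
                self.focal_index = int(np.searchsorted(keep, self.focal_index))
            self.alleles = self.alleles[:, keep]
            self.positions = self.positions[keep]
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Derived-allele count per site."""
        return self.alleles.sum(axis=0)

    def derived_freqs(self) -> np.ndarray:
        return self.derived_counts() / self.n

    def window(self, start: int, end: int) -> "HaplotypeMatrix | None":
        """Sub-matrix of sites with ``start <= pos < end``.

        Returns ``None`` when no site in the window segregates.
        """
        lo, hi = np.searchsorted(self.positions, [start, end])
        if hi <= lo:
            return None
        focal = None
        if self.focal_index is not None and lo <= self.focal_index < hi:
            focal = self.focal_index - lo
        return HaplotypeMatrix(
            self.alleles[:, lo:hi], self.positions[lo:hi], self.chrom, focal
        )

    def site_window_slice(self, start: int, end: int) -> slice:
        lo, hi = np.searchsorted(self.positions, [start, end])
        return slice(int(lo), int(hi))
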