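"""Phased haplotype matrices over ordered genomic sites.

A :class:`HaplotypeBlock` is the substrate of every diversity computation in
this package: a matrix of small-integer allele codes, one row per haplotype,
one column per site, with strictly increasing 0-based positions.  Missing
alleles (unphased or uncalled genotypes) carry the distinguished code
:data:`MISSING`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Allele code marking a missing/unphased allele.
MISSING: int = -1


@dataclass
class HaplotypeBlock:
    """Matrix of phased allele codes over ordered sites.

    Parameters
    ----------
    positions
        0-based genomic coordinates, strictly increasing, one per site.
    alleles
        ``(n_haplotypes, n_sites)`` integer matrix of allele codes.
        Non-missing codes at a site are ``0..k-1`` for a site with ``k``
        alleles; missing entries are :data:`MISSING`.
    haplotype_ids
        Opaque labels, one per row.  Defaults to ``hap0..hapn``.
    """

    positions: np.ndarray
    alleles: np.ndarray
    haplotype_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (n_haplotypes x n_sites) matrix")
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("positions and allele columns disagree in length")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.shape[0] < 1:
            raise ValueError("need at least one haplotype")
        if not self.haplotype_ids:
            self.haplotype_ids = [f"hap{i}" for i in range(self.alleles.shape[0])]
        if len(self.haplotype_ids) != self.alleles.shape[0]:
            raise ValueError("haplotype_ids and allele rows disagree in length")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def site_index(self, position: int) -> int:
        """Column index of a genomic position; raises if absent."""
        i = int(np.searchsorted(self.positions, position))
        if i >= self.positions.size or self.positions[i] != position:
            raise KeyError(f"position {position} not in block")
        return i

    def subset_haplotypes(self, rows: np.ndarray) -> "HaplotypeBlock":
        """New block restricted to the given haplotype rows."""
        rows = np.asarray(rows)
        return HaplotypeBlock(
            positions=self.positions,
            alleles=self.alleles[rows],
            haplotype_ids=[self.haplotype_ids[i] for i in np.atleast_1d(rows)],
        )

    def subset_region(self, start: int, stop: int) -> "HaplotypeBlock":
        """New block restricted to positions in ``[start, stop)``."""
        lo = int(np.searchsorted(self.positions, start, side="left"))
        hi = int(np.searchsorted(self.positions, stop, side="left"))
        return HaplotypeBlock(
            positions=self.positions[lo:hi],
            alleles=self.alleles[:, lo:hi],
            haplotype_ids=list(self.haplotype_ids),
        )
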