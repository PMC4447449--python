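"""Haplotype-diversity estimators of the population mutation parameter.

Two estimators of θ = 4Nμ (per base pair) are computed from a window of
sites around a focal variant, separately for each haplotype class:

* θ₁ = log(1−P) / log(q), where P is the proportion of polymorphic sites in
  the window and q is the smallest non-zero allele frequency of the
  haplotype sample (1/n for n haplotypes).
* θ₂ = ½·(m(1−m)/v − 1), the beta parameter of Wright's stationary allele
  frequency law, where m and v are the mean and variance of the window's
  *folded* allele frequency set.

Folding removes allele-label orientation: each frequency f is mapped to
min(f, 1−f), the mapped values are sorted ascending, and alternate ranks
are reflected back to 1−f so that the folded set is symmetric about 0.5
("ordered and evenly assigned to either f or 1−f").  Monomorphic window
sites contribute frequency 0 before folding; under the alternation they
become an even mixture of 0s and 1s, which calibrates θ₂ to the stationary
beta law (a fully monomorphic window has m = 0.5, v = 0.25, θ₂ = 0).

The public entry points operate on :class:`~thetacall.block.HaplotypeBlock`
objects; ``*_from_counts`` variants operate directly on integer allele-count
arrays and are the vectorized path used by the Wright–Fisher simulator.
Both paths are exact and are tested for equivalence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .block import MISSING, HaplotypeBlock
from .errors import (
    DomainError,
    InsufficientHaplotypesError,
    UndefinedEstimateError,
    UndefinedWindowError,
)

__all__ = [
    "WindowSummary",
    "ThetaEstimate",
    "fold_frequencies",
    "summarize_window",
    "estimate_theta1",
    "estimate_theta2",
    "folded_moments_from_counts",
    "summary_from_counts",
]


@dataclass(frozen=True)
class WindowSummary:
    """Per-haplotype-class window quantities feeding the θ formulas."""

    n_sites: int
    n_polymorphic: int
    P: float
    q: float
    m: float
    v: float
    n_haplotypes: int


@dataclass(frozen=True)
class ThetaEstimate:
    """A θ value together with the window summary it came from."""

    method: str  # "theta1" | "theta2"
    value: float
    window_summary: WindowSummary


def fold_frequencies(freqs) -> np.ndarray:
    """Fold allele frequencies symmetrically about 0.5.

    Each input f is mapped to min(f, 1−f); the mapped values are sorted
    ascending and entries at odd 0-based ranks are reflected to 1−f.  The
    result is returned in sorted-fold order.  The output multiset does not
    depend on the input order (ties in the sort only permute equal values).

    Raises
    ------
    DomainError
        If any frequency lies outside [0, 1].
    """
    f = np.asarray(freqs, dtype=float)
    if f.size and (np.min(f) < 0.0 or np.max(f) > 1.0):
        raise DomainError("allele frequencies must lie in [0, 1]")
    g = np.minimum(f, 1.0 - f)
    out = np.sort(g, kind="stable")
    out[1::2] = 1.0 - out[1::2]
    return out


def _window_columns(block: HaplotypeBlock, focal_position: int, radius: int) -> np.ndarray:
    """Column indices within ±radius of the focal position, focal excluded."""
    lo = int(np.searchsorted(block.positions, focal_position - radius, side="left"))
    hi = int(np.searchsorted(block.positions, focal_position + radius, side="right"))
    cols = np.arange(lo, hi)
    return cols[block.positions[cols] != focal_position]


def summarize_window(
    block: HaplotypeBlock,
    focal_position: int,
    radius: int,
    include_monomorphic: bool = True,
    assume_covered_span: bool = False,
) -> WindowSummary:
    """Summarize diversity of a haplotype class around a focal variant.

    The block must already be subset to one allele class of the focal
    variant; the focal position itself is excluded from the window.  A
    site's allele frequency is the frequency of the non-reference (non-zero)
    allele code among non-missing haplotypes; sites entirely missing in the
    subset are dropped from the site count.

    ``include_monomorphic=False`` restricts the folded frequency set (hence
    m and v) to polymorphic sites; P is unaffected.  The default includes
    monomorphic sites at frequency 0, which calibrates θ₂ to the stationary
    law.

    ``assume_covered_span=True`` treats the block as listing only the
    *variant* positions of a fully covered span (the situation for a block
    read from a VCF): every window bp without a record is an implicit
    monomorphic site, so the denominator is the window's 2·radius bp and
    implicit sites contribute frequency 0 before folding.  The default
    counts only the block's own positions, for blocks that carry every
    site (e.g. full simulator output).
    """
    n = block.n_haplotypes
    if n < 2:
        raise InsufficientHaplotypesError("need at least 2 haplotypes in the class")
    cols = _window_columns(block, focal_position, radius)
    if cols.size == 0 and not assume_covered_span:
        raise UndefinedWindowError("no sites within the window")
    sub = block.alleles[:, cols]
    present = sub != MISSING
    n_present = present.sum(axis=0)
    usable = n_present > 0
    if not np.any(usable) and not assume_covered_span:
        raise UndefinedWindowError("every window site is entirely missing")
    sub = sub[:, usable]
    present = present[:, usable]
    n_present = n_present[usable]

    nonref = np.where(present, sub != 0, False).sum(axis=0)
    freqs = nonref / n_present if sub.size else np.empty(0)
    # polymorphic: >= 2 distinct non-missing codes at the site
    poly = np.zeros(sub.shape[1], dtype=bool)
    for j in range(sub.shape[1]):
        codes = sub[present[:, j], j]
        poly[j] = np.unique(codes).size > 1

    n_sites = int(sub.shape[1])
    n_poly = int(poly.sum())
    if assume_covered_span:
        implicit = 2 * radius - n_sites
        if implicit < 0:
            implicit = 0
        n_sites += implicit
        if include_monomorphic and implicit:
            freqs = np.concatenate([freqs, np.zeros(implicit)])
    folded = fold_frequencies(freqs if include_monomorphic else freqs[poly])
    if folded.size:
        m = float(folded.mean())
        v = float(folded.var())  # population variance (divide by n)
    else:
        m, v = math.nan, math.nan
    return WindowSummary(
        n_sites=n_sites,
        n_polymorphic=n_poly,
        P=n_poly / n_sites,
        q=1.0 / n,
        m=m,
        v=max(v, 0.0) if not math.isnan(v) else v,
        n_haplotypes=n,
    )


def estimate_theta1(summary: WindowSummary) -> ThetaEstimate:
    """θ₁ = log(1−P)/log(q); exactly 0 when the window is monomorphic.

    A window polymorphic at every site (P = 1, possible only in degenerate
    tiny windows) yields +inf rather than an error, so that the caller can
    still compare classes (two infinite estimates tie into a no-call).
    """
    if not (0.0 < summary.q < 1.0):
        raise DomainError(f"q must lie in (0, 1); got {summary.q}")
    if not (0.0 <= summary.P <= 1.0):
        raise DomainError(f"P must lie in [0, 1]; got {summary.P}")
    if summary.P == 0.0:
        value = 0.0
    elif summary.P == 1.0:
        value = math.inf
    else:
        value = math.log1p(-summary.P) / math.log(summary.q)
    return ThetaEstimate("theta1", value, summary)


def estimate_theta2(summary: WindowSummary) -> ThetaEstimate:
    """θ₂ = ½·(m(1−m)/v − 1); undefined (signalled) when v = 0."""
    if math.isnan(summary.v) or summary.v == 0.0:
        raise UndefinedEstimateError("window folded-frequency variance is zero")
    value = 0.5 * (summary.m * (1.0 - summary.m) / summary.v - 1.0)
    # v <= m(1-m) for any distribution on [0,1]; clip float round-off only
    return ThetaEstimate("theta2", max(value, 0.0), summary)


# ---------------------------------------------------------------------------
# Count-based fast path (exact; used by the simulator's inner loop)
# ---------------------------------------------------------------------------

def folded_moments_from_counts(counts: np.ndarray, n: int) -> tuple[float, float]:
    """Mean and population variance of the folded-alternated frequency set.

    ``counts`` holds, per window site, the number of haplotypes (out of
    ``n``) carrying the counted allele.  Exploits that the alternation rule
    affects only which *rank* is reflected: within a run of equal folded
    values, the reflected multiplicity depends only on the run's start-rank
    parity, so the moments follow from a bincount without sorting.
    """
    k = np.minimum(counts, n - counts)
    b = np.bincount(k, minlength=n // 2 + 1)
    starts = np.concatenate(([0], np.cumsum(b)[:-1]))
    n_odd = (b + (starts & 1)) // 2
    n_even = b - n_odd
    vals = np.arange(b.size) / n
    s1 = float(np.sum(n_even * vals + n_odd * (1.0 - vals)))
    s2 = float(np.sum(n_even * vals * vals + n_odd * (1.0 - vals) ** 2))
    w = counts.size
    m = s1 / w
    v = s2 / w - m * m
    return m, max(v, 0.0)


def summary_from_counts(counts: np.ndarray, n: int) -> WindowSummary:
    """WindowSummary from per-site allele counts of a haplotype class."""
    if n < 2:
        raise InsufficientHaplotypesError("need at least 2 haplotypes in the class")
    counts = np.asarray(counts)
    if counts.size == 0:
        raise UndefinedWindowError("no sites within the window")
    poly = int(np.count_nonzero((counts > 0) & (counts < n)))
    m, v = folded_moments_from_counts(counts, n)
    return WindowSummary(
        n_sites=int(counts.size),
        n_polymorphic=poly,
        P=poly / counts.size,
        q=1.0 / n,
        m=m,
        v=v,
        n_haplotypes=n,
    )
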