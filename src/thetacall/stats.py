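"""Genome-evolution statistics over ancestral-annotated variants.

Once each variant's ancestral allele is known, substitutions acquire a
direction (ancestral → derived) and indels become insertions or deletions
of derived sequence.  This module computes the descriptive statistics used
to characterize genome evolution:

* directed substitution tables over the 12 ordered base pairs (strand is
  not complemented: A→G and T→C are distinct cells);
* the transitions fraction of all substitutions;
* the AT mutation-rate bias — the composition-normalized ratio of G/C→A/T
  to A/T→G/C substitution rates,
  ``rate = (N_GC→AT / f_GC) / (N_AT→GC / f_AT)``,
  and the equilibrium GC content it implies, ``1 / (1 + rate)``;
* the same bias within derived-allele-frequency bins (a bias that falls
  with frequency diagnoses GC-biased gene conversion);
* deletion-to-insertion count and base ratios and GC proportions,
  overall and stratified by indel size (1..10 bp and >10 bp).

Variants may be given as a pandas DataFrame or a list of
:class:`AnnotatedVariant`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedProportionError

__all__ = [
    "AnnotatedVariant",
    "StatsConfig",
    "SubstitutionTable",
    "IndelTable",
    "substitution_table",
    "transitions_fraction",
    "at_bias_rate",
    "expected_gc",
    "binned_at_bias",
    "indel_table",
    "indel_ratios",
    "binned_deletion_insertion_ratio",
]

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
#: Unordered substitution pairs in conventional table order.
PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G"))
TRANSITION_PAIRS = (("A", "G"), ("C", "T"))
#: Directed types counted toward G/C → A/T and A/T → G/C in the bias rate.
GC_TO_AT = (("G", "A"), ("C", "T"), ("C", "A"), ("G", "T"))
AT_TO_GC = (("A", "G"), ("T", "C"), ("A", "C"), ("T", "G"))

SIZE_CLASSES = tuple(range(1, 11)) + (">10",)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One ancestral-annotated variant.

    For substitutions, ``ancestral`` and ``derived`` are single differing
    bases.  For indels they hold the event sequence: the inserted bases
    (``derived``) for an insertion, the deleted bases (``ancestral``) for a
    deletion.  ``derived_freq`` is the derived-allele frequency in [0, 1].
    """

    kind: str  # "substitution" | "insertion" | "deletion"
    ancestral: str = ""
    derived: str = ""
    derived_freq: float = float("nan")
    length: int | None = None

    @property
    def event_bases(self) -> str:
        return self.derived if self.kind == "insertion" else self.ancestral

    @property
    def event_length(self) -> int:
        return self.length if self.length is not None else len(self.event_bases)


@dataclass(frozen=True)
class StatsConfig:
    """Genome composition and binning used by the bias statistics."""

    f_gc: float = 0.41  # genome GC content
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.f_gc < 1.0):
            raise ValueError("f_gc must lie in (0, 1)")
        if not (0.0 < self.bin_width <= 1.0):
            raise ValueError("bin_width must lie in (0, 1]")


def _as_frame(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    rows = []
    for v in variants:
        rows.append({
            "kind": v.kind, "ancestral": v.ancestral, "derived": v.derived,
            "derived_freq": v.derived_freq, "length": v.event_length,
        })
    df = pd.DataFrame(
        rows, columns=["kind", "ancestral", "derived", "derived_freq", "length"]
    )
    return df


def _gc_count(seq: str) -> int:
    s = seq.upper()
    return s.count("G") + s.count("C")


class SubstitutionTable:
    """Counts of the 12 directed substitutions (6 pairs × 2 directions)."""

    def __init__(self, counts: dict | None = None):
        self.counts = {(a, d): 0 for a in BASES for d in BASES if a != d}
        if counts:
            for k, v in counts.items():
                if k not in self.counts:
                    raise KeyError(f"not a directed substitution: {k}")
                self.counts[k] = int(v)

    def directed(self, ancestral: str, derived: str) -> int:
        return self.counts[(ancestral, derived)]

    def pair_total(self, x: str, y: str) -> int:
        return self.counts[(x, y)] + self.counts[(y, x)]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        """Table-layout frame: pairs as columns, forward/reverse/total rows."""
        data = {
            f"{x}{y}": [self.counts[(x, y)], self.counts[(y, x)], self.pair_total(x, y)]
            for x, y in PAIRS
        }
        return pd.DataFrame(data, index=["forward", "reverse", "total"])


def substitution_table(variants) -> SubstitutionTable:
    """Tally directed substitution counts; non-ACGT records are dropped
    (logged), never silently miscounted."""
    df = _as_frame(variants)
    df = df[df["kind"] == "substitution"]
    table = SubstitutionTable()
    bad = 0
    for anc, der in zip(df["ancestral"], df["derived"]):
        key = (str(anc).upper(), str(der).upper())
        if key in table.counts:
            table.counts[key] += 1
        else:
            bad += 1
    if bad:
        logger.warning("dropped %d records with non-ACGT or identical bases", bad)
    return table


def transitions_fraction(table: SubstitutionTable) -> float:
    """(A↔G + C↔T) / all substitutions."""
    total = table.total
    if total == 0:
        raise UndefinedProportionError("empty substitution table")
    transitions = sum(table.pair_total(x, y) for x, y in TRANSITION_PAIRS)
    return transitions / total


def at_bias_rate(table: SubstitutionTable, config: StatsConfig = StatsConfig()) -> float:
    """Composition-normalized G/C→A/T over A/T→G/C substitution-rate ratio."""
    n_gc_at = sum(table.counts[k] for k in GC_TO_AT)
    n_at_gc = sum(table.counts[k] for k in AT_TO_GC)
    if n_at_gc == 0 or n_gc_at == 0:
        raise UndefinedProportionError("both directional sums must be positive")
    f_at = 1.0 - config.f_gc
    return (n_gc_at / config.f_gc) / (n_at_gc / f_at)


def expected_gc(rate: float) -> float:
    """Equilibrium GC proportion implied by the AT mutation-rate bias."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return 1.0 / (1.0 + rate)


def _freq_bins(freqs: np.ndarray, width: float) -> np.ndarray:
    """Bin index per frequency: half-open [k·w, (k+1)·w), last bin closed."""
    nbins = int(round(1.0 / width))
    idx = np.floor(np.asarray(freqs, dtype=float) / width).astype(int)
    return np.clip(idx, 0, nbins - 1)


def binned_at_bias(variants, config: StatsConfig = StatsConfig(), subset: str = "all") -> pd.DataFrame:
    """AT bias per derived-allele-frequency bin.

    ``subset`` selects which variants enter each bin's rate: ``all``
    substitutions, ``transitions``, ``transversions`` (between A/T and G/C
    only), or ``single-bp-indels``, where the inserted or deleted base is
    classified as GC or AT and the bias is the composition-normalized
    AT-base over GC-base event ratio.  Bins with an undefined rate hold
    NaN, not zero.
    """
    df = _as_frame(variants)
    nbins = int(round(1.0 / config.bin_width))
    edges = [i * config.bin_width for i in range(nbins)]
    rows = []
    if subset == "single-bp-indels":
        sel = df[(df["kind"].isin(["insertion", "deletion"])) & (df["length"] == 1)]
        bases = np.array([
            (v.upper() if isinstance(v, str) else "?")
            for v in np.where(sel["kind"] == "insertion", sel["derived"], sel["ancestral"])
        ])
        bins = _freq_bins(sel["derived_freq"].to_numpy(), config.bin_width) if len(sel) else np.array([], int)
        for b in range(nbins):
            sub = bases[bins == b]
            n_gc = int(np.isin(sub, ["G", "C"]).sum())
            n_at = int(np.isin(sub, ["A", "T"]).sum())
            if n_gc == 0 or n_at == 0:
                rate = np.nan
            else:
                rate = (n_at / (1.0 - config.f_gc)) / (n_gc / config.f_gc)
            rows.append({"bin_low": edges[b], "n": n_gc + n_at, "at_bias": rate})
        return pd.DataFrame(rows)

    sel = df[df["kind"] == "substitution"]
    if subset == "transitions":
        keep = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    elif subset == "transversions":
        keep = [("C", "A"), ("A", "C"), ("G", "T"), ("T", "G")]
    elif subset == "all":
        keep = list(GC_TO_AT) + list(AT_TO_GC)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    pairs = list(zip(sel["ancestral"].str.upper(), sel["derived"].str.upper()))
    mask = np.array([p in keep for p in pairs]) if pairs else np.array([], bool)
    sel = sel[mask]
    pairs = [p for p, m in zip(pairs, mask) if m]
    bins = _freq_bins(sel["derived_freq"].to_numpy(), config.bin_width) if len(sel) else np.array([], int)
    gc_at = np.array([p in GC_TO_AT for p in pairs])
    for b in range(nbins):
        inb = bins == b
        n_gc_at = int((inb & gc_at).sum())
        n_at_gc = int((inb & ~gc_at).sum())
        if n_gc_at == 0 or n_at_gc == 0:
            rate = np.nan
        else:
            rate = (n_gc_at / config.f_gc) / (n_at_gc / (1.0 - config.f_gc))
        rows.append({"bin_low": edges[b], "n": n_gc_at + n_at_gc, "at_bias": rate})
    return pd.DataFrame(rows)


class IndelTable:
    """Insertion/deletion counts, bases and GC bases per size class."""

    COLUMNS = ("insertions", "deletions", "inserted_bases", "deleted_bases",
               "gc_inserted", "gc_deleted")

    def __init__(self):
        idx = list(SIZE_CLASSES) + ["overall"]
        self.frame = pd.DataFrame(0, index=idx, columns=list(self.COLUMNS))

    @staticmethod
    def size_class(length: int):
        return length if 1 <= length <= 10 else ">10"


def indel_table(variants) -> IndelTable:
    """Tally indel events, bases and GC bases by size class."""
    df = _as_frame(variants)
    df = df[df["kind"].isin(["insertion", "deletion"])]
    table = IndelTable()
    f = table.frame
    for kind, anc, der, length in zip(df["kind"], df["ancestral"], df["derived"], df["length"]):
        seq = der if kind == "insertion" else anc
        seq = str(seq) if isinstance(seq, str) else ""
        n = int(length) if length and not pd.isna(length) else len(seq)
        if n < 1:
            logger.warning("dropped indel with non-positive length")
            continue
        cls = IndelTable.size_class(n)
        gc = _gc_count(seq)
        if kind == "insertion":
            cols = ("insertions", "inserted_bases", "gc_inserted")
        else:
            cols = ("deletions", "deleted_bases", "gc_deleted")
        for row in (cls, "overall"):
            f.loc[row, cols[0]] += 1
            f.loc[row, cols[1]] += n
            f.loc[row, cols[2]] += gc
    return table


def indel_ratios(table: IndelTable) -> pd.DataFrame:
    """Deletion/insertion count and base ratios and per-side GC proportions,
    per size class and overall.  Cells with a zero denominator are NaN."""
    f = table.frame

    def safe(num, den):
        return np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)

    out = pd.DataFrame(index=f.index)
    out["count_ratio"] = safe(f["deletions"], f["insertions"])
    out["base_ratio"] = safe(f["deleted_bases"], f["inserted_bases"])
    out["gc_insertion"] = safe(f["gc_inserted"], f["inserted_bases"])
    out["gc_deletion"] = safe(f["gc_deleted"], f["deleted_bases"])
    return out


def binned_deletion_insertion_ratio(variants, config: StatsConfig = StatsConfig()) -> pd.DataFrame:
    """Deletion-to-insertion count ratio per derived-frequency bin; bins
    without insertions (or empty) are NaN."""
    df = _as_frame(variants)
    df = df[df["kind"].isin(["insertion", "deletion"])]
    nbins = int(round(1.0 / config.bin_width))
    edges = [i * config.bin_width for i in range(nbins)]
    bins = _freq_bins(df["derived_freq"].to_numpy(), config.bin_width) if len(df) else np.array([], int)
    is_del = (df["kind"] == "deletion").to_numpy()
    rows = []
    for b in range(nbins):
        inb = bins == b
        n_del = int((inb & is_del).sum())
        n_ins = int((inb & ~is_del).sum())
        rows.append({
            "bin_low": edges[b],
            "insertions": n_ins,
            "deletions": n_del,
            "ratio": (n_del / n_ins) if n_ins > 0 else np.nan,
        })
    return pd.DataFrame(rows)
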