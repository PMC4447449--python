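"""Phased-VCF input/output and synthetic fixture generation.

Reads phased diploid genotypes into :class:`~thetacall.block.HaplotypeBlock`
matrices (two haplotypes per sample, 1-based VCF positions converted to the
package's 0-based coordinates), parses alignment-based ancestral-allele
(AA) annotations where uppercase means high confidence, writes caller
output as TSV or as an annotated VCF copy, and exports simulator
populations as phased VCF fixtures with a side truth table.

Unphased or missing genotypes become missing codes for both haplotypes:
the estimators need haplotypes, and an unphased genotype does not provide
them.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .block import MISSING, HaplotypeBlock
from .caller import AncestralCall

__all__ = [
    "AnnotationRecord",
    "read_phased_vcf",
    "parse_aa",
    "aa_call_set",
    "write_calls",
    "read_calls",
    "annotate_vcf",
    "make_fixture",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """Alignment-based ancestral-allele annotation of one variant."""

    allele: str | None
    confidence: str  # "high" (uppercase) | "low" (lowercase) | "absent"

    @property
    def usable(self) -> bool:
        return self.confidence == "high"


_ABSENT = {"", ".", "-", "N", "n"}


def parse_aa(info) -> AnnotationRecord:
    """Extract the AA annotation from an INFO mapping or raw INFO string.

    Case encodes confidence: uppercase = high, lowercase = low; missing,
    '.', '-' or N = absent.  Total function: anything unparseable is
    absent.
    """
    value = None
    if isinstance(info, str):
        for field in info.split(";"):
            if field.startswith("AA="):
                value = field[3:]
                break
    elif info is not None:
        try:
            value = info.get("AA")
        except AttributeError:
            value = None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    if value is None or str(value) in _ABSENT:
        return AnnotationRecord(None, "absent")
    value = str(value)
    conf = "high" if value == value.upper() else "low"
    return AnnotationRecord(value.upper(), conf)


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def _parse_region(region: str | None):
    if region is None:
        return None
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}; expected chrom[:start-end]")
    chrom, s, e = m.groups()
    return chrom, (int(s) - 1 if s else 0), (int(e) if e else None)  # 0-based half-open


def read_phased_vcf(path, region: str | None = None):
    """Read a phased VCF into a HaplotypeBlock plus variant metadata.

    Returns ``(block, meta)`` where ``meta`` is a DataFrame with one row
    per site: chrom, pos (0-based), ref, alts, the parsed AA annotation
    and its confidence.  Samples contribute two haplotype rows each
    (``<sample>_1``, ``<sample>_2``); any unphased or missing genotype is
    recorded as missing on both haplotypes.  Raises if the region holds no
    usable variant or no phased genotype at all.
    """
    reg = _parse_region(region)
    positions: list[int] = []
    meta_rows = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no samples")
        any_phased = False
        last_pos = None
        for rec in vcf:
            if reg is not None:
                chrom, start, stop = reg
                if rec.chrom != chrom or rec.start < start:
                    continue
                if stop is not None and rec.start >= stop:
                    continue
            if rec.start == last_pos:
                continue  # duplicate position: keep the first record
            col = np.full(2 * len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                sample = rec.samples[s]
                gt = sample.allele_indices
                if (
                    sample.phased
                    and gt is not None
                    and len(gt) == 2
                    and gt[0] is not None
                    and gt[1] is not None
                ):
                    col[2 * i] = gt[0]
                    col[2 * i + 1] = gt[1]
                    any_phased = True
            positions.append(rec.start)
            last_pos = rec.start
            columns.append(col)
            meta_rows.append({
                "chrom": rec.chrom,
                "pos": rec.start,
                "ref": rec.ref,
                "alts": ",".join(rec.alts or ()),
                "aa": parse_aa(dict(rec.info)).allele,
                "aa_confidence": parse_aa(dict(rec.info)).confidence,
            })
    if not positions:
        raise ValueError(f"{path}: no variants in region {region!r}")
    if not any_phased:
        raise ValueError(f"{path}: no phased genotypes found")
    ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    block = HaplotypeBlock(
        positions=np.array(positions, dtype=np.int64),
        alleles=np.column_stack(columns),
        haplotype_ids=ids,
    )
    return block, pd.DataFrame(meta_rows)


def aa_call_set(meta: pd.DataFrame) -> dict:
    """Alignment-based ancestral calls as an AncestralCall set.

    Converts the AA annotations of :func:`read_phased_vcf` metadata into
    ``{position: AncestralCall}`` so they can be compared with θ-based
    calls via :func:`thetacall.caller.concordance` or ``consensus``.  Only
    high-confidence (uppercase) annotations matching the record's REF or
    an ALT become pass calls (exact string match on the allele sequence);
    everything else is a no-call.
    """
    out: dict[int, AncestralCall] = {}
    for _, row in meta.iterrows():
        pos = int(row["pos"])
        alleles = [row["ref"]] + [a for a in str(row["alts"]).split(",") if a]
        aa = row["aa"]
        if row["aa_confidence"] == "high" and aa in alleles:
            out[pos] = AncestralCall(
                pos, "seq-align", ancestral_allele=alleles.index(aa),
                filter_status="pass",
            )
        else:
            reason = "aa-" + str(row["aa_confidence"])
            out[pos] = AncestralCall(pos, "seq-align", filter_status=reason)
    return out


# ---------------------------------------------------------------------------
# Call tables
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "position", "method", "filter_status", "ancestral_allele",
    "derived_allele_frequency", "thetas", "emergence_order",
]


def write_calls(calls, path) -> None:
    """Write a call set to TSV (one row per variant per method).

    ``calls`` is ``{method: {position: AncestralCall}}`` as produced by
    :func:`thetacall.caller.call_variants`.  θ values are serialized as
    ``allele=value`` pairs.
    """
    rows = []
    for method in sorted(calls):
        for pos in sorted(calls[method]):
            c = calls[method][pos]
            rows.append({
                "position": pos,
                "method": method,
                "filter_status": c.filter_status,
                "ancestral_allele": "" if c.ancestral_allele is None else c.ancestral_allele,
                "derived_allele_frequency": c.derived_allele_frequency,
                "thetas": ";".join(f"{a}={c.thetas[a]:.10g}" for a in sorted(c.thetas)),
                "emergence_order": ",".join(str(a) for a in c.emergence_order),
            })
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path):
    """Read back a TSV call table into ``{method: {position: AncestralCall}}``."""
    df = pd.read_csv(path, sep="\t", dtype={"ancestral_allele": "Int64"})
    out: dict[str, dict[int, AncestralCall]] = {}
    for _, r in df.iterrows():
        thetas = {}
        if isinstance(r["thetas"], str) and r["thetas"]:
            for item in r["thetas"].split(";"):
                a, v = item.split("=")
                thetas[int(a)] = float(v)
        order = ()
        if isinstance(r["emergence_order"], str) and r["emergence_order"]:
            order = tuple(int(a) for a in r["emergence_order"].split(","))
        call = AncestralCall(
            variant_id=int(r["position"]),
            method=r["method"],
            thetas=thetas,
            ancestral_allele=None if pd.isna(r["ancestral_allele"]) else int(r["ancestral_allele"]),
            emergence_order=order,
            filter_status=r["filter_status"],
            derived_allele_frequency=float(r["derived_allele_frequency"]),
        )
        out.setdefault(r["method"], {})[int(r["position"])] = call
    return out


def annotate_vcf(vcf_in, vcf_out, calls: dict, tag: str = "AAT") -> None:
    """Copy a VCF adding an INFO tag with the called ancestral allele.

    ``calls`` maps 0-based position to AncestralCall (one method); the tag
    value is the called ancestral allele's base (REF/ALT resolved), written
    only for pass calls.
    """
    with pysam.VariantFile(str(vcf_in)) as fin:
        header = fin.header.copy()
        header.info.add(tag, 1, "String", "Ancestral allele from haplotype diversity")
        with pysam.VariantFile(str(vcf_out), "w", header=header) as fout:
            for rec in fin:
                rec.translate(header)
                call = calls.get(rec.start)
                if call is not None and call.passed:
                    alleles = (rec.ref,) + tuple(rec.alts or ())
                    code = call.ancestral_allele
                    if code is not None and code < len(alleles):
                        rec.info[tag] = alleles[code]
                fout.write(rec)


# ---------------------------------------------------------------------------
# Synthetic fixtures from simulator state
# ---------------------------------------------------------------------------

def make_fixture(
    state,
    vcf_path,
    truth_path=None,
    ledger=None,
    chrom: str = "1",
    n_samples: int | None = None,
):
    """Write a phased VCF of a simulated population (synthetic fixture).

    Haplotypes are paired in order into diploid samples (an odd haplotype
    count is an error).  Only segregating sites become records; the binary
    simulator alleles map to REF=A (code 0), ALT=G (code 1).  If a
    mutation ledger is given, a truth TSV of its live variants (position,
    ancestral and derived codes and bases, birth generation) is written
    alongside, and each ledgered record carries an uppercase AA INFO tag.
    Returns the number of variant records written.
    """
    H = state.haplotypes if hasattr(state, "haplotypes") else np.asarray(state)
    two_n, L = H.shape
    if two_n % 2:
        raise ValueError("odd haplotype count cannot be paired into samples")
    n_total = two_n // 2
    if n_samples is not None:
        if n_samples > n_total:
            raise ValueError("not enough haplotypes for requested samples")
        H = H[: 2 * n_samples]
        two_n = 2 * n_samples
    counts = H.sum(axis=0)
    seg = np.flatnonzero((counts > 0) & (counts < two_n))

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={L}>")
    header.info.add("AA", 1, "String", "True ancestral allele (simulation truth)")
    header.formats.add("GT", 1, "String", "Genotype")
    n_samples_out = two_n // 2
    for i in range(n_samples_out):
        header.add_sample(f"s{i}")
    base = {0: "A", 1: "G"}
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for site in seg:
            rec = out.new_record(
                contig=chrom, start=int(site), alleles=("A", "G")
            )
            if ledger is not None and ledger.birth_gen[site] >= 0:
                rec.info["AA"] = base[int(1 - ledger.derived[site])]
            col = H[:, site]
            for i in range(n_samples_out):
                rec.samples[i]["GT"] = (int(col[2 * i]), int(col[2 * i + 1]))
                rec.samples[i].phased = True
            out.write(rec)

    if truth_path is not None and ledger is not None:
        live = ledger.live_sites()
        live = live[np.isin(live, seg)]
        pd.DataFrame({
            "position": live,
            "ancestral_code": 1 - ledger.derived[live],
            "derived_code": ledger.derived[live],
            "ancestral_base": [base[int(1 - d)] for d in ledger.derived[live]],
            "derived_base": [base[int(d)] for d in ledger.derived[live]],
            "birth_generation": ledger.birth_gen[live],
        }).to_csv(truth_path, sep="\t", index=False)
    return int(seg.size)
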