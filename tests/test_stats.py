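"""Substitution/indel statistics tests, including full reproduction of the
published human-genome summary tables from their printed counts."""
import numpy as np
import pandas as pd
import pytest

from thetacall.errors import UndefinedProportionError
from thetacall.stats import (
    AnnotatedVariant,
    IndelTable,
    StatsConfig,
    at_bias_rate,
    binned_at_bias,
    binned_deletion_insertion_ratio,
    expected_gc,
    indel_ratios,
    indel_table,
    substitution_table,
    transitions_fraction,
    SubstitutionTable,
)

# Directed substitution counts per identification method, as printed
# (pair columns AG CT AC GT AT CG; forward = first->second base).
TABLE2 = {
    "seq-align": {
        "fwd": (4681715, 6561124, 1178641, 1521824, 1136407, 1417275),
        "rev": (6586189, 4674730, 1531910, 1174490, 1137087, 1412037),
        "transitions": 0.682, "rate": 1.99, "expected_gc": 0.33,
    },
    "theta1": {
        "fwd": (2206576, 3162284, 567220, 708308, 536149, 674353),
        "rev": (3175293, 2206561, 714588, 566844, 538419, 671601),
        "transitions": 0.684, "rate": 2.01, "expected_gc": 0.33,
    },
    "theta2": {
        "fwd": (1732983, 2392367, 443313, 545528, 416808, 520360),
        "rev": (2399720, 1732124, 548508, 442025, 418021, 519494),
        "transitions": 0.682, "rate": 1.95, "expected_gc": 0.34,
    },
    "all": {
        "fwd": (1176686, 1684162, 305448, 386391, 289539, 367475),
        "rev": (1687828, 1177402, 389332, 305098, 289983, 367192),
        "transitions": 0.680, "rate": 2.01, "expected_gc": 0.33,
    },
    "any": {
        "fwd": (2088389, 3009224, 540251, 676928, 509582, 642936),
        "rev": (3020729, 2088422, 682527, 539225, 512084, 641544),
        "transitions": 0.683, "rate": 2.02, "expected_gc": 0.33,
    },
}
PAIR_ORDER = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G"))

# Indel counts and bases per method, as printed, with the printed ratios.
TABLE3 = {
    "seq-align": (204282, 491037, 402554, 1221722, 2.40, 3.03),
    "theta1": (534245, 830413, 2217770, 23439382, 1.55, 10.57),
    "theta2": (463693, 715306, 3993462, 14434339, 1.54, 3.61),
    "all": (125424, 325099, 251301, 825430, 2.59, 3.28),
    "any": (408917, 725312, 1245483, 14295582, 1.77, 11.48),
    "theta1&theta2": (352473, 596505, 1138427, 13981366, 1.69, 12.28),
}


def table2_counts(method: str) -> SubstitutionTable:
    row = TABLE2[method]
    counts = {}
    for (x, y), f, r in zip(PAIR_ORDER, row["fwd"], row["rev"]):
        counts[(x, y)] = f
        counts[(y, x)] = r
    return SubstitutionTable(counts)


def _round_half_up(x, nd):
    import decimal

    return float(decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("1." + "0" * nd), rounding=decimal.ROUND_HALF_UP))


@pytest.mark.parametrize("method", list(TABLE2))
def test_published_substitution_summaries_reproduced(method):
    """Transitions fraction, AT-bias rate and expected GC match the printed
    values at printed precision for every identification method."""
    table = table2_counts(method)
    row = TABLE2[method]
    assert _round_half_up(transitions_fraction(table), 3) == row["transitions"]
    rate = at_bias_rate(table, StatsConfig(f_gc=0.41))
    assert _round_half_up(rate, 2) == row["rate"]
    assert _round_half_up(expected_gc(rate), 2) == row["expected_gc"]


@pytest.mark.parametrize("method", list(TABLE3))
def test_published_indel_ratios_reproduced(method):
    """Deletion/insertion count and base ratios match the printed values."""
    ins, dele, ib, db, ratio, bratio = TABLE3[method]
    table = IndelTable()
    table.frame.loc["overall", ["insertions", "deletions", "inserted_bases", "deleted_bases"]] = [ins, dele, ib, db]
    out = indel_ratios(table)
    assert _round_half_up(out.loc["overall", "count_ratio"], 2) == ratio
    assert _round_half_up(out.loc["overall", "base_ratio"], 2) == bratio


# ---------------------------------------------------------------------------
# unit behaviour
# ---------------------------------------------------------------------------

def test_substitution_table_single_and_exhaustive():
    t = substitution_table([AnnotatedVariant("substitution", "A", "G", 0.1)])
    assert t.directed("A", "G") == 1 and t.total == 1

    variants = [
        AnnotatedVariant("substitution", a, d, 0.5)
        for a in "ACGT" for d in "ACGT" if a != d
    ]
    t12 = substitution_table(variants)
    assert all(v == 1 for v in t12.counts.values())


def test_substitution_table_order_invariance(rng):
    variants = [
        AnnotatedVariant("substitution", a, d, 0.5)
        for a in "ACGT" for d in "ACGT" if a != d
    ] * 3
    shuffled = list(variants)
    rng.shuffle(shuffled)
    assert substitution_table(variants).counts == substitution_table(shuffled).counts


def test_substitution_table_rejects_bad_bases(caplog):
    variants = [
        AnnotatedVariant("substitution", "A", "G", 0.1),
        AnnotatedVariant("substitution", "N", "G", 0.1),
        AnnotatedVariant("substitution", "A", "A", 0.1),
    ]
    t = substitution_table(variants)
    assert t.total == 1


def test_transitions_fraction_edge_cases():
    only_ag = SubstitutionTable({("A", "G"): 5, ("G", "A"): 3})
    assert transitions_fraction(only_ag) == 1.0
    with pytest.raises(UndefinedProportionError):
        transitions_fraction(SubstitutionTable())


def test_at_bias_symmetric_counts_no_bias():
    counts = {k: 100 for k in [("G", "A"), ("C", "T"), ("C", "A"), ("G", "T"),
                               ("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]}
    t = SubstitutionTable(counts)
    assert at_bias_rate(t, StatsConfig(f_gc=0.5)) == pytest.approx(1.0)


def test_expected_gc_no_bias_is_half():
    assert expected_gc(1.0) == 0.5
    with pytest.raises(ValueError):
        expected_gc(0.0)


def test_binned_at_bias_flat_for_frequency_independent_input():
    variants = []
    for b in range(10):
        f = b / 10 + 0.05
        variants += [AnnotatedVariant("substitution", "G", "A", f)] * 50
        variants += [AnnotatedVariant("substitution", "A", "G", f)] * 50
    out = binned_at_bias(variants, StatsConfig(f_gc=0.5))
    assert len(out) == 10
    np.testing.assert_allclose(out["at_bias"], 1.0)


def test_binned_at_bias_detects_planted_gc_fixation_bias():
    """AT->GC enriched at high frequency => AT bias decreasing across bins."""
    variants = []
    for b in range(10):
        f = b / 10 + 0.05
        variants += [AnnotatedVariant("substitution", "G", "A", f)] * 100
        variants += [AnnotatedVariant("substitution", "A", "G", f)] * (50 + 20 * b)
    out = binned_at_bias(variants, StatsConfig(f_gc=0.5))
    assert np.all(np.diff(out["at_bias"]) < 0)


def test_binned_at_bias_empty_bins_are_nan():
    variants = [
        AnnotatedVariant("substitution", "G", "A", 0.05),
        AnnotatedVariant("substitution", "A", "G", 0.05),
    ]
    out = binned_at_bias(variants, StatsConfig(f_gc=0.5))
    assert np.isfinite(out["at_bias"].iloc[0])
    assert out["at_bias"].iloc[1:].isna().all()


def test_binned_at_bias_subsets():
    variants = [
        AnnotatedVariant("substitution", "G", "A", 0.05),  # transition GC->AT
        AnnotatedVariant("substitution", "A", "G", 0.05),  # transition AT->GC
        AnnotatedVariant("substitution", "C", "A", 0.05),  # transversion GC->AT
        AnnotatedVariant("substitution", "A", "C", 0.05),  # transversion AT->GC
        AnnotatedVariant("substitution", "A", "T", 0.05),  # not in either class
    ]
    cfg = StatsConfig(f_gc=0.5)
    ts = binned_at_bias(variants, cfg, subset="transitions")
    tv = binned_at_bias(variants, cfg, subset="transversions")
    assert ts["n"].iloc[0] == 2 and tv["n"].iloc[0] == 2
    both = binned_at_bias(variants, cfg, subset="all")
    assert both["n"].iloc[0] == 4  # A<->T ignored by the bias rate


def test_binned_at_bias_single_bp_indels():
    variants = [
        AnnotatedVariant("insertion", "", "G", 0.05),
        AnnotatedVariant("insertion", "", "A", 0.05),
        AnnotatedVariant("deletion", "C", "", 0.05),
        AnnotatedVariant("deletion", "TT", "", 0.05),  # 2 bp: excluded
    ]
    out = binned_at_bias(variants, StatsConfig(f_gc=0.5), subset="single-bp-indels")
    assert out["n"].iloc[0] == 3
    assert out["at_bias"].iloc[0] == pytest.approx((1 / 0.5) / (2 / 0.5))


def test_indel_table_and_ratios_hand_example():
    variants = [
        AnnotatedVariant("insertion", "", "GCA", 0.2),
        AnnotatedVariant("deletion", "TTT", "", 0.4),
    ]
    table = indel_table(variants)
    out = indel_ratios(table)
    assert out.loc["overall", "count_ratio"] == pytest.approx(1.0)
    assert out.loc["overall", "base_ratio"] == pytest.approx(1.0)
    assert out.loc["overall", "gc_insertion"] == pytest.approx(2 / 3)
    assert out.loc["overall", "gc_deletion"] == 0.0
    assert table.frame.loc[3, "insertions"] == 1
    assert np.isnan(out.loc[1, "count_ratio"])  # no 1-bp insertions


def test_indel_size_classes_above_ten_pooled():
    variants = [
        AnnotatedVariant("insertion", "", "A" * 15, 0.2),
        AnnotatedVariant("deletion", "G" * 30, "", 0.2),
    ]
    f = indel_table(variants).frame
    assert f.loc[">10", "insertions"] == 1
    assert f.loc[">10", "deleted_bases"] == 30


def test_binned_deletion_insertion_ratio():
    flat = []
    for b in range(10):
        f = b / 10 + 0.05
        flat += [AnnotatedVariant("insertion", "", "A", f),
                 AnnotatedVariant("deletion", "A", "", f)]
    out = binned_deletion_insertion_ratio(flat)
    np.testing.assert_allclose(out["ratio"], 1.0)

    planted = []
    for b in range(10):
        f = b / 10 + 0.05
        planted += [AnnotatedVariant("insertion", "", "A", f)] * 10
        planted += [AnnotatedVariant("deletion", "A", "", f)] * (5 + 3 * b)
    out2 = binned_deletion_insertion_ratio(planted)
    assert np.all(np.diff(out2["ratio"]) > 0)

    single = [AnnotatedVariant("deletion", "A", "", 0.35),
              AnnotatedVariant("insertion", "", "A", 0.35)]
    out3 = binned_deletion_insertion_ratio(single)
    assert out3["ratio"].notna().sum() == 1


def test_dataframe_input_equivalent_to_dataclasses():
    variants = [AnnotatedVariant("substitution", "G", "A", 0.3),
                AnnotatedVariant("substitution", "A", "G", 0.8)]
    df = pd.DataFrame({
        "kind": ["substitution"] * 2,
        "ancestral": ["G", "A"], "derived": ["A", "G"],
        "derived_freq": [0.3, 0.8], "length": [1, 1],
    })
    assert substitution_table(variants).counts == substitution_table(df).counts
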