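"""Column profiling, LVR delimitation, and length tabulation."""

import numpy as np
import pytest

from rrnalvr.delimit import (
    ColumnProfile,
    LvrLengthTable,
    check_no_overlap,
    column_profile,
    delimit_lvrs,
    lvr_lengths,
)
from rrnalvr.io import Msa, RegionMap
from rrnalvr.simulate import default_generator_spec, generate


def _profile(pattern: str, threshold: float = 0.2) -> ColumnProfile:
    """Build a profile from a V/C pattern string (variable/conserved)."""
    var = np.array([c == "V" for c in pattern])
    gf = np.where(var, 0.9, 0.0)
    return ColumnProfile(gap_fraction=gf, entropy=np.zeros(len(pattern)),
                         is_variable=var, gap_threshold=threshold)


def test_profile_of_identical_gapless_columns():
    msa = Msa.from_pairs([("a", "ACGU"), ("b", "ACGU")])
    p = column_profile(msa, gap_threshold=0.4)
    assert np.all(p.gap_fraction == 0)
    assert np.all(p.entropy == 0)
    assert not p.is_variable.any()


def test_profile_gap_fraction_and_threshold():
    msa = Msa.from_pairs([("a", "-A"), ("b", "-A"), ("c", "AA"), ("d", "AA")])
    p = column_profile(msa, gap_threshold=0.4)
    assert p.gap_fraction[0] == pytest.approx(0.5)
    assert p.is_variable[0] and not p.is_variable[1]


def test_profile_entropy_uniform_column_is_two_bits():
    msa = Msa.from_pairs([("a", "A"), ("b", "C"), ("c", "G"), ("d", "U")])
    p = column_profile(msa, gap_threshold=0.5)
    assert p.entropy[0] == pytest.approx(2.0)


def test_profile_threshold_out_of_range():
    msa = Msa.from_pairs([("a", "AC")])
    with pytest.raises(ValueError):
        column_profile(msa, gap_threshold=1.0)


def test_delimit_all_conserved_gives_empty_map():
    assert delimit_lvrs(_profile("C" * 20)).regions == ()


def test_delimit_two_regions_across_long_conserved_block():
    rm = delimit_lvrs(_profile("VVVVV" + "C" * 10 + "VVVV"), min_conserved_block=5)
    assert rm.regions == (("B", 0, 5), ("C", 15, 19))


def test_delimit_absorbs_short_conserved_interruption():
    rm = delimit_lvrs(_profile("VVV" + "CC" + "VVVV"), min_conserved_block=5)
    assert rm.regions == (("B", 0, 9),)


def test_delimit_min_lvr_cols_drops_scattered_indels():
    rm = delimit_lvrs(_profile("CCCCCVCCCCCVVC"), min_conserved_block=5, min_lvr_cols=2)
    assert rm.regions == (("B", 11, 13),)


def test_delimit_label_schemes():
    prof = _profile("VV" + "C" * 6 + "VV" + "C" * 6 + "VV")
    assert delimit_lvrs(prof, label_scheme="d").labels == ("D2", "D3", "D4")
    assert delimit_lvrs(prof, label_scheme="sub:D3").labels == ("D3-1", "D3-2", "D3-3")


def test_delimit_invariant_to_row_order_and_duplication():
    msa = Msa.from_pairs([("a", "AC--GAA"), ("b", "ACGUGAA"), ("c", "AC-UGAA")])
    rm1 = delimit_lvrs(column_profile(msa), min_conserved_block=2)
    perm = Msa(tuple(reversed(msa.rows)))
    rm2 = delimit_lvrs(column_profile(perm), min_conserved_block=2)
    dup = Msa.from_pairs(list(msa.rows) + [("a2", msa.row("a")), ("b2", msa.row("b")),
                                           ("c2", msa.row("c"))])
    rm3 = delimit_lvrs(column_profile(dup), min_conserved_block=2)
    assert rm1.regions == rm2.regions == rm3.regions


def test_variable_column_count_monotone_in_threshold():
    rng = np.random.default_rng(2)
    rows = [
        (f"s{i}", "".join(rng.choice(list("ACGU-"), size=40))) for i in range(8)
    ]
    msa = Msa.from_pairs(rows)
    counts = [
        column_profile(msa, gap_threshold=t).is_variable.sum()
        for t in (0.1, 0.3, 0.5, 0.7, 0.9)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_lvr_lengths_counts_non_gap_residues():
    msa = Msa.from_pairs([("a", "AC--G"), ("b", "ACGUG")])
    table = lvr_lengths(msa, RegionMap((("B", 1, 4),)))
    assert table.length("a", "B") == 1
    assert table.length("b", "B") == 3


def test_lvr_lengths_zero_length_region():
    msa = Msa.from_pairs([("a", "ACG")])
    table = lvr_lengths(msa, RegionMap((("B", 1, 1),)))
    assert table.length("a", "B") == 0


def test_lvr_lengths_unknown_label_errors():
    msa = Msa.from_pairs([("a", "ACG")])
    table = lvr_lengths(msa, RegionMap((("B", 0, 2),)))
    with pytest.raises(KeyError):
        table.length("a", "Z")


def test_region_plus_remainder_recounts_full_ungapped_length():
    rng = np.random.default_rng(4)
    for _ in range(20):
        msa = Msa.from_pairs(
            [(f"s{i}", "".join(rng.choice(list("ACGU-"), size=30))) for i in range(4)]
        )
        rm = RegionMap((("B", 3, 8), ("C", 12, 20), ("D", 25, 28)))
        table = lvr_lengths(msa, rm)
        in_regions = set()
        for _, s, e in rm:
            in_regions.update(range(s, e))
        for rid, row in msa:
            outside = sum(
                1 for c, x in enumerate(row) if x != "-" and c not in in_regions
            )
            total = sum(table.length(rid, lab) for lab in rm.labels)
            assert total + outside == len(msa.ungapped(rid))


def test_check_no_overlap():
    a = RegionMap((("B", 0, 5), ("C", 10, 15)))
    b = RegionMap((("D3-1", 20, 24),))
    shares = RegionMap((("X", 4, 7),))
    assert check_no_overlap([a, b])
    assert not check_no_overlap([a, shares])
    assert check_no_overlap([RegionMap(()), RegionMap(())])


def test_length_table_requires_complete_cross_product():
    import pandas as pd

    df = pd.DataFrame(
        [("a", "B", 3), ("a", "C", 2), ("b", "B", 3)], columns=["id", "region", "length"]
    )
    with pytest.raises(Exception):
        LvrLengthTable(df)


def test_zero_noise_delimitation_recovers_planted_boundaries():
    _, truth = generate(default_generator_spec(seed=11))
    recovered = delimit_lvrs(column_profile(truth.msa))
    assert recovered.regions == truth.region_map.regions
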