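"""Synapomorphy scanning: tallies, flagging logic, and report rendering."""

import numpy as np
import pandas as pd
import pytest

from rrnalvr.delimit import LvrLengthTable
from rrnalvr.io import CladeMap
from rrnalvr.scan import (
    SynapomorphyCandidate,
    candidates_frame,
    flag_synapomorphies,
    report_table,
    state_distribution,
)

from _oracles import scan_brute

# the 19 cimicoid/naboid-style accessions of the 5 nt LVR-W fixture
W_FIXTURE_IDS = [
    "EF487300", "GQ258424", "GQ258425", "EF487298", "AY252319", "EF487297",
    "EF487307", "EF487295", "EF487301", "EF487296", "EF487308", "EF487310",
    "GQ258395", "GQ258406", "GQ258407", "GQ258410", "GQ258411", "GQ258396",
    "EU683128",
]


def _table(rows):
    return LvrLengthTable(pd.DataFrame(rows, columns=["id", "region", "length"]))


def _clades(all_ids, **clades):
    return CladeMap(
        terminals=frozenset(all_ids),
        clades={k: frozenset(v) for k, v in clades.items()},
    )


def test_state_distribution_counts():
    table = _table([("a", "B", 5), ("b", "B", 5), ("c", "B", 5), ("d", "B", 7)])
    assert state_distribution(table, {"a", "b", "c"}, "B") == {5: 3}
    assert state_distribution(table, set(), "B") == {}


def test_state_distribution_unknown_region_errors():
    table = _table([("a", "B", 5)])
    with pytest.raises(KeyError):
        state_distribution(table, {"a"}, "Z")


def test_state_distribution_matches_groupby_recount():
    rng = np.random.default_rng(6)
    ids = [f"s{i}" for i in range(25)]
    rows = [(i, r, int(rng.integers(3, 8))) for i in ids for r in "BC"]
    table = _table(rows)
    members = set(ids[:10])
    got = state_distribution(table, members, "B")
    df = table.frame
    expect = (
        df[(df["region"] == "B") & (df["id"].isin(members))]
        .groupby("length")["id"].count().to_dict()
    )
    assert got == {int(k): int(v) for k, v in expect.items()}


def test_unique_length_state_flagged_as_unique_within_parent():
    """All 19 in-clade ids share a 5 nt state absent outside the clade."""
    others = [f"out{i}" for i in range(20)]
    rows = [(i, "W", 5) for i in W_FIXTURE_IDS]
    rows += [(o, "W", 7 + (k % 3)) for k, o in enumerate(others)]
    table = _table(rows)
    clades = _clades(W_FIXTURE_IDS + others, **{"Naboidea+Cimicoidea": W_FIXTURE_IDS})
    cands = flag_synapomorphies(table, clades, min_share=0.9, outside_max_freq=0.5)
    assert len(cands) == 1
    c = cands[0]
    assert (c.clade, c.region, c.state_length) == ("Naboidea+Cimicoidea", "W", 5)
    assert c.n_in == 19 and c.n_exceptions == 0
    assert c.outside_freq == 0.0 and c.unique_within_parent


def test_split_state_not_flagged():
    rows = [("a", "B", 5), ("b", "B", 5), ("c", "B", 7), ("d", "B", 7),
            ("e", "B", 9), ("f", "B", 9)]
    table = _table(rows)
    clades = _clades("abcdef", X=["a", "b", "c", "d"])
    assert flag_synapomorphies(table, clades, min_share=0.9) == []


def test_exceptions_are_counted_not_hidden():
    members = [f"m{i}" for i in range(10)]
    rows = [(m, "B", 11) for m in members[:9]] + [("m9", "B", 10)]
    rows += [(f"o{i}", "B", 6) for i in range(10)]
    table = _table(rows)
    clades = _clades([r[0] for r in rows], P=members)
    (c,) = flag_synapomorphies(table, clades, min_share=0.9)
    assert (c.n_in, c.n_in_state, c.n_exceptions) == (10, 9, 1)


def test_min_share_must_be_majority():
    table = _table([("a", "B", 5)])
    clades = _clades("a", X=["a"])
    with pytest.raises(ValueError):
        flag_synapomorphies(table, clades, min_share=0.5)


def test_flags_match_brute_force_scan_on_random_tables():
    rng = np.random.default_rng(8)
    for _ in range(20):
        ids = [f"s{i}" for i in range(12)]
        rows = [(i, r, int(rng.integers(2, 6))) for i in ids for r in ("B", "C", "D")]
        table = _table(rows)
        clades = _clades(ids, X=ids[:4], Y=ids[4:10], Z=ids[2:8])
        cands = flag_synapomorphies(table, clades, min_share=0.75, outside_max_freq=0.4)
        got = {(c.clade, c.region, c.state_length) for c in cands}
        assert got == scan_brute(table, clades, 0.75, 0.4)


def test_flags_invariant_to_row_order_and_renaming():
    rng = np.random.default_rng(12)
    ids = [f"s{i}" for i in range(10)]
    rows = [(i, r, int(rng.integers(2, 5))) for i in ids for r in ("B", "C")]
    table = _table(rows)
    clades = _clades(ids, X=ids[:5])
    base = {(c.clade, c.region, c.state_length, c.n_in_state)
            for c in flag_synapomorphies(table, clades, min_share=0.8)}
    shuffled = _table(list(reversed(rows)))
    assert base == {(c.clade, c.region, c.state_length, c.n_in_state)
                    for c in flag_synapomorphies(shuffled, clades, min_share=0.8)}
    renamed_rows = [(f"x_{i}", r, L) for i, r, L in rows]
    renamed_table = _table(renamed_rows)
    renamed_clades = _clades([f"x_{i}" for i in ids], X=[f"x_{i}" for i in ids[:5]])
    renamed = {(c.region, c.state_length, c.n_in_state)
               for c in flag_synapomorphies(renamed_table, renamed_clades, min_share=0.8)}
    assert renamed == {(r, L, n) for _, r, L, n in base}


def test_tightening_thresholds_never_adds_flags():
    rng = np.random.default_rng(13)
    ids = [f"s{i}" for i in range(15)]
    rows = [(i, r, int(rng.integers(2, 6))) for i in ids for r in ("B", "C")]
    table = _table(rows)
    clades = _clades(ids, X=ids[:6], Y=ids[6:])
    loose = {(c.clade, c.region, c.state_length)
             for c in flag_synapomorphies(table, clades, 0.7, 0.6)}
    for ms, om in [(0.8, 0.6), (0.7, 0.3), (0.9, 0.1)]:
        tight = {(c.clade, c.region, c.state_length)
                 for c in flag_synapomorphies(table, clades, ms, om)}
        assert tight <= loose


def _cand(clade, region, L, n_in, n_exc=0):
    return SynapomorphyCandidate(
        clade=clade, region=region, state_length=L, n_in=n_in,
        n_in_state=n_in - n_exc, n_exceptions=n_exc,
        outside_freq=0.0, unique_within_parent=True,
    )


def test_report_rows_follow_table_convention():
    report = report_table([
        _cand("Neoheteroptera", "U", 9, 131),
        _cand("Acanthosomatidae+Lestoniidae", "D3-1", 5, 8),
    ])
    assert "9nt U (131)" in report
    assert "5nt D3-1 (8)" in report


def test_report_empty_is_header_only():
    report = report_table([])
    assert report.strip() == "Monophyletic group\tLVR (number of sequences examined)"


def test_candidates_frame_columns():
    df = candidates_frame([_cand("X", "B", 11, 39, n_exc=2)])
    assert df.loc[0, "n_exceptions"] == 2
    assert list(df.columns[:3]) == ["clade", "region", "state_length"]
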