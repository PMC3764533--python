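"""Stem-retention scoring, model ranking, and projection onto sequences."""

import numpy as np
import pytest

from rrnalvr.fold import PairRule, StructureError, dot_bracket
from rrnalvr.io import Msa
from rrnalvr.model import (
    Helix,
    StructureModel,
    model_score,
    random_model_like,
    retained_stem_length,
    select_model,
    sequence_structure_from_model,
)

from _oracles import retained_recount

WOB = PairRule.canonical_wobble()

# one 3-pair helix: columns (0,1,2) pair with (10,9,8)
ONE_HELIX = StructureModel(n_cols=11, helices=(Helix(side5=(0, 3), side3=(8, 11)),))


def test_retained_counts_allowed_pairs():
    # pairs formed: G-C, A-U, G-U  (all allowed under canonical+wobble)
    assert retained_stem_length(ONE_HELIX, "GAGAAAAAUUC", WOB) == 3


def test_gap_destroys_one_pair():
    assert retained_stem_length(ONE_HELIX, "GA-AAAAAUUC", WOB) == 2


def test_retained_length_mismatch_errors():
    with pytest.raises(ValueError):
        retained_stem_length(ONE_HELIX, "GAG", WOB)


def test_retained_matches_recount_on_random_models():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n_cols = int(rng.integers(12, 40))
        L = int(rng.integers(1, 4))
        s5 = int(rng.integers(0, n_cols - 2 * L - 3))
        s3 = int(rng.integers(s5 + L, n_cols - L))
        model = StructureModel(n_cols, (Helix((s5, s5 + L), (s3, s3 + L)),))
        chars = np.array(list("ACGU-"))
        row = "".join(rng.choice(chars, size=n_cols))
        assert retained_stem_length(model, row, WOB) == retained_recount(model, row, WOB)


def test_model_score_totals_and_min():
    msa = Msa.from_pairs([("a", "GAGAAAAAUUC"), ("b", "GAGAAAAAUUC")])
    sc = model_score(ONE_HELIX, msa)
    assert (sc.total, sc.min_per_row, sc.n_helices) == (6, 3, 1)
    per_row = [retained_stem_length(ONE_HELIX, s, WOB) for _, s in msa]
    assert sc.total == sum(per_row)


def test_model_score_empty_model():
    msa = Msa.from_pairs([("a", "GAGAAAAAUUC")])
    assert tuple(model_score(StructureModel(11, ()), msa)) == (0, 0, 0)


def test_select_model_by_total_then_min_then_helices_then_order():
    msa = Msa.from_pairs([("a", "GGGAAAACCC"), ("b", "GGGAAAACCC")])
    strong = StructureModel(10, (Helix((0, 3), (7, 10)),))
    weak = StructureModel(10, (Helix((3, 4), (6, 7)),))  # A-C, not allowed
    assert select_model([weak, strong], msa) is strong
    # all scores tied -> earliest in input order
    twin = StructureModel(10, (Helix((0, 3), (7, 10)),))
    assert select_model([strong, twin], msa) is strong


def test_select_model_ties_broken_by_min_per_row():
    # equal totals: X retained once by each row, Y twice by row a and never by b
    msa = Msa.from_pairs([("a", "GGGAAAAACCCC"), ("b", "G--AAAAACC-C")])
    m_x = StructureModel(12, (Helix((0, 1), (11, 12)),))
    m_y = StructureModel(12, (Helix((1, 3), (9, 11)),))
    sx, sy = model_score(m_x, msa), model_score(m_y, msa)
    assert sx.total == sy.total == 2  # construction check
    assert (sx.min_per_row, sy.min_per_row) == (1, 0)
    assert select_model([m_y, m_x], msa) is m_x


def test_select_model_empty_candidates_errors():
    msa = Msa.from_pairs([("a", "ACGU")])
    with pytest.raises(ValueError):
        select_model([], msa)


def test_select_model_invariant_to_row_permutation():
    rng = np.random.default_rng(3)
    msa = Msa.from_pairs(
        [(f"s{i}", "".join(rng.choice(list("ACGU-"), size=12))) for i in range(5)]
    )
    cands = [
        StructureModel(12, (Helix((0, 2), (10, 12)),)),
        StructureModel(12, (Helix((2, 4), (8, 10)),)),
        StructureModel(12, (Helix((1, 3), (9, 11)),)),
    ]
    best = select_model(cands, msa)
    perm = Msa(tuple(reversed(msa.rows)))
    assert select_model(cands, perm) is best


def test_adding_helix_never_decreases_total():
    rng = np.random.default_rng(11)
    msa = Msa.from_pairs(
        [(f"s{i}", "".join(rng.choice(list("ACGU-"), size=20))) for i in range(4)]
    )
    base = StructureModel(20, (Helix((0, 3), (17, 20)),))
    extended = StructureModel(20, base.helices + (Helix((5, 7), (12, 14)),))
    assert model_score(extended, msa).total >= model_score(base, msa).total


def test_projection_maps_to_sequence_positions():
    proj = sequence_structure_from_model(ONE_HELIX, "GAGAAAAAUUC")
    assert proj.structure.length == 11
    assert (0, 10) in proj.structure.pairs and not proj.noncanonical
    # a gap before the helix 3' side shifts positions left
    proj2 = sequence_structure_from_model(ONE_HELIX, "GAGAA-AAUUC")
    assert proj2.structure.length == 10
    assert (0, 9) in proj2.structure.pairs


def test_projection_drops_fully_gapped_side_and_flags_noncanonical():
    proj = sequence_structure_from_model(ONE_HELIX, "GAGAAAAA---")
    assert proj.structure.pairs == frozenset()
    # A-A pair retained but flagged as noncanonical
    proj2 = sequence_structure_from_model(ONE_HELIX, "AAAAAAAAAAA")
    assert proj2.structure.pairs == {(0, 10), (1, 9), (2, 8)}
    assert proj2.noncanonical == {(0, 10), (1, 9), (2, 8)}


def test_projection_dot_bracket_length_bookkeeping():
    row = "GA-GAAAAUUC"
    proj = sequence_structure_from_model(ONE_HELIX, row)
    assert len(dot_bracket(proj.structure)) == len(row.replace("-", ""))


def test_column_pseudoknot_rejected():
    with pytest.raises(StructureError):
        StructureModel(12, (Helix((0, 2), (6, 8)), Helix((3, 5), (9, 11))))


def test_random_model_like_preserves_helix_lengths():
    rng = np.random.default_rng(0)
    model = StructureModel(40, (Helix((0, 5), (35, 40)), Helix((10, 13), (20, 23))))
    for _ in range(20):
        rival = random_model_like(model, rng)
        assert sorted(h.length for h in rival.helices) == sorted(
            h.length for h in model.helices
        )
        assert rival.n_cols == model.n_cols
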