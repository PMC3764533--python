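"""Consensus secondary-structure models on alignment columns, and model
selection by the co-variation (stem-retention) criterion.

A consensus model is a list of helices defined on alignment columns. The
selection principle used throughout comparative rRNA work is qualitative —
the best model is the one whose paired regions are least disrupted across the
homologous sequences, because compensatory substitutions preserve pairing.
Here it is made operational as a ranking: maximize the total number of
retained paired columns over all rows, break ties by the worst-supported row
(larger minimum per-row retention), then by parsimony (fewer helices), then
by input order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .fold import DEFAULT_RULE, PairRule, SecondaryStructure, StructureError
from .io import GAP, Msa, RegionMap


@dataclass(frozen=True)
class Helix:
    """A consensus helix: the k-th column of ``side5`` pairs with the
    (len-1-k)-th column of ``side3``. Intervals are 0-based half-open and
    ``side5`` lies entirely left of ``side3``."""

    side5: tuple[int, int]
    side3: tuple[int, int]

    def __post_init__(self) -> None:
        (s5, e5), (s3, e3) = self.side5, self.side3
        if not (0 <= s5 < e5 <= s3 < e3):
            raise StructureError(f"bad helix geometry side5={self.side5} side3={self.side3}")
        if e5 - s5 != e3 - s3:
            raise StructureError("helix sides of unequal length")

    @property
    def length(self) -> int:
        return self.side5[1] - self.side5[0]

    def column_pairs(self) -> list[tuple[int, int]]:
        (s5, _), (_, e3) = self.side5, self.side3
        return [(s5 + k, e3 - 1 - k) for k in range(self.length)]


@dataclass(frozen=True)
class StructureModel:
    """Consensus helices on ``n_cols`` alignment columns, optionally with a
    labeled region map."""

    n_cols: int
    helices: tuple[Helix, ...]
    region_map: RegionMap | None = None

    def __post_init__(self) -> None:
        pairs = self.column_pairs()
        used: set[int] = set()
        for a, b in pairs:
            if b >= self.n_cols:
                raise StructureError(f"helix column {b} outside alignment of {self.n_cols}")
            if a in used or b in used:
                raise StructureError(f"column used by two helices near pair {(a, b)}")
            used.update((a, b))
        ordered = sorted(pairs)
        for x in range(len(ordered)):
            i, j = ordered[x]
            for y in range(x + 1, len(ordered)):
                k, l = ordered[y]
                if k > j:
                    break
                if i < k < j < l:
                    raise StructureError(
                        f"column-level pseudoknot between pairs {(i, j)} and {(k, l)}"
                    )

    def column_pairs(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for h in self.helices:
            out.extend(h.column_pairs())
        return out

    def ss_cons(self) -> str:
        """Column-level dot-bracket consensus line (for Stockholm output)."""
        chars = ["."] * self.n_cols
        for a, b in self.column_pairs():
            chars[a] = "("
            chars[b] = ")"
        return "".join(chars)


class ModelScore(NamedTuple):
    total: int
    min_per_row: int
    n_helices: int


class ProjectedStructure(NamedTuple):
    """A column model projected onto one (ungapped) sequence. ``noncanonical``
    flags the retained pairs whose residues the rule disallows — they are kept
    in the structure, as curated diagrams keep them with distinct symbols."""

    structure: SecondaryStructure
    noncanonical: frozenset[tuple[int, int]]


def retained_stem_length(
    model: StructureModel, row: str, rule: PairRule = DEFAULT_RULE
) -> int:
    """Number of model column-pairs this aligned row retains: both columns
    hold non-gap residues and the residue pair is allowed by ``rule``."""
    if len(row) != model.n_cols:
        raise ValueError(
            f"row length {len(row)} does not match model n_cols {model.n_cols}"
        )
    kept = 0
    for a, b in model.column_pairs():
        x, y = row[a], row[b]
        if x != GAP and y != GAP and rule.allows(x, y):
            kept += 1
    return kept


def model_score(
    model: StructureModel, msa: Msa, rule: PairRule = DEFAULT_RULE
) -> ModelScore:
    """Total retained paired columns over all rows, the per-row minimum, and
    the helix count."""
    if msa.n_cols != model.n_cols:
        raise ValueError(
            f"msa n_cols {msa.n_cols} does not match model n_cols {model.n_cols}"
        )
    if not model.helices:
        return ModelScore(0, 0, 0)
    per_row = [retained_stem_length(model, s, rule) for _, s in msa]
    return ModelScore(sum(per_row), min(per_row, default=0), len(model.helices))


def select_model(
    candidates: Sequence[StructureModel], msa: Msa, rule: PairRule = DEFAULT_RULE
) -> StructureModel:
    """Rank candidate models by the co-variation criterion and return the best.

    Ordering: larger total retained stem length, then larger minimum per-row
    retention, then fewer helices, then earliest in input order. Candidates
    are not modified.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    best = candidates[0]
    best_key = None
    for cand in candidates:
        sc = model_score(cand, msa, rule)
        key = (sc.total, sc.min_per_row, -sc.n_helices)
        if best_key is None or key > best_key:
            best, best_key = cand, key
    return best


def sequence_structure_from_model(
    model: StructureModel, row: str, rule: PairRule = DEFAULT_RULE
) -> ProjectedStructure:
    """Project a column-level model onto one aligned row.

    Column pairs with a gap on either side are dropped; the rest are mapped to
    ungapped sequence positions. Pairs whose residues the rule disallows are
    retained but flagged in ``noncanonical``.
    """
    if len(row) != model.n_cols:
        raise ValueError(
            f"row length {len(row)} does not match model n_cols {model.n_cols}"
        )
    # seq position of each non-gap column
    seq_pos: list[int | None] = []
    p = 0
    for c in row:
        if c == GAP:
            seq_pos.append(None)
        else:
            seq_pos.append(p)
            p += 1
    pairs: set[tuple[int, int]] = set()
    flagged: set[tuple[int, int]] = set()
    for a, b in model.column_pairs():
        pa, pb = seq_pos[a], seq_pos[b]
        if pa is None or pb is None:
            continue
        pairs.add((pa, pb))
        if not rule.allows(row[a], row[b]):
            flagged.add((pa, pb))
    return ProjectedStructure(
        SecondaryStructure(p, frozenset(pairs)), frozenset(flagged)
    )


# ---------------------------------------------------------------------------
# Random rival models (null models for selection experiments)


def random_model_like(
    model: StructureModel, rng: np.random.Generator
) -> StructureModel:
    """A random model with the same helix-length multiset on the same columns.

    Helix sides are placed as ordered disjoint intervals (each helix's 5' side
    immediately preceding its 3' side along the alignment), which is always a
    valid pseudoknot-free configuration; the inter-interval spacings are drawn
    at random.
    """
    lens: list[int] = []
    for h in model.helices:
        lens.extend([h.length, h.length])
    total = sum(lens)
    slack = model.n_cols - total
    if slack < 0:
        raise ValueError("model helices do not fit in n_cols")
    gaps = rng.multinomial(slack, np.full(len(lens) + 1, 1.0 / (len(lens) + 1)))
    starts: list[int] = []
    pos = 0
    for g, L in zip(gaps[:-1], lens):
        pos += int(g)
        starts.append(pos)
        pos += L
    helices = []
    it = iter(range(0, len(lens), 2))
    for m, h in zip(it, model.helices):
        L = h.length
        helices.append(
            Helix(side5=(starts[m], starts[m] + L), side3=(starts[m + 1], starts[m + 1] + L))
        )
    return StructureModel(n_cols=model.n_cols, helices=tuple(helices))


# ---------------------------------------------------------------------------
# Model files: CSV helix tables

_MODEL_HEADER = ["side5_start", "side5_end", "side3_start", "side3_end"]


def write_model_csv(model: StructureModel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# n_cols={model.n_cols}  (alignment columns, 0-based, half-open)\n")
        w = csv.writer(fh)
        w.writerow(_MODEL_HEADER)
        for h in model.helices:
            w.writerow([h.side5[0], h.side5[1], h.side3[0], h.side3[1]])


def read_model_csv(path: str | Path, n_cols: int | None = None) -> StructureModel:
    helices: list[Helix] = []
    file_n_cols = None
    with open(path, newline="") as fh:
        rows = []
        for r in csv.reader(fh):
            if not r:
                continue
            if r[0].startswith("#"):
                if "n_cols=" in r[0]:
                    file_n_cols = int(r[0].split("n_cols=")[1].split()[0])
                continue
            rows.append(r)
    if not rows or [c.strip() for c in rows[0]] != _MODEL_HEADER:
        raise StructureError(f"model file {path}: expected header {','.join(_MODEL_HEADER)}")
    for r in rows[1:]:
        s5, e5, s3, e3 = (int(x) for x in r[:4])
        helices.append(Helix(side5=(s5, e5), side3=(s3, e3)))
    if n_cols is None:
        n_cols = file_n_cols
    if n_cols is None:
        n_cols = max((h.side3[1] for h in helices), default=0)
    return StructureModel(n_cols=n_cols, helices=tuple(helices))
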