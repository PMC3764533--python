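"""Pseudoknot-free secondary-structure prediction for LVR subsequences.

Expansion-segment (LVR) structures are short, hairpin-dominated elements, so a
base-pair maximization dynamic program in the style of Nussinov is used: the
primary objective is the number of base pairs, and ties are broken by the
number of stacked pairs (pairs ``(i, j)`` whose inner neighbor ``(i+1, j-1)``
is also paired), which favors contiguous helices over scattered isolated
pairs. Full nearest-neighbor free-energy minimization is deliberately out of
scope; users who want an external thermodynamic folder can feed its
dot-bracket output back in through :func:`parse_dot_bracket`.

Pairing rules follow the usual rRNA drawing conventions: canonical Watson–
Crick pairs (G–C, A–U), the G·U wobble pair, and — only when explicitly
enabled — the noncanonical A:G / A:C classes seen in curated diagrams.
``N`` never pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

Pair = tuple[int, int]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


class StructureError(ValueError):
    """Invalid secondary structure or dot-bracket string."""


def _pairset(pairs: Iterable[tuple[str, str]]) -> frozenset[frozenset[str]]:
    return frozenset(frozenset(p) for p in pairs)


@dataclass(frozen=True)
class PairRule:
    """A named set of allowed unordered residue pairs."""

    name: str
    allowed: frozenset[frozenset[str]]

    def allows(self, x: str, y: str) -> bool:
        if x == "N" or y == "N":
            return False
        return frozenset((x, y)) in self.allowed

    @classmethod
    def canonical(cls) -> "PairRule":
        return cls("canonical", _pairset([("A", "U"), ("G", "C")]))

    @classmethod
    def canonical_wobble(cls) -> "PairRule":
        return cls(
            "canonical+wobble", _pairset([("A", "U"), ("G", "C"), ("G", "U")])
        )

    @classmethod
    def extended(cls, extra: Iterable[tuple[str, str]] = ()) -> "PairRule":
        """Canonical + wobble + the A:G / A:C noncanonical classes, plus any
        explicitly enabled extra pairs (including self pairs such as A:A)."""
        base = [("A", "U"), ("G", "C"), ("G", "U"), ("A", "G"), ("A", "C")]
        return cls("extended", _pairset(base) | _pairset(extra))


DEFAULT_RULE = PairRule.canonical_wobble()


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs ``(i, j)``, ``i < j``, on sequence
    positions of a sequence of the given length."""

    length: int
    pairs: frozenset[Pair]

    def __post_init__(self) -> None:
        used: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise StructureError(f"pair {(i, j)} outside sequence of length {self.length}")
            if i in used or j in used:
                raise StructureError(f"position in more than one pair near {(i, j)}")
            used.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for b in range(a + 1, len(ordered)):
                k, l = ordered[b]
                if k > j:
                    break
                if i < k < j < l:
                    raise StructureError(f"pseudoknot between {(i, j)} and {(k, l)}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def n_stacked(self) -> int:
        return sum(1 for i, j in self.pairs if (i + 1, j - 1) in self.pairs)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Dynamic programming


def _tables(seq: str, rule: PairRule, min_loop: int):
    """Fill interval tables.

    ``P[i][j]``: best ``(pairs, stacks)`` among structures of ``seq[i..j]``
    in which ``(i, j)`` is a pair (``None`` if ``(i, j)`` cannot pair).
    ``F[i][j]``: best ``(pairs, stacks)`` over all structures of ``seq[i..j]``.
    """
    n = len(seq)
    F = [[(0, 0)] * n for _ in range(n)]
    P: list[list[tuple[int, int] | None]] = [[None] * n for _ in range(n)]
    for j in range(n):
        for i in range(j, -1, -1):
            if j - i - 1 >= min_loop and rule.allows(seq[i], seq[j]):
                ip, jm = i + 1, j - 1
                inner = F[ip][jm] if ip <= jm else (0, 0)
                if ip <= jm and P[ip][jm] is not None:
                    stacked = (P[ip][jm][0], P[ip][jm][1] + 1)
                    if stacked > inner:
                        inner = stacked
                P[i][j] = (1 + inner[0], inner[1])
            best = F[i + 1][j] if i + 1 <= j else (0, 0)
            for k in range(i + min_loop + 1, j + 1):
                pk = P[i][k]
                if pk is None:
                    continue
                rest = F[k + 1][j] if k + 1 <= j else (0, 0)
                cand = (pk[0] + rest[0], pk[1] + rest[1])
                if cand > best:
                    best = cand
            F[i][j] = best
    return F, P


def fold_max_pairs(
    seq: str, rule: PairRule = DEFAULT_RULE, min_loop: int = 3
) -> SecondaryStructure:
    """Fold ``seq`` by base-pair maximization with stacking tie-break.

    Deterministic traceback: at the leftmost undecided position, pairing is
    preferred over leaving it unpaired, with the smallest admissible partner
    taken first; inside a pair, the stacked continuation is preferred on ties.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        return SecondaryStructure(0, frozenset())
    F, P = _tables(seq, rule, min_loop)
    pairs: set[Pair] = set()

    def trace_P(i: int, j: int) -> None:
        pairs.add((i, j))
        ip, jm = i + 1, j - 1
        if ip > jm:
            return
        target = (P[i][j][0] - 1, P[i][j][1])
        if P[ip][jm] is not None and (P[ip][jm][0], P[ip][jm][1] + 1) == target:
            trace_P(ip, jm)
        else:
            trace_F(ip, jm)

    def trace_F(i: int, j: int) -> None:
        while i <= j:
            target = F[i][j]
            if target == (0, 0):
                return
            chosen = None
            for k in range(i + min_loop + 1, j + 1):
                pk = P[i][k]
                if pk is None:
                    continue
                rest = F[k + 1][j] if k + 1 <= j else (0, 0)
                if (pk[0] + rest[0], pk[1] + rest[1]) == target:
                    chosen = k
                    break
            if chosen is None:
                i += 1
                continue
            trace_P(i, chosen)
            i = chosen + 1

    trace_F(0, n - 1)
    return SecondaryStructure(n, frozenset(pairs))


def enumerate_cooptimal(
    seq: str,
    rule: PairRule = DEFAULT_RULE,
    min_loop: int = 3,
    max_structures: int = 100,
) -> list[SecondaryStructure]:
    """All structures achieving the optimal base-pair count, in lexicographic
    order of their sorted pair lists, truncated to ``max_structures``.

    Intended for short subsequences (LVRs); the co-optimal set can grow
    exponentially with length, so collection is capped internally.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        return [SecondaryStructure(0, frozenset())]
    # pair-count-only table
    N = [[0] * n for _ in range(n)]
    for j in range(n):
        for i in range(j, -1, -1):
            best = N[i + 1][j] if i + 1 <= j else 0
            for k in range(i + min_loop + 1, j + 1):
                if rule.allows(seq[i], seq[k]):
                    inner = N[i + 1][k - 1] if i + 1 <= k - 1 else 0
                    rest = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + rest)
            N[i][j] = best

    cap = max(max_structures, 4096)
    out: list[frozenset[Pair]] = []

    def emit(i: int, j: int):
        """Yield the pair sets of all optimal structures of seq[i..j].

        Each structure arises from exactly one derivation (decide the fate of
        the leftmost position), so no deduplication is needed.
        """
        if i > j:
            yield frozenset()
            return
        target = N[i][j]
        if (N[i + 1][j] if i + 1 <= j else 0) == target:
            yield from emit(i + 1, j)
        if target == 0:
            return
        for k in range(i + min_loop + 1, j + 1):
            if not rule.allows(seq[i], seq[k]):
                continue
            inner = N[i + 1][k - 1] if i + 1 <= k - 1 else 0
            rest = N[k + 1][j] if k + 1 <= j else 0
            if 1 + inner + rest != target:
                continue
            for s1 in emit(i + 1, k - 1):
                for s2 in emit(k + 1, j):
                    yield frozenset({(i, k)}) | s1 | s2

    for ps in emit(0, n - 1):
        out.append(ps)
        if len(out) >= cap:
            break
    out.sort(key=lambda ps: sorted(ps))
    return [SecondaryStructure(n, ps) for ps in out[:max_structures]]


# ---------------------------------------------------------------------------
# Dot-bracket


def dot_bracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.length
    for i, j in structure.pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def parse_dot_bracket(s: str) -> SecondaryStructure:
    """Parse a dot-bracket string; unpaired positions are ``.`` (``,``, ``:``,
    ``_`` and ``-`` are accepted as unpaired, covering WUSS-ish output)."""
    stack: list[int] = []
    pairs: set[Pair] = set()
    for pos, c in enumerate(s):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c in ".,:_-~":
            continue
        else:
            raise StructureError(f"unexpected character {c!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[0]}")
    return SecondaryStructure(len(s), frozenset(pairs))


# ---------------------------------------------------------------------------
# Vienna 2-line records (header, sequence, structure)


def write_vienna(
    records: Sequence[tuple[str, str, SecondaryStructure]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, seq, structure in records:
            fh.write(f">{name}\n{seq}\n{dot_bracket(structure)}\n")


def read_vienna(path: str | Path) -> list[tuple[str, str, SecondaryStructure]]:
    out = []
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"expected '>' header at line {i + 1}")
        name = lines[i][1:].strip()
        seq = lines[i + 1]
        structure = parse_dot_bracket(lines[i + 2])
        if structure.length != len(seq):
            raise StructureError(f"record {name!r}: structure/sequence length mismatch")
        out.append((name, seq, structure))
        i += 3
    return out
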