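"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations, structurally unrelated to the
package's dynamic programs: exhaustive enumeration of secondary structures,
exhaustive enumeration of pairwise alignments with affine gap scoring, and a
triple-loop synapomorphy scan.
"""

from __future__ import annotations

from typing import Iterator

GAP = "-"


def all_structures(seq: str, rule, min_loop: int) -> Iterator[frozenset]:
    """Every valid pseudoknot-free structure (as a frozenset of pairs)."""

    def rec(positions: tuple[int, ...]) -> Iterator[frozenset]:
        if not positions:
            yield frozenset()
            return
        i = positions[0]
        rest = positions[1:]
        yield from rec(rest)  # i unpaired
        for j in rest:
            if j - i - 1 >= min_loop and rule.allows(seq[i], seq[j]):
                inside = tuple(p for p in rest if i < p < j)
                outside = tuple(p for p in rest if p > j)
                for s1 in rec(inside):
                    for s2 in rec(outside):
                        yield frozenset({(i, j)}) | s1 | s2

    return rec(tuple(range(len(seq))))


def max_pairs_brute(seq: str, rule, min_loop: int) -> int:
    return max(len(s) for s in all_structures(seq, rule, min_loop))


def cooptimal_brute(seq: str, rule, min_loop: int) -> set[frozenset]:
    structs = list(all_structures(seq, rule, min_loop))
    best = max(len(s) for s in structs)
    return {s for s in structs if len(s) == best}


def affine_alignment_score(aligned_a: str, aligned_b: str,
                           match: float, mismatch: float,
                           gap_open: float, gap_extend: float) -> float:
    """Score one gapped alignment; a gap run of length L costs
    open + (L-1)*extend, terminal gaps included."""
    score = 0.0
    prev = "M"
    for x, y in zip(aligned_a, aligned_b):
        if x != GAP and y != GAP:
            score += match if x == y else mismatch
            prev = "M"
        elif y == GAP:
            score += gap_extend if prev == "A" else gap_open
            prev = "A"
        else:
            score += gap_extend if prev == "B" else gap_open
            prev = "B"
    return score


def best_alignment_brute(a: str, b: str, match: float, mismatch: float,
                         gap_open: float, gap_extend: float) -> float:
    """Max score over ALL global alignments of a and b (exhaustive)."""
    best = [float("-inf")]

    def rec(i: int, j: int, ca: list[str], cb: list[str]) -> None:
        if i == len(a) and j == len(b):
            s = affine_alignment_score("".join(ca), "".join(cb),
                                       match, mismatch, gap_open, gap_extend)
            if s > best[0]:
                best[0] = s
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ca + [a[i]], cb + [b[j]])
        if i < len(a):
            rec(i + 1, j, ca + [a[i]], cb + [GAP])
        if j < len(b):
            rec(i, j + 1, ca + [GAP], cb + [b[j]])

    rec(0, 0, [], [])
    return best[0]


def scan_brute(table, clades, min_share: float, outside_max: float) -> set[tuple]:
    """Triple-loop synapomorphy scan: every (clade, region, length)."""
    df = table.frame
    all_ids = set(df["id"].unique())
    flags = set()
    for clade in clades.clades:
        members = set(clades.members(clade))
        outside = all_ids - members
        for region in df["region"].unique():
            sub = df[df["region"] == region]
            in_lengths = [int(l) for i, l in zip(sub["id"], sub["length"]) if i in members]
            out_lengths = [int(l) for i, l in zip(sub["id"], sub["length"]) if i in outside]
            for L in set(in_lengths):
                share = in_lengths.count(L) / len(in_lengths)
                ofreq = out_lengths.count(L) / len(out_lengths) if out_lengths else 0.0
                if share >= min_share and ofreq <= outside_max:
                    flags.add((clade, region, L))
    return flags


def retained_recount(model, row, rule) -> int:
    """Position-by-position recount of retained model pairs for one row."""
    kept = 0
    for h in model.helices:
        (s5, e5), (s3, e3) = h.side5, h.side3
        L = e5 - s5
        for k in range(L):
            a, b = s5 + k, e3 - 1 - k
            if row[a] != GAP and row[b] != GAP and rule.allows(row[a], row[b]):
                kept += 1
    return kept
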