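"""Scan named clades for LVR length states that are (near-)invariant inside
the clade and rare outside it — candidate molecular synapomorphies.

The scan is deliberately descriptive, not probabilistic: a state is flagged
when its share within the clade reaches ``min_share`` and its frequency among
non-clade sequences stays at or below ``outside_max_freq``. No ancestral-state
reconstruction and no significance test is attempted; the output is the raw
material for a comparative table ("9nt U (131)"-style rows), with exceptions
counted rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .delimit import LvrLengthTable
from .io import CladeMap


@dataclass(frozen=True)
class SynapomorphyCandidate:
    """One flagged (clade, region, length-state) triple.

    ``n_in`` counts clade sequences examined, ``n_in_state`` those showing the
    state, ``n_exceptions = n_in - n_in_state``; ``outside_freq`` is the share
    of non-clade sequences with the same length; ``unique_within_parent`` is
    true when no sequence outside the clade shows the state at all.
    """

    clade: str
    region: str
    state_length: int
    n_in: int
    n_in_state: int
    n_exceptions: int
    outside_freq: float
    unique_within_parent: bool

    def __post_init__(self) -> None:
        if self.n_in_state + self.n_exceptions != self.n_in:
            raise ValueError("n_in_state + n_exceptions must equal n_in")
        if not 0.0 <= self.outside_freq <= 1.0:
            raise ValueError("outside_freq outside [0, 1]")


def state_distribution(
    table: LvrLengthTable, clade_members: Iterable[str], region: str
) -> dict[int, int]:
    """Length -> count over the clade members, for one region."""
    members = set(clade_members)
    if region not in table.regions:
        raise KeyError(f"unknown region {region!r}")
    df = table.frame
    sel = df[(df["region"] == region) & (df["id"].isin(members))]
    missing = members - set(sel["id"])
    if missing:
        raise KeyError(f"clade member(s) absent from length table: {sorted(missing)}")
    counts = sel["length"].value_counts()
    return {int(k): int(v) for k, v in counts.items()}


def flag_synapomorphies(
    table: LvrLengthTable,
    clades: CladeMap,
    min_share: float = 0.9,
    outside_max_freq: float = 0.5,
) -> list[SynapomorphyCandidate]:
    """Flag every (clade, region, L) with in-clade share of L >= ``min_share``
    and outside frequency of L <= ``outside_max_freq``.

    ``min_share`` must exceed 0.5 (a majority is required for a meaningful
    state, and it guarantees at most one flagged length per clade and region).
    Output is sorted by clade then region.
    """
    if min_share <= 0.5:
        raise ValueError(f"min_share must exceed 0.5, got {min_share}")
    all_ids = set(table.ids)
    out: list[SynapomorphyCandidate] = []
    for clade in sorted(clades.clades):
        members = set(clades.members(clade))
        n_in = len(members)
        outside = all_ids - members
        for region in sorted(table.regions):
            dist = state_distribution(table, members, region)
            for L, n_state in sorted(dist.items()):
                if n_state / n_in < min_share:
                    continue
                if outside:
                    df = table.frame
                    sel = df[(df["region"] == region) & (df["id"].isin(outside))]
                    n_out_state = int((sel["length"] == L).sum())
                    outside_freq = n_out_state / len(outside)
                else:
                    outside_freq = 0.0
                if outside_freq > outside_max_freq:
                    continue
                out.append(
                    SynapomorphyCandidate(
                        clade=clade,
                        region=region,
                        state_length=L,
                        n_in=n_in,
                        n_in_state=n_state,
                        n_exceptions=n_in - n_state,
                        outside_freq=outside_freq,
                        unique_within_parent=(outside_freq == 0.0),
                    )
                )
    return out


def candidates_frame(candidates: Sequence[SynapomorphyCandidate]) -> pd.DataFrame:
    cols = [
        "clade", "region", "state_length", "n_in", "n_in_state",
        "n_exceptions", "outside_freq", "unique_within_parent",
    ]
    return pd.DataFrame(
        [{c: getattr(cand, c) for c in cols} for cand in candidates], columns=cols
    )


def _cell(c: SynapomorphyCandidate) -> str:
    s = f"{c.state_length}nt {c.region} ({c.n_in})"
    if c.n_exceptions:
        s += f" [{c.n_exceptions} exception{'s' if c.n_exceptions != 1 else ''}]"
    return s


def report_table(candidates: Sequence[SynapomorphyCandidate]) -> str:
    """Plain-text comparative table: one row per clade, cells rendered as
    "<L>nt <region> (<n sequences examined>)", exceptions appended."""
    lines = ["Monophyletic group\tLVR (number of sequences examined)"]
    by_clade: dict[str, list[SynapomorphyCandidate]] = {}
    for c in candidates:
        by_clade.setdefault(c.clade, []).append(c)
    for clade in sorted(by_clade):
        cells = "; ".join(_cell(c) for c in by_clade[clade])
        lines.append(f"{clade}\t{cells}")
    return "\n".join(lines) + "\n"
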