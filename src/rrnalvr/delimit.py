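"""Delimit length-variable regions (LVRs) from a multiple alignment and
tabulate per-sequence LVR lengths.

LVRs are *length*-variable: what distinguishes them from length-conservative
blocks is the presence of gaps, not substitution variability. Delimitation is
therefore gap-driven — a column is variable when its gap fraction exceeds a
threshold — while per-column residue entropy is computed and reported but not
used for delimitation by default. Variable runs separated by conserved runs
shorter than ``min_conserved_block`` are merged (real LVRs are interspaced by
several *short* length-conservative stretches), and merged runs shorter than
``min_lvr_cols`` are discarded as scattered indels rather than bona fide LVRs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import GAP, FormatError, Msa, RegionMap


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column gap fraction, residue entropy (bits, over non-gap A/C/G/U),
    and the variable-column flag."""

    gap_fraction: np.ndarray
    entropy: np.ndarray
    is_variable: np.ndarray
    gap_threshold: float

    @property
    def n_cols(self) -> int:
        return len(self.gap_fraction)


def column_profile(msa: Msa, gap_threshold: float = 0.2) -> ColumnProfile:
    """Profile every alignment column; ``is_variable = gap_fraction > gap_threshold``."""
    if not 0 < gap_threshold < 1:
        raise ValueError(f"gap_threshold must be in (0, 1), got {gap_threshold}")
    mat = np.array([list(s) for _, s in msa])
    gap_fraction = (mat == GAP).mean(axis=0)
    counts = np.stack([(mat == base).sum(axis=0) for base in "ACGU"], axis=0).astype(float)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -(p * logp).sum(axis=0)
    return ColumnProfile(
        gap_fraction=gap_fraction,
        entropy=entropy,
        is_variable=gap_fraction > gap_threshold,
        gap_threshold=gap_threshold,
    )


_ALPHA_LABELS = string.ascii_uppercase[1:]  # B..Z; A is reserved/absent by convention


def _labels(scheme: str, n: int) -> list[str]:
    if scheme == "alpha":
        if n > len(_ALPHA_LABELS):
            raise ValueError(f"alpha scheme supports at most {len(_ALPHA_LABELS)} regions")
        return list(_ALPHA_LABELS[:n])
    if scheme == "d":
        return [f"D{k}" for k in range(2, 2 + n)]
    if scheme.startswith("sub:"):
        parent = scheme.split(":", 1)[1]
        return [f"{parent}-{k}" for k in range(1, n + 1)]
    raise ValueError(f"unknown label scheme {scheme!r}")


def delimit_lvrs(
    profile: ColumnProfile,
    min_conserved_block: int = 5,
    min_lvr_cols: int = 2,
    label_scheme: str = "alpha",
) -> RegionMap:
    """Maximal runs of variable columns, absorbing conserved interruptions
    shorter than ``min_conserved_block``, kept when spanning at least
    ``min_lvr_cols`` columns.

    Label schemes: ``"alpha"`` (B, C, D, ... along the alignment, the 18S
    convention), ``"d"`` (D2, D3, ... the 28S divergent-domain convention), or
    ``"sub:<parent>"`` (``<parent>-1``, ``<parent>-2``, ... for subdividing a
    single divergent domain such as D3).
    """
    var = np.asarray(profile.is_variable, dtype=bool)
    runs: list[list[int]] = []  # [start, end) of variable runs
    c = 0
    n = len(var)
    while c < n:
        if var[c]:
            s = c
            while c < n and var[c]:
                c += 1
            runs.append([s, c])
        else:
            c += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_conserved_block:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kept = [(s, e) for s, e in merged if e - s >= min_lvr_cols]
    labels = _labels(label_scheme, len(kept))
    return RegionMap(tuple((lab, s, e) for lab, (s, e) in zip(labels, kept)))


@dataclass(frozen=True)
class LvrLengthTable:
    """Per (sequence x region) ungapped lengths — the substrate of the
    synapomorphy scan. The frame holds the complete cross product of ids and
    region labels (no missing cells); ``N`` residues count toward lengths."""

    frame: pd.DataFrame  # columns: id, region, length

    def __post_init__(self) -> None:
        df = self.frame
        required = ["id", "region", "length"]
        if list(df.columns[:3]) != required:
            raise FormatError(f"length table must have columns {required}")
        if (df["length"] < 0).any():
            raise FormatError("negative region length")
        ids = df["id"].unique()
        regions = df["region"].unique()
        if len(df) != len(ids) * len(regions) or df.duplicated(["id", "region"]).any():
            raise FormatError("length table is not a complete id x region cross product")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.frame["id"].unique())

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.frame["region"].unique())

    def length(self, rid: str, region: str) -> int:
        sel = self.frame[(self.frame["id"] == rid) & (self.frame["region"] == region)]
        if sel.empty:
            raise KeyError((rid, region))
        return int(sel["length"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LvrLengthTable":
        df = pd.read_csv(path, comment="#", dtype={"id": str, "region": str})
        return cls(df[["id", "region", "length"]])


def lvr_lengths(msa: Msa, region_map: RegionMap) -> LvrLengthTable:
    """Ungapped residue count of every row within every region's columns."""
    for lab, s, e in region_map:
        if e > msa.n_cols:
            raise ValueError(f"region {lab!r} outside alignment of {msa.n_cols} columns")
    rows = []
    for rid, aligned in msa:
        for lab, s, e in region_map:
            seg = aligned[s:e]
            rows.append(
                {"id": rid, "region": lab, "length": len(seg) - seg.count(GAP)}
            )
    return LvrLengthTable(pd.DataFrame(rows, columns=["id", "region", "length"]))


def check_no_overlap(region_maps: Iterable[RegionMap]) -> bool:
    """True iff all (non-empty) intervals across the given maps are pairwise
    disjoint — adjacent LVR domains must not overlap on the alignment."""
    intervals = sorted(
        (s, e)
        for rmap in region_maps
        for _, s, e in rmap
        if e > s
    )
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            return False
    return True
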