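"""Readers/writers for every external representation the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`RnaSequence`, :class:`Msa`, :class:`CladeMap`, :class:`RegionMap`.

Conventions (used package-wide):

* sequence and alignment coordinates are 0-based; intervals are half-open
  ``[start, end)``;
* RNA alphabet is ``{A, C, G, U, N}``; DNA input is transcribed (``T`` -> ``U``)
  and case-folded on read; ``N`` is a real residue (it counts toward lengths)
  but never pairs;
* alignment gap characters ``.`` and ``-`` are normalized to ``-``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGUN")
GAP = "-"
GAPPED_ALPHABET = RNA_ALPHABET | {GAP}


class FormatError(ValueError):
    """Malformed external input (bad FASTA, ragged alignment, overlapping regions...)."""


def normalize_residues(raw: str) -> str:
    """Uppercase, strip whitespace, transcribe T->U."""
    return "".join(raw.split()).upper().replace("T", "U")


def _normalize_aligned(raw: str) -> str:
    return normalize_residues(raw).replace(".", GAP)


@dataclass(frozen=True)
class RnaSequence:
    """One homologous rRNA sequence with taxon metadata.

    ``id`` is an accession-like string, unique within a dataset; ``taxon`` is
    the terminal taxon name used by clade maps (defaults to ``id``).
    """

    id: str
    residues: str
    taxon: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: characters {sorted(bad)} outside alphabet A,C,G,U,N"
            )
        if not self.taxon:
            object.__setattr__(self, "taxon", self.id)

    @classmethod
    def from_raw(cls, id: str, raw: str, taxon: str = "", description: str = "") -> "RnaSequence":
        return cls(id=id, residues=normalize_residues(raw), taxon=taxon, description=description)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Msa:
    """Aligned sequences: ordered ``(id, aligned-string)`` rows of equal length."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            detail = ", ".join(f"{i}={len(s)}" for i, s in self.rows)
            raise FormatError(f"ragged alignment rows (id=length): {detail}")
        seen: set[str] = set()
        for rid, s in self.rows:
            if rid in seen:
                raise FormatError(f"duplicate row id {rid!r}")
            seen.add(rid)
            bad = set(s) - GAPPED_ALPHABET
            if bad:
                raise FormatError(f"row {rid!r}: characters {sorted(bad)} outside gapped alphabet")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Msa":
        return cls(tuple((rid, _normalize_aligned(s)) for rid, s in pairs))

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.rows)


@dataclass(frozen=True)
class CladeMap:
    """Named groups of terminal taxa (the scan units: infraorders, superfamily
    unions like ``Naboidea+Cimicoidea``, family pairs...).

    ``ranks`` optionally records taxon -> (family, superfamily, infraorder).
    """

    terminals: frozenset[str]
    clades: Mapping[str, frozenset[str]]
    ranks: Mapping[str, tuple[str, str, str]] | None = None

    def __post_init__(self) -> None:
        for name, members in self.clades.items():
            if not members:
                raise FormatError(f"clade {name!r} is empty")
            unknown = members - self.terminals
            if unknown:
                raise FormatError(
                    f"clade {name!r} references unknown terminal(s): {sorted(unknown)}"
                )

    def members(self, name: str) -> frozenset[str]:
        return self.clades[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self.clades))

    def restricted_to(self, ids: Iterable[str]) -> tuple["CladeMap", dict[str, list[str]]]:
        """Drop terminals absent from ``ids``; returns (new map, excluded-by-clade)."""
        keep = frozenset(ids) & self.terminals
        excluded: dict[str, list[str]] = {}
        clades: dict[str, frozenset[str]] = {}
        for name, members in self.clades.items():
            gone = sorted(members - keep)
            if gone:
                excluded[name] = gone
            kept = members & keep
            if kept:
                clades[name] = kept
        return CladeMap(terminals=keep, clades=clades, ranks=self.ranks), excluded


@dataclass(frozen=True)
class RegionMap:
    """Ordered, disjoint, labeled column intervals (0-based, half-open).

    Canonical label vocabularies: ``B``..``W`` for 18S LVRs; ``D2``..``D11``
    and dash-suffixed subdivisions (``D3-1``, ``D3-2``, ``D3-3``) for 28S.
    """

    regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _, _ in self.regions]
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate region labels")
        prev_end = None
        prev_lab = None
        for lab, s, e in sorted(self.regions, key=lambda r: (r[1], r[2])):
            if s < 0 or e < s:
                raise FormatError(f"region {lab!r}: bad interval [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"regions {prev_lab!r} and {lab!r} overlap")
            prev_end, prev_lab = e, lab
        object.__setattr__(
            self, "regions", tuple(sorted(self.regions, key=lambda r: (r[1], r[2])))
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _, _ in self.regions)

    def interval(self, label: str) -> tuple[int, int]:
        for lab, s, e in self.regions:
            if lab == label:
                return s, e
        raise KeyError(label)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into :class:`RnaSequence` records (order preserved).

    The id is the first whitespace-delimited header token; the remainder, if
    any, becomes the description and the taxon defaults to the id.
    """
    records: list[RnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(RnaSequence.from_raw(rec.id, str(rec.seq), description=desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Sequence[RnaSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Alignments (FASTA / Stockholm with SS_cons)


def read_msa(path: str | Path, format: str = "fasta") -> tuple[Msa, str | None]:
    """Read a multiple alignment; returns ``(msa, ss_cons-or-None)``.

    ``format`` is ``"fasta"`` or ``"stockholm"``. For Stockholm the
    ``#=GC SS_cons`` line, if present, is returned as a structure string of
    length ``n_cols`` (WUSS/dot-bracket, unaltered apart from gap symbols).
    """
    if format == "fasta":
        rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not rows:
            raise FormatError(f"no alignment rows in {path}")
        lengths = {len(s) for _, s in rows}
        if len(lengths) > 1:
            detail = ", ".join(f"{rid}={len(s)}" for rid, s in rows)
            raise FormatError(f"ragged alignment rows (id=length): {detail}")
        return Msa.from_pairs(rows), None
    if format == "stockholm":
        aln = AlignIO.read(str(path), "stockholm")
        msa = Msa.from_pairs((rec.id, str(rec.seq)) for rec in aln)
        ss = aln.column_annotations.get("secondary_structure")
        return msa, ss
    raise ValueError(f"unsupported alignment format {format!r}")


def write_msa(
    msa: Msa, path: str | Path, format: str = "fasta", ss_cons: str | None = None
) -> None:
    recs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in msa]
    if format == "fasta":
        SeqIO.write(recs, str(path), "fasta")
        return
    if format == "stockholm":
        aln = MultipleSeqAlignment(recs)
        if ss_cons is not None:
            if len(ss_cons) != msa.n_cols:
                raise FormatError("SS_cons length does not match alignment width")
            aln.column_annotations["secondary_structure"] = ss_cons
        AlignIO.write(aln, str(path), "stockholm")
        return
    raise ValueError(f"unsupported alignment format {format!r}")


# ---------------------------------------------------------------------------
# Clade maps (Newick with labeled internal nodes, or a rank table)


def read_clade_map(
    path: str | Path, format: str = "newick", unions: Iterable[str] = ()
) -> CladeMap:
    """Read a clade map.

    * ``newick``: every labeled internal node defines a clade = its leaf set.
    * ``table``: CSV with columns ``taxon,family,superfamily,infraorder``;
      each distinct rank value defines a clade.

    ``unions`` declares compound clades as ``"X+Y"`` strings whose parts must
    already be defined (e.g. ``"Naboidea+Cimicoidea"``).
    """
    if format == "newick":
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        terminals = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
        clades: dict[str, frozenset[str]] = {}
        for node in tree.preorder_internal_node_iter():
            label = node.label
            if label:
                if label in clades:
                    raise FormatError(f"duplicate clade name {label!r}")
                clades[label] = frozenset(
                    leaf.taxon.label for leaf in node.leaf_iter()
                )
        ranks = None
    elif format == "table":
        df = pd.read_csv(path, comment="#")
        required = ["taxon", "family", "superfamily", "infraorder"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"clade table missing column(s) {missing}")
        terminals = frozenset(df["taxon"].astype(str))
        if len(terminals) != len(df):
            raise FormatError("duplicate taxa in clade table")
        clades = {}
        ranks = {}
        for _, r in df.iterrows():
            ranks[str(r["taxon"])] = (
                str(r["family"]), str(r["superfamily"]), str(r["infraorder"])
            )
        for rank in ["family", "superfamily", "infraorder"]:
            for value, group in df.groupby(rank):
                value = str(value)
                if not value or value.lower() == "nan":
                    continue
                members = frozenset(group["taxon"].astype(str))
                if value in clades and clades[value] != members:
                    raise FormatError(f"clade name {value!r} used at two ranks")
                clades[value] = members
    else:
        raise ValueError(f"unsupported clade map format {format!r}")

    for union in unions:
        parts = [p.strip() for p in union.split("+")]
        members: frozenset[str] = frozenset()
        for part in parts:
            if part not in clades:
                raise FormatError(f"union {union!r}: clade {part!r} is not defined")
            members = members | clades[part]
        clades[union] = members
    return CladeMap(terminals=terminals, clades=clades, ranks=ranks)


# ---------------------------------------------------------------------------
# Region maps (CSV)

_REGION_HEADER_COMMENT = "# label,start,end  (alignment columns, 0-based, half-open)"


def write_region_map(region_map: RegionMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_REGION_HEADER_COMMENT + "\n")
        w = csv.writer(fh)
        w.writerow(["label", "start", "end"])
        for lab, s, e in region_map:
            w.writerow([lab, s, e])


def read_region_map(path: str | Path) -> RegionMap:
    regions: list[tuple[str, int, int]] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows or [c.strip() for c in rows[0]] != ["label", "start", "end"]:
        raise FormatError(f"region map {path}: expected header 'label,start,end'")
    for r in rows[1:]:
        regions.append((r[0], int(r[1]), int(r[2])))
    return RegionMap(tuple(regions))
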