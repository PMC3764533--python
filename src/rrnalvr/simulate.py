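"""Generate rRNA-like datasets with known structure, planted clade-specific
LVR length states, and controlled noise.

The generator emulates the statistical structure of comparative rRNA data: a
length-conservative core (identical across sequences up to substitutions,
with planted helices whose substitutions are compensated at a configurable
rate) interrupted by LVRs whose ungapped lengths are discrete clade states,
with a small per-(sequence, region) "exception" process that perturbs a state
by +-1 nt. Indels are confined to LVRs; the core never gains or loses
columns.

Within each LVR the true alignment places every sequence's residues so that
every LVR column carries a substantial gap fraction (the alignment window is
wider than the longest realized state, and each sequence's gap block is
rotated along the window). Gap-driven delimitation therefore recovers the
planted boundaries exactly at zero noise; this is a property of the planted
truth, not of any real aligner's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .delimit import LvrLengthTable, lvr_lengths
from .fold import PairRule
from .io import CladeMap, Msa, RegionMap, RnaSequence, write_region_map, write_msa
from .model import Helix, StructureModel, model_score, select_model, write_model_csv
from .scan import SynapomorphyCandidate, flag_synapomorphies

_BASES = np.array(list("ACGU"))
_CANONICAL_PAIRS = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

# window width: longest realized state / this fraction, so every LVR column
# keeps a gap fraction comfortably above the default delimitation threshold
_LVR_OCCUPANCY = 0.65


@dataclass(frozen=True)
class CoreBlock:
    """A length-conservative block; the first and last ``stem`` positions form
    a planted helix (0 = unstructured block)."""

    length: int
    stem: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("core block length must be positive")
        if self.stem < 0 or 2 * self.stem > self.length - (3 if self.stem else 0):
            raise ValueError(f"stem {self.stem} does not fit in block of {self.length}")


@dataclass(frozen=True)
class LvrSpec:
    """One planted LVR: clade -> length state, a default state for taxa not
    covered by any key, and an optional hairpin constraint on the content."""

    label: str
    states: Mapping[str, int]
    default: int
    hairpin: bool = False

    def __post_init__(self) -> None:
        if self.default < 0 or any(v < 0 for v in self.states.values()):
            raise ValueError(f"LVR {self.label!r}: length states must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    taxonomy: CladeMap
    core_blocks: tuple[CoreBlock, ...]
    lvr_specs: tuple[LvrSpec, ...]
    sub_rate: float = 0.0
    compensatory_rate: float = 0.9
    lvr_indel_rate: float = 0.0
    seed: int = 0
    scan_clades: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, rate in [
            ("sub_rate", self.sub_rate),
            ("compensatory_rate", self.compensatory_rate),
            ("lvr_indel_rate", self.lvr_indel_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if len(self.core_blocks) != len(self.lvr_specs) + 1:
            raise ValueError(
                "need exactly one more core block than LVRs (blocks flank every LVR)"
            )
        for lvr in self.lvr_specs:
            for clade in lvr.states:
                if clade not in self.taxonomy.clades:
                    raise ValueError(
                        f"LVR {lvr.label!r} references clade {clade!r} absent from taxonomy"
                    )
        for name in self.scan_clades:
            if name not in self.taxonomy.clades:
                raise ValueError(f"scan clade {name!r} absent from taxonomy")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset: the true alignment, the
    planted region map and structure model, the realized length table, the
    per-(sequence, region) planted/realized states with exception flags, the
    clades intended for scanning, and the planted synapomorphy triples."""

    msa: Msa
    region_map: RegionMap
    model: StructureModel
    length_table: LvrLengthTable
    planted: pd.DataFrame  # id, region, state, realized, exception
    scan_clades: CladeMap
    synapomorphies: list[tuple[str, str, int]]  # (clade, region, length)

    @property
    def ss_cons(self) -> str:
        return self.model.ss_cons()


def _content_rng(seed: int, region_index: int, length: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, 7919, region_index, length))
    )


def _lvr_content(seed: int, region_index: int, length: int, hairpin: bool) -> str:
    """Deterministic LVR content for a given (region, length): identical
    states imply identical content, so zero-noise same-clade sequences are
    identical. With ``hairpin`` the content folds into a stem-loop
    (3' half is the reverse complement of the 5' half)."""
    rng = _content_rng(seed, region_index, length)
    if length == 0:
        return ""
    if hairpin and length >= 5:
        stem = (length - 3) // 2
        loop = length - 2 * stem
        left = "".join(rng.choice(_BASES, size=stem))
        mid = "".join(rng.choice(_BASES, size=loop))
        right = "".join(_COMP[c] for c in reversed(left))
        return left + mid + right
    return "".join(rng.choice(_BASES, size=length))


def _mutate_block(
    t: list[str], stem: int, rng: np.random.Generator, sub_rate: float, comp_rate: float
) -> None:
    """Per-site substitutions within one core block; a substitution at a stem
    site is compensated (partner changed to the canonical complement) with
    probability ``comp_rate``."""
    nb = len(t)
    partner = {}
    for k in range(stem):
        partner[k] = nb - 1 - k
        partner[nb - 1 - k] = k
    for pos in range(nb):
        if rng.random() >= sub_rate:
            continue
        new = str(rng.choice(_BASES[_BASES != t[pos]]))
        t[pos] = new
        if pos in partner and rng.random() < comp_rate:
            t[partner[pos]] = _COMP[new]


def generate(spec: GeneratorSpec) -> tuple[list[RnaSequence], SyntheticTruth]:
    """Generate sequences plus full ground truth. Deterministic for a fixed
    ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    taxa = sorted(spec.taxonomy.terminals)
    n_seq = len(taxa)
    n_lvr = len(spec.lvr_specs)

    # planted state per (taxon, lvr): the smallest matching clade key wins,
    # otherwise the LVR's default
    def planted_state(taxon: str, lvr: LvrSpec) -> int:
        hits = [
            name
            for name in lvr.states
            if taxon in spec.taxonomy.clades[name]
        ]
        if not hits:
            return lvr.default
        best = min(hits, key=lambda n: (len(spec.taxonomy.clades[n]), n))
        return lvr.states[best]

    # pass 1: realized lengths (exception process)
    states = np.zeros((n_seq, n_lvr), dtype=int)
    realized = np.zeros((n_seq, n_lvr), dtype=int)
    exception = np.zeros((n_seq, n_lvr), dtype=bool)
    for si, taxon in enumerate(taxa):
        for li, lvr in enumerate(spec.lvr_specs):
            st = planted_state(taxon, lvr)
            states[si, li] = st
            real = st
            if rng.random() < spec.lvr_indel_rate:
                real = max(0, st + (1 if rng.random() < 0.5 else -1))
                exception[si, li] = real != st
            realized[si, li] = real

    widths = []
    for li in range(n_lvr):
        mx = int(realized[:, li].max())
        widths.append(max(int(np.ceil(mx / _LVR_OCCUPANCY)), mx + 2))

    # core templates with complementary stem sides
    templates: list[list[str]] = []
    for block in spec.core_blocks:
        t = list(rng.choice(_BASES, size=block.length))
        for k in range(block.stem):
            t[block.length - 1 - k] = _COMP[t[k]]
        templates.append(t)

    # column layout: core 0, LVR 0, core 1, LVR 1, ..., core n
    col = 0
    core_starts: list[int] = []
    lvr_starts: list[int] = []
    for bi, block in enumerate(spec.core_blocks):
        core_starts.append(col)
        col += block.length
        if bi < n_lvr:
            lvr_starts.append(col)
            col += widths[bi]
    n_cols = col

    region_map = RegionMap(
        tuple(
            (lvr.label, lvr_starts[li], lvr_starts[li] + widths[li])
            for li, lvr in enumerate(spec.lvr_specs)
        )
    )
    helices = tuple(
        Helix(
            side5=(core_starts[bi], core_starts[bi] + block.stem),
            side3=(
                core_starts[bi] + block.length - block.stem,
                core_starts[bi] + block.length,
            ),
        )
        for bi, block in enumerate(spec.core_blocks)
        if block.stem > 0
    )
    model = StructureModel(n_cols=n_cols, helices=helices, region_map=region_map)

    # pass 2: rows
    rows: list[tuple[str, str]] = []
    for si, taxon in enumerate(taxa):
        parts: list[str] = []
        for bi, block in enumerate(spec.core_blocks):
            t = list(templates[bi])
            if spec.sub_rate > 0:
                _mutate_block(t, block.stem, rng, spec.sub_rate, spec.compensatory_rate)
            parts.append("".join(t))
            if bi < n_lvr:
                L = int(realized[si, bi])
                W = widths[bi]
                content = list(
                    _lvr_content(spec.seed, bi, L, spec.lvr_specs[bi].hairpin)
                )
                if spec.sub_rate > 0:
                    for p in range(L):
                        if rng.random() < spec.sub_rate:
                            content[p] = str(rng.choice(_BASES[_BASES != content[p]]))
                # rotate this sequence's gap block along the window so every
                # LVR column ends up heavily gapped across the dataset
                offset = (si * W) // n_seq
                gap_cols = {(offset + t_) % W for t_ in range(W - L)}
                cells = ["-"] * W
                ci = 0
                for c in range(W):
                    if c not in gap_cols:
                        cells[c] = content[ci]
                        ci += 1
                parts.append("".join(cells))
        rows.append((taxon, "".join(parts)))

    msa = Msa(tuple(rows))
    length_table = lvr_lengths(msa, region_map)
    planted = pd.DataFrame(
        [
            {
                "id": taxa[si],
                "region": spec.lvr_specs[li].label,
                "state": int(states[si, li]),
                "realized": int(realized[si, li]),
                "exception": bool(exception[si, li]),
            }
            for si in range(n_seq)
            for li in range(n_lvr)
        ],
        columns=["id", "region", "state", "realized", "exception"],
    )

    scan_names = spec.scan_clades or tuple(sorted(spec.taxonomy.clades))
    scan_clades = CladeMap(
        terminals=spec.taxonomy.terminals,
        clades={name: spec.taxonomy.clades[name] for name in scan_names},
        ranks=spec.taxonomy.ranks,
    )

    planted_table = LvrLengthTable(
        planted.rename(columns={"state": "length"})[["id", "region", "length"]]
    )
    truth_flags = flag_synapomorphies(
        planted_table, scan_clades, min_share=1.0, outside_max_freq=0.5
    )
    synapomorphies = [(c.clade, c.region, c.state_length) for c in truth_flags]

    seqs = [
        RnaSequence(id=taxon, residues=aligned.replace("-", ""), taxon=taxon)
        for taxon, aligned in rows
    ]
    truth = SyntheticTruth(
        msa=msa,
        region_map=region_map,
        model=model,
        length_table=length_table,
        planted=planted,
        scan_clades=scan_clades,
        synapomorphies=synapomorphies,
    )
    return seqs, truth


def truth_msa(truth: SyntheticTruth) -> Msa:
    """The true alignment (accessor; kept as a function for API symmetry with
    the truth writers)."""
    return truth.msa


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the truth bundle: Stockholm alignment with SS_cons from the
    planted model, region map, model helix table, length table, and planted
    state table. Everything round-trips through the package readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "truth_alignment.sto",
        "regions": out / "truth_regions.csv",
        "model": out / "truth_model.csv",
        "lengths": out / "truth_lengths.csv",
        "planted": out / "truth_planted.csv",
    }
    write_msa(truth.msa, paths["alignment"], format="stockholm", ss_cons=truth.ss_cons)
    write_region_map(truth.region_map, paths["regions"])
    write_model_csv(truth.model, paths["model"])
    truth.length_table.to_csv(paths["lengths"])
    truth.planted.to_csv(paths["planted"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Study-style default configurations


def _five_family_taxonomy(seqs_per_family: int = 6) -> CladeMap:
    families = {
        f"F{i}": frozenset(f"F{i}_t{j}" for j in range(1, seqs_per_family + 1))
        for i in range(1, 6)
    }
    terminals = frozenset().union(*families.values())
    clades: dict[str, frozenset[str]] = dict(families)
    clades["CladeA"] = families["F1"] | families["F2"]
    clades["CladeB"] = families["F4"] | families["F5"]
    return CladeMap(terminals=terminals, clades=clades)


def default_generator_spec(
    seed: int = 0,
    seqs_per_family: int = 6,
    sub_rate: float = 0.0,
    compensatory_rate: float = 0.9,
    lvr_indel_rate: float = 0.0,
) -> GeneratorSpec:
    """The study-scale default: 5 families x ``seqs_per_family`` sequences,
    4 planted LVRs, and exactly 2 planted synapomorphies (CladeA = families
    F1+F2 with an 11 nt state in LVR B; CladeB = F4+F5 with a 4 nt state in
    LVR D). The other LVRs vary in length between families without any
    scan-clade-consistent state, and all planted states in a scanned region
    differ from the synapomorphic state by >= 2 nt so single-nucleotide
    exceptions cannot collide with it.
    """
    taxonomy = _five_family_taxonomy(seqs_per_family)
    core = tuple(CoreBlock(length=30, stem=7) for _ in range(5))
    lvrs = (
        LvrSpec("B", {"CladeA": 11, "F3": 7, "F4": 8, "F5": 9}, default=7, hairpin=True),
        LvrSpec("C", {"F1": 5, "F2": 6, "F3": 7, "F4": 5, "F5": 6}, default=5),
        LvrSpec("D", {"CladeB": 4, "F1": 8, "F2": 9, "F3": 10}, default=8, hairpin=True),
        LvrSpec("E", {"F1": 3, "F2": 4, "F3": 5, "F4": 3, "F5": 4}, default=3),
    )
    return GeneratorSpec(
        taxonomy=taxonomy,
        core_blocks=core,
        lvr_specs=lvrs,
        sub_rate=sub_rate,
        compensatory_rate=compensatory_rate,
        lvr_indel_rate=lvr_indel_rate,
        seed=seed,
        scan_clades=("CladeA", "CladeB"),
    )


def small_subunit_like_spec(seed: int = 0, seqs_per_family: int = 6) -> GeneratorSpec:
    """An 18S-scale configuration: 13 planted LVRs between 14 conserved
    blocks, with between-family length variation in every LVR but no
    scan-clade synapomorphies. Used to exercise delimitation at the region
    count reported for small-subunit rRNA."""
    taxonomy = _five_family_taxonomy(seqs_per_family)
    core = tuple(CoreBlock(length=20, stem=5) for _ in range(14))
    bases = [5, 7, 9, 11, 6, 8, 10, 12, 5, 7, 9, 11, 6]
    labels = list("BCDEFGHIJKLMN")
    lvrs = tuple(
        LvrSpec(
            labels[k],
            {f"F{i}": bases[k] + (i % 3) for i in range(1, 6)},
            default=bases[k],
            hairpin=(k % 4 == 0),
        )
        for k in range(13)
    )
    return GeneratorSpec(
        taxonomy=taxonomy,
        core_blocks=core,
        lvr_specs=lvrs,
        seed=seed,
        scan_clades=("CladeA", "CladeB"),
    )


# ---------------------------------------------------------------------------
# Recovery evaluation (used by the property/acceptance suites)


def match_regions(truth_map: RegionMap, recovered: RegionMap) -> dict[str, str]:
    """Map recovered labels -> truth labels by maximal column overlap."""
    out: dict[str, str] = {}
    for rlab, rs, re_ in recovered:
        best, best_ov = None, 0
        for tlab, ts, te in truth_map:
            ov = max(0, min(re_, te) - max(rs, ts))
            if ov > best_ov:
                best, best_ov = tlab, ov
        if best is not None:
            out[rlab] = best
    return out


def evaluate_scan(
    truth: SyntheticTruth,
    recovered_regions: RegionMap,
    candidates: Sequence[SynapomorphyCandidate],
) -> dict[str, int]:
    """Compare flagged candidates against the planted synapomorphies.

    A planted (clade, region, L) counts as recovered when a candidate names
    the same clade and state length in a recovered region overlapping the
    planted one; any other candidate is a false positive.
    """
    label_map = match_regions(truth.region_map, recovered_regions)
    found: set[tuple[str, str, int]] = set()
    n_false = 0
    for c in candidates:
        tlab = label_map.get(c.region)
        key = (c.clade, tlab, c.state_length)
        if tlab is not None and key in set(truth.synapomorphies):
            found.add(key)
        else:
            n_false += 1
    return {
        "n_planted": len(truth.synapomorphies),
        "n_recovered": len(found),
        "n_false_positives": n_false,
    }


def planted_model_wins(
    truth: SyntheticTruth,
    n_rivals: int,
    rng: np.random.Generator,
    rule: PairRule | None = None,
) -> bool:
    """Does the co-variation criterion pick the planted model over random
    same-size rivals on the truth alignment?"""
    from .fold import DEFAULT_RULE
    from .model import random_model_like

    rule = rule or DEFAULT_RULE
    rivals = [random_model_like(truth.model, rng) for _ in range(n_rivals)]
    chosen = select_model([truth.model] + rivals, truth.msa, rule)
    return chosen is truth.model
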