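"""End-to-end orchestration: alignment -> column profile -> LVR delimitation
-> length table -> synapomorphy scan (optionally scoring candidate structure
models), with a reproducible manifest.

The pipeline output is a pure function of (inputs, config): the manifest
records parameters, the seed, and SHA-256 checksums of inputs and outputs,
and contains no timestamps, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .delimit import column_profile, delimit_lvrs, lvr_lengths
from .fold import PairRule
from .io import FormatError, read_clade_map, read_msa, write_region_map
from .model import model_score, read_model_csv
from .scan import candidates_frame, flag_synapomorphies, report_table

_RULES = {
    "canonical": PairRule.canonical,
    "canonical+wobble": PairRule.canonical_wobble,
    "extended": PairRule.extended,
}


@dataclass
class PipelineConfig:
    msa: str
    clades: str
    out_dir: str
    msa_format: str = "fasta"
    clades_format: str = "newick"
    clade_unions: list[str] = field(default_factory=list)
    model: str | None = None
    gap_threshold: float = 0.2
    min_conserved_block: int = 5
    min_lvr_cols: int = 2
    label_scheme: str = "alpha"
    min_share: float = 0.9
    outside_max_freq: float = 0.5
    pair_rule: str = "canonical+wobble"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; write artifacts + ``manifest.json`` to ``out_dir``.

    Returns a dict with the in-memory results (region map, length table,
    candidates, report, manifest).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rule = _RULES[config.pair_rule]()

    msa, ss_cons = read_msa(config.msa, format=config.msa_format)
    clades = read_clade_map(
        config.clades, format=config.clades_format, unions=config.clade_unions
    )

    profile = column_profile(msa, gap_threshold=config.gap_threshold)
    region_map = delimit_lvrs(
        profile,
        min_conserved_block=config.min_conserved_block,
        min_lvr_cols=config.min_lvr_cols,
        label_scheme=config.label_scheme,
    )
    table = lvr_lengths(msa, region_map)

    scan_clades, excluded = clades.restricted_to(table.ids)
    warnings = [
        f"clade {name!r}: excluded members absent from alignment: {members}"
        for name, members in sorted(excluded.items())
    ]
    candidates = flag_synapomorphies(
        table,
        scan_clades,
        min_share=config.min_share,
        outside_max_freq=config.outside_max_freq,
    )

    scores = None
    if config.model:
        model = read_model_csv(config.model, n_cols=msa.n_cols)
        scores = model_score(model, msa, rule)._asdict()

    outputs: dict[str, Path] = {
        "region_map": out_dir / "region_map.csv",
        "lengths": out_dir / "lvr_lengths.csv",
        "candidates": out_dir / "synapomorphy_candidates.csv",
        "report": out_dir / "synapomorphy_report.txt",
    }
    write_region_map(region_map, outputs["region_map"])
    table.to_csv(outputs["lengths"])
    candidates_frame(candidates).to_csv(outputs["candidates"], index=False)
    report = report_table(candidates)
    outputs["report"].write_text(report)
    if scores is not None:
        outputs["model_scores"] = out_dir / "model_scores.json"
        outputs["model_scores"].write_text(json.dumps(scores, sort_keys=True) + "\n")

    manifest = {
        "tool": "rrnalvr",
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in [("msa", config.msa), ("clades", config.clades)]
            + ([("model", config.model)] if config.model else [])
        },
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
        "warnings": warnings,
        "n_regions": len(region_map),
        "n_candidates": len(candidates),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")

    return {
        "region_map": region_map,
        "length_table": table,
        "candidates": candidates,
        "report": report,
        "model_scores": scores,
        "manifest": manifest,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
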