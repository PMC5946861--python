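"""The key=value pipeline configuration file ("data.txt" dialect).

Lines are ``key=value``; ``//`` starts a comment line; values may be quoted
(straight or typographic quotes both occur in the wild) and list-valued
keys are comma-separated.  Relative paths are resolved against the config
file's directory.  Unknown keys warn rather than error, so configs written
for richer pipeline front ends still parse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .models import HitFilter

__all__ = ["PipelineConfig", "ConfigError", "parse_config"]

MANDATORY_KEYS = (
    "genome",
    "annotation",
    "annotation_related_species",
    "genome_related_species",
)

_KNOWN_KEYS = set(MANDATORY_KEYS) | {
    "reads_R1",
    "reads_R2",
    "assembled_gtf",
    "contig_fasta",
    "psl_genome",
    "psl_related",
    "sam_files",
    "output_dir",
    "min_identity",
    "min_aligned_fraction",
    "min_aligned_bases",
    "min_anchor",
    "min_support",
}

_QUOTES = "\"'“”‘’"


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    annotation_related_species: str
    genome_related_species: str
    reads_r1: list[str] = field(default_factory=list)
    reads_r2: list[str] = field(default_factory=list)
    assembled_gtf: Optional[str] = None
    contig_fasta: Optional[str] = None
    psl_genome: Optional[str] = None
    psl_related: Optional[str] = None
    sam_files: list[str] = field(default_factory=list)
    output_dir: str = "supertx_out"
    hit_filter: HitFilter = field(default_factory=HitFilter)
    min_anchor: int = 30
    min_support: int = 1

    def __post_init__(self) -> None:
        if len(self.reads_r1) != len(self.reads_r2):
            raise ConfigError(
                f"reads_R1 lists {len(self.reads_r1)} files but reads_R2 lists "
                f"{len(self.reads_r2)}; paired lists must match"
            )

    @property
    def sample_names(self) -> list[str]:
        return [Path(p).stem for p in self.sam_files]


def _unquote(value: str) -> str:
    value = value.strip()
    while value and value[0] in _QUOTES:
        value = value[1:]
    while value and value[-1] in _QUOTES:
        value = value[:-1]
    return value


def _split_list(value: str) -> list[str]:
    return [v.strip() for v in value.split(",") if v.strip()]


def parse_config(path) -> PipelineConfig:
    """Parse a ``data.txt``-style configuration file.

    Raises
    ------
    ConfigError
        Naming every missing mandatory key, or on a mismatched
        reads_R1/reads_R2 pairing.
    """
    path = Path(path)
    base = path.parent
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("//") or line.startswith("#"):
                continue
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip().strip("*").strip()
            raw[key] = _unquote(value)
    missing = [k for k in MANDATORY_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"missing mandatory config keys: {', '.join(missing)}")
    for key in raw:
        if key not in _KNOWN_KEYS:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q) if q.is_absolute() else str(base / q)

    def resolve_list(key: str) -> list[str]:
        return [resolve(p) for p in _split_list(raw.get(key, ""))]

    hit_filter = HitFilter(
        min_identity=float(raw.get("min_identity", 0.98)),
        min_aligned_fraction=float(raw.get("min_aligned_fraction", 0.5)),
        min_aligned_bases=int(raw.get("min_aligned_bases", 100)),
    )
    return PipelineConfig(
        genome=resolve(raw["genome"]),
        annotation=resolve(raw["annotation"]),
        annotation_related_species=resolve(raw["annotation_related_species"]),
        genome_related_species=resolve(raw["genome_related_species"]),
        reads_r1=resolve_list("reads_R1"),
        reads_r2=resolve_list("reads_R2"),
        assembled_gtf=resolve(raw["assembled_gtf"]) if "assembled_gtf" in raw else None,
        contig_fasta=resolve(raw["contig_fasta"]) if "contig_fasta" in raw else None,
        psl_genome=resolve(raw["psl_genome"]) if "psl_genome" in raw else None,
        psl_related=resolve(raw["psl_related"]) if "psl_related" in raw else None,
        sam_files=resolve_list("sam_files"),
        output_dir=resolve(raw["output_dir"]) if "output_dir" in raw else "supertx_out",
        hit_filter=hit_filter,
        min_anchor=int(raw.get("min_anchor", 30)),
        min_support=int(raw.get("min_support", 1)),
    )
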