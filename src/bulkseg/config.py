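"""Run configuration: every tunable in one place, with strict loading."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import yaml

log = logging.getLogger("bulkseg")


@dataclass
class RunConfig:
    """All pipeline thresholds and tuning parameters with their defaults.

    Unknown keys in a config file are rejected rather than ignored, so typos
    cannot silently fall back to defaults.
    """

    seed: int = 1
    # bsa scan
    min_depth: int = 10
    max_depth: int = 200
    span: float = 0.1
    confidence_level: float = 0.95
    threshold_reps: int = 1_000
    rate_cm_per_mb: float = 2.0
    min_snps: int = 10
    merge_gap: int = 100_000
    generations: int = 8
    n_tall_bulk: int = 36
    n_dwarf_bulk: int = 40
    mean_depth_tall: float = 46.0
    mean_depth_dwarf: float = 57.0
    # samples in VCF mode
    tall_sample: str = "tall_bulk"
    dwarf_sample: str = "dwarf_bulk"
    maternal_is_ref: bool = True
    # differential expression
    lfc_cutoff: float = 1.0
    padj_cutoff: float = 0.05
    fpkm_min: float = 1.0
    fpkm_filter_rule: str = "any"
    kmeans_k: int = 6
    kmeans_restarts: int = 10
    # simulation
    population_size: int = 965
    n_genes: int = 2_000
    extra: dict = field(default_factory=dict, repr=False)  # reserved; must stay empty

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)} - {"extra"}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("extra")
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def log_echo(self) -> None:
        from . import __version__

        log.info("bulkseg %s | config %s | seed %d", __version__, self.digest(), self.seed)
        for k, v in sorted(self.to_dict().items()):
            log.info("config %s = %r", k, v)
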