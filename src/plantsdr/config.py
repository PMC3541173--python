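"""Declarative pipeline configuration.

All published constants (type cutoffs and unknown floors, the 60-residue /
50%-identity rescue rule, the 1e-40 clustering threshold, 500 bootstrap
replicates) live here as overridable defaults; no stage hard-codes them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .inventory import InventoryConfig, TypeCutoffs

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    rescue_window: int = 60
    rescue_min_identity: float = 0.5
    cluster_evalue: float = 1e-40
    bootstrap_replicates: int = 500
    rng_seed: int = 0
    type_inclusion: dict[str, float] = field(default_factory=dict)
    type_unknown_floor: dict[str, float] = field(default_factory=dict)
    whitelist_path: str | None = None
    exclusion_path: str | None = None
    taxon_tiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.rescue_window <= 0 or self.cluster_evalue <= 0 \
                or self.bootstrap_replicates <= 0:
            raise ConfigurationError("thresholds must be positive")
        for p in (self.whitelist_path, self.exclusion_path):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"referenced file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def type_cutoffs(self) -> TypeCutoffs:
        c = TypeCutoffs.default_plant()
        c.inclusion.update(self.type_inclusion)
        c.unknown_floor.update(self.type_unknown_floor)
        return c

    def inventory_config(self) -> InventoryConfig:
        whitelist: dict[str, str] = {}
        if self.whitelist_path:
            with open(self.whitelist_path) as fh:
                for line in fh:
                    line = line.strip()
                    if line and not line.startswith("#"):
                        sid, _, typ = line.partition("\t")
                        whitelist[sid] = typ or "atypical"
        exclusion: set[str] = set()
        if self.exclusion_path:
            with open(self.exclusion_path) as fh:
                exclusion = {
                    l.strip() for l in fh if l.strip() and not l.startswith("#")
                }
        return InventoryConfig(
            rescue_window=self.rescue_window,
            rescue_min_identity=self.rescue_min_identity,
            cluster_evalue=self.cluster_evalue,
            whitelist=whitelist,
            exclusion=frozenset(exclusion),
        )
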