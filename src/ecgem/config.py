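"""Run configuration: a flat, file-round-trippable record of every knob of the
pipeline, with defaults matching the reference analysis (FVA at 90% of max
growth, essentiality threshold 0.05 h⁻¹, 10,000 kcat permutations, uptake
released to −100 mmol/gDW/h)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    model_path: str = ""
    model_format: str | None = None  # inferred from extension when None
    enzyme_table: str = "table1"
    mode: str = "gecko"  # gecko | pool | none
    uptake_release: str | None = None  # exchange reaction id
    uptake_bound: float = -100.0
    fva_fraction: float = 0.9
    essentiality_threshold: float = 0.05
    randomization_n: int = 10000
    randomization_seed: int = 0
    randomization_frozen: list[str] = field(default_factory=list)
    design_target: str = "PGA"
    max_deletions: int = 1
    output_dir: str = "ecgem_out"

    def validate(self) -> None:
        if self.mode not in ("gecko", "pool", "none"):
            raise ValueError(f"mode must be gecko/pool/none, got {self.mode!r}")
        if not (0 < self.fva_fraction <= 1):
            raise ValueError(f"fva_fraction must be in (0, 1], got {self.fva_fraction}")
        if self.essentiality_threshold <= 0:
            raise ValueError("essentiality_threshold must be positive")
        if self.randomization_n < 1:
            raise ValueError("randomization_n must be at least 1")
        if self.max_deletions not in (1, 2):
            raise ValueError("max_deletions must be 1 or 2")
        if self.uptake_bound > 0:
            raise ValueError("uptake_bound is an uptake (negative) flux")

    def to_yaml(self, path: str) -> None:
        self.validate()
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg
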