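"""Analysis configuration: every threshold the pipeline applies, in one place.

Defaults follow the study conventions the pipeline re-implements: taxa in
fewer than 25% of samples are excluded from network inference, association
strengths of at most |0.15| are discarded, taxa under 0.1% overall relative
abundance are removed before dose-response testing, subjects are split into
eight balanced exposure groups, and counts are rarefied to 10,452 (16S)
and 8,194 (ITS) reads.  The on-disk format is a flat ``key = value`` text
file with ``#`` comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ConfigError


@dataclass
class AnalysisConfig:
    prevalence_min: float = 0.25
    edge_weight_min: float = 0.15
    abundance_min: float = 0.001
    n_exposure_groups: int = 8
    rarefaction_depth_bacteria: int = 10452
    rarefaction_depth_fungi: int = 8194
    q_threshold: float = 0.25
    n_permutations: int = 999
    n_subsamples: int = 50
    stability_threshold: float = 0.05
    seed: int = 0
    extra_seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("prevalence_min", "abundance_min", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.edge_weight_min < 0:
            raise ConfigError("edge_weight_min must be >= 0")
        if not 0.0 < self.stability_threshold < 1.0:
            raise ConfigError("stability_threshold outside (0, 1)")
        for name in (
            "n_exposure_groups",
            "rarefaction_depth_bacteria",
            "rarefaction_depth_fungi",
            "n_permutations",
            "n_subsamples",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")

    def seed_for(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        if stage in self.extra_seeds:
            return int(self.extra_seeds[stage])
        h = 0
        for ch in stage:
            h = (h * 131 + ord(ch)) % (2**31 - 1)
        return (self.seed * 7919 + h) % (2**31 - 1)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# skinpah analysis configuration\n")
            for f in fields(self):
                if f.name == "extra_seeds":
                    continue
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(open(path), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types or key == "extra_seeds":
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            caster = int if types[key] in ("int", int) else float
            try:
                kwargs[key] = caster(val)
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: bad value for {key}") from exc
        return cls(**kwargs)
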