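"""Run configuration: one YAML-serializable object holding every knob.

All randomness flows from the single ``seed``; every analysis threshold
has its documented default, so a recorded config file reruns a pipeline to
identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .corpus import DEFAULT_STAGE_DIRECTION_PATTERNS, TokenizerConfig

__all__ = ["RunConfig", "DEFAULT_CONTESTED_CHUNKS"]

#: Chunk ids excluded before discriminant training: works whose authorship
#: the literature disputes (partial collections, two-author pieces, and the
#: stylistic outliers that cluster with them).
DEFAULT_CONTESTED_CHUNKS = (8, 23, 24, 25, 29, 30, 41, 54, 55, 56)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default."""

    # tokenizer
    lowercase: bool = True
    strip_stage_directions: bool = True
    stage_direction_patterns: tuple[str, ...] = DEFAULT_STAGE_DIRECTION_PATTERNS
    neuter_his_as_its: bool = False
    keep_internal_apostrophes: bool = True
    # lexicons
    ra_lexicon_path: str | None = None
    sensory_lexicon_path: str | None = None
    # features
    layout: str = "RPAS11"
    richness_sqrt_denominator: bool = True
    ra_power_exponent: int = 2
    # accumulation
    n_groups: int = 100
    group_order: str = "group_size"
    rel_gain: float = 0.001
    # multivariate
    loading_threshold: float = 0.30
    f_enter: float = 3.84
    f_remove: float = 2.71
    n_clusters: int = 3
    outlier_r_percentile: float = 90.0
    outlier_a_percentile: float = 10.0
    contested_chunks: tuple[int, ...] = DEFAULT_CONTESTED_CHUNKS
    # randomness
    seed: int = 0

    def tokenizer(self) -> TokenizerConfig:
        return TokenizerConfig(
            lowercase=self.lowercase,
            strip_stage_directions=self.strip_stage_directions,
            stage_direction_patterns=tuple(self.stage_direction_patterns),
            neuter_his_as_its=self.neuter_his_as_its,
            keep_internal_apostrophes=self.keep_internal_apostrophes,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["stage_direction_patterns"] = list(self.stage_direction_patterns)
        data["contested_chunks"] = list(self.contested_chunks)
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stage_direction_patterns" in data:
            data["stage_direction_patterns"] = tuple(data["stage_direction_patterns"])
        if "contested_chunks" in data:
            data["contested_chunks"] = tuple(data["contested_chunks"])
        return cls(**data)
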