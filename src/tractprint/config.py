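"""Pipeline configuration: the four numbers that govern the analysis."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the fingerprinting pipeline.

    Attributes
    ----------
    S
        Streamline samples drawn per seed voxel (default 5000).
    row_threshold_frac
        Per-seed-row connection threshold: a connection is kept when its
        streamline count is at least this fraction of the strongest
        connection in the same row (default 0.01, i.e. 1 %).
    voxel_class_frac
        Voxel-to-template classification fraction: a voxel counts as
        connected to a target template when at least this fraction of its
        S samples reach it (default 0.25, i.e. 1250 of 5000).
    group_frac
        Group-consistency fraction: a connection (or voxel assignment) is
        retained when present in at least this fraction of subjects
        (default 0.50).
    """

    S: int = 5000
    row_threshold_frac: float = 0.01
    voxel_class_frac: float = 0.25
    group_frac: float = 0.50

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        for name in ("row_threshold_frac", "voxel_class_frac", "group_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})
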