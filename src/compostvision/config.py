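"""Run configuration for pipeline commands (YAML-loadable)."""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Analysis settings shared by the extract and compare stages.

    thresholds: binarization thresholds on the normalised [0, 1] scale,
    strictly increasing. glcm_levels: number of gray levels for the
    co-occurrence matrices. glcm_quantization: ``fixed_range`` (equal bins
    over [0, 255], the default and the setting under which features are
    comparable across images) or ``min_max`` (per-image stretch, for
    sensitivity checks). alpha: significance level of the group test.
    """

    thresholds: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
    glcm_levels: int = 8
    glcm_quantization: str = "fixed_range"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if any(not 0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError(f"thresholds must lie in (0, 1): {self.thresholds}")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {self.thresholds}")
        if len(self.thresholds) != 4:
            raise ValueError("exactly four binarization thresholds are required "
                             "(they define WH_PERCENT1..4)")
        if self.glcm_levels < 2:
            raise ValueError(f"glcm_levels must be >= 2, got {self.glcm_levels}")
        if self.glcm_quantization not in ("fixed_range", "min_max"):
            raise ValueError(f"unknown glcm_quantization {self.glcm_quantization!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
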