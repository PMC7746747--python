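"""Run configuration: the pipeline's constants, validated and serialisable.

The fixed thresholds reflect the controlled backlight imaging this pipeline
assumes: plate ROI above grey level 35, worms near level 0 on a ~48
background, a x3 working scale for the background transform, 90% body
overlap for pose de-duplication and a 4-px skeleton-hole limit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    roi_threshold: int = 35
    worm_threshold: int = 24
    threshold_levels: tuple[int, ...] = (8, 16, 24, 32)
    scale: int = 3
    tolerance_fraction: float = 0.25
    similarity_threshold: float = 0.90
    max_hole_px: int = 4
    weight_length: float = 1.0
    weight_width: float = 1.0
    weight_previous: float = 1.0
    coverage_weight: float = 1.0
    max_candidates: int = 50
    max_combinations: int = 10_000
    evaluation_radius: int | None = None  # None: from each worm's model
    min_track_length: int | None = None  # None: half the default model length
    default_w_max: float = 2.5
    default_w_min: float = 1.5
    default_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.roi_threshold <= 255, "roi_threshold in [0, 255]"),
            (0 <= self.worm_threshold <= 255, "worm_threshold in [0, 255]"),
            (all(0 <= t <= 255 for t in self.threshold_levels),
             "threshold_levels in [0, 255]"),
            (self.scale >= 1, "scale >= 1"),
            (0 < self.tolerance_fraction < 1, "tolerance_fraction in (0, 1)"),
            (0 < self.similarity_threshold <= 1,
             "similarity_threshold in (0, 1]"),
            (self.max_hole_px >= 1, "max_hole_px >= 1"),
            (min(self.weight_length, self.weight_width, self.weight_previous,
                 self.coverage_weight) >= 0, "weights >= 0"),
            (0 < self.default_w_min <= self.default_w_max,
             "0 < default_w_min <= default_w_max"),
            (self.default_length >= 1, "default_length >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: require {msg}")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.weight_length, self.weight_width, self.weight_previous)

    @property
    def min_length(self) -> int:
        if self.min_track_length is not None:
            return self.min_track_length
        return self.default_length // 2


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON config; missing keys take defaults, unknown keys warn,
    invalid values raise naming the offending constraint."""
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in data.items() if k in known}
    if "threshold_levels" in kwargs:
        kwargs["threshold_levels"] = tuple(kwargs["threshold_levels"])
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    d = asdict(config)
    d["threshold_levels"] = list(d["threshold_levels"])
    Path(path).write_text(json.dumps(d, indent=1) + "\n")
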