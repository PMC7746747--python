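"""Per-worm width/length models estimated from isolated blobs.

A worm model is the triple (w_max, w_min, length): the maximum and minimum
Euclidean distance-transform values found along the worm's classic skeleton,
and the skeleton pixel count. Width values are *half*-widths in the
distance-transform sense; a displayed full body width is twice the stored
value (a worm with w_max 2.32 is "2.32 x 2 pixels" wide at its thickest).
The model drives the background transform thresholds and the expected pose
length during tracking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Any, Mapping

import numpy as np
from scipy import ndimage

from .skeletonize import classic_skeleton

__all__ = ["WormModel", "distance_map", "estimate_worm_model", "default_model"]


@dataclass(frozen=True)
class WormModel:
    """Maximum/minimum half-width (distance values, px) and skeleton length
    (pixel count) of one worm."""

    w_max: float
    w_min: float
    length: int
    worm_id: int | None = None
    source_frame: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.w_min <= self.w_max:
            raise ValueError(
                f"need 0 < w_min <= w_max, got w_min={self.w_min}, w_max={self.w_max}"
            )
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")

    @property
    def full_width_max(self) -> float:
        return 2 * self.w_max

    @property
    def full_width_min(self) -> float:
        return 2 * self.w_min

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "WormModel":
        return cls(**json.loads(text))


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of each foreground pixel to the nearest
    background pixel; 0 on background.

    The mask should carry a background margin (as produced by
    ``segmentation.crop_blob``) so that values at the blob border are bounded
    by the crop geometry rather than the array edge.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, float)
    if mask.all():
        raise ValueError("mask has no background pixel; distances undefined")
    return ndimage.distance_transform_edt(mask)


def estimate_worm_model(
    blob: Any, worm_id: int | None = None, source_frame: int | None = None
) -> WormModel:
    """Estimate (w_max, w_min, length) from a single isolated, non-occluded
    worm blob.

    Procedure: Euclidean distance transform of the blob mask; classic
    skeleton of the mask; w_max/w_min are the largest and smallest distance
    values over skeleton pixels (endpoints included), and length is the
    skeleton pixel count.
    """
    mask = np.asarray(getattr(blob, "mask", blob), bool)
    skel = classic_skeleton(mask)
    n = int(skel.sum())
    if n < 3:
        raise ValueError(f"blob skeletonises to {n} pixels; not a worm")
    dmap = distance_map(mask)
    vals = dmap[skel]
    return WormModel(
        w_max=float(vals.max()),
        w_min=float(vals.min()),
        length=n,
        worm_id=worm_id,
        source_frame=source_frame,
    )


def default_model(config: Mapping[str, Any] | Any) -> WormModel:
    """Build a model from configured defaults, for tracks that never show a
    separated worm. Synchronised cultures make one default per experiment
    reasonable: all worms on a plate are of comparable size."""
    if not isinstance(config, Mapping):
        config = {
            "w_max": getattr(config, "default_w_max"),
            "w_min": getattr(config, "default_w_min"),
            "length": getattr(config, "default_length"),
        }
    try:
        return WormModel(
            w_max=float(config["w_max"]),
            w_min=float(config["w_min"]),
            length=int(config["length"]),
        )
    except KeyError as e:
        raise ValueError(f"default worm model config missing key {e}") from e
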