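"""Plate ROI extraction, worm segmentation, track finding and blob cropping.

Backlit plate imaging keeps intensities nearly constant: the plate region
sits near grey level 48, worms near 0, and the surround is black, so fixed
thresholds work for entire sequences. The ROI is the largest bright region
common to all frames; worms are the dark pixels inside it; a connected
region of the temporal union of worm masks is a worm track if, at some
attempted threshold level, it skeletonises to at least a minimum expected
length, otherwise it is noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .skeletonize import classic_skeleton

__all__ = ["Blob", "extract_roi", "segment_worms", "find_tracks", "crop_blob"]

_EIGHT = np.ones((3, 3), bool)


@dataclass(frozen=True)
class Blob:
    """One connected foreground region, cropped with a 1-px background
    margin; ``bbox`` = (top, left, height, width) of the tight extent in
    full-frame coordinates. Blob pixel (r, c) maps to frame pixel
    (r + top - 1, c + left - 1)."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    blob_id: int = 0

    @property
    def offset(self) -> tuple[int, int]:
        return self.bbox[0] - 1, self.bbox[1] - 1

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros(mask.shape, bool)
    sizes = ndimage.sum_labels(np.ones(mask.shape), labels, np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def extract_roi(
    frames: Sequence[np.ndarray], roi_threshold: int = 35
) -> np.ndarray:
    """Plate region of interest for a whole sequence.

    Per frame: keep pixels brighter than ``roi_threshold``; AND across all
    frames; morphological close (3x3, one iteration) to fill small holes;
    keep the largest 8-connected component. Empty if nothing passes.
    """
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("need at least one frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("frames have mismatched shapes")
    acc = np.ones(shape, bool)
    for f in frames:
        acc &= f > roi_threshold
    if not acc.any():
        return acc
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(acc, structure=_EIGHT), structure=_EIGHT
    )
    return _largest_component(closed)


def segment_worms(
    frame: np.ndarray, roi: np.ndarray, worm_threshold: int = 24
) -> np.ndarray:
    """Dark pixels inside the ROI: intensity strictly below
    ``worm_threshold``. Everything outside the ROI is background."""
    frame = np.asarray(frame)
    roi = np.asarray(roi, bool)
    if roi.shape != frame.shape:
        raise ValueError("roi shape does not match frame")
    return (frame < worm_threshold) & roi


def find_tracks(
    frames: Sequence[np.ndarray],
    min_length: int,
    threshold_levels: Sequence[int] = (8, 16, 24, 32),
    roi: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label connected regions of the temporal union of worm masks as worm
    tracks or noise.

    ``frames`` may be grayscale frames (each attempted ``threshold_levels``
    intensity is tried) or pre-binarised worm masks (used as-is). A region
    is a TRACK if at some attempted level its classic skeleton, restricted
    to the region, has at least ``min_length`` pixels; otherwise NOISE.

    Returns ``(track_labels, noise_labels)`` int arrays (0 = background);
    labels are assigned in scan order and stable for a given input.
    """
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("empty sequence")
    binary = frames[0].dtype == bool
    if binary:
        per_level_unions = [np.logical_or.reduce([f for f in frames])]
    else:
        if roi is None:
            roi = np.ones(frames[0].shape, bool)
        per_level_unions = [
            np.logical_or.reduce([segment_worms(f, roi, t) for f in frames])
            for t in threshold_levels
        ]
    # regions come from the most permissive union
    base = np.logical_or.reduce(per_level_unions)
    labels, n = ndimage.label(base, structure=_EIGHT)
    track_labels = np.zeros(base.shape, np.int32)
    noise_labels = np.zeros(base.shape, np.int32)
    n_track = n_noise = 0
    for lab in range(1, n + 1):
        region = labels == lab
        is_track = False
        for union in per_level_unions:
            sk = classic_skeleton(union & region)
            if int(sk.sum()) >= min_length:
                is_track = True
                break
        if is_track:
            n_track += 1
            track_labels[region] = n_track
        else:
            n_noise += 1
            noise_labels[region] = n_noise
    return track_labels, noise_labels


def crop_blob(mask: np.ndarray, component_id: int | None = None,
              labels: np.ndarray | None = None, blob_id: int = 0) -> Blob:
    """Crop one connected component to its bounding box plus a 1-px
    background margin on all sides (so the standalone distance transform is
    finite at the blob border).

    With ``labels``/``component_id`` given, crops that labelled component;
    otherwise ``mask`` must contain exactly one component.
    """
    mask = np.asarray(mask, bool)
    if labels is not None:
        if component_id is None:
            raise ValueError("component_id required with labels")
        mask = mask & (labels == component_id)
    if not mask.any():
        raise ValueError("empty component")
    rs, cs = np.nonzero(mask)
    top, left = int(rs.min()), int(cs.min())
    h = int(rs.max()) - top + 1
    w = int(cs.max()) - left + 1
    out = np.zeros((h + 2, w + 2), bool)
    out[1:-1, 1:-1] = mask[top : top + h, left : left + w]
    return Blob(mask=out, bbox=(top, left, h, w), blob_id=blob_id)
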