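"""End-to-end pipeline: frames -> ROI -> worm masks -> tracks -> models ->
width-aware skeletons -> per-frame poses, plus the file conventions used by
the CLI.

Coordinate convention everywhere: 0-based (row, col), origin at the
top-left pixel; pose coordinates may be sub-pixel (working-scale skeletons
mapped back to original resolution). Frames in a directory are processed in
lexicographic filename order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
import pandas as pd

from .config import RunConfig
from .pose_tracking import TrackState, track_sequence
from .segmentation import extract_roi, find_tracks, segment_worms
from .worm_model import WormModel, default_model

__all__ = ["PipelineResult", "run_pipeline", "read_frames", "write_poses_csv",
           "read_poses_csv", "write_mask"]

log = logging.getLogger("wormskel")

_COORD_HEADER = (
    "# coordinates: 0-based (row, col), origin top-left; sub-pixel allowed\n"
)


@dataclass
class PipelineResult:
    roi: np.ndarray
    worm_masks: list[np.ndarray]
    track_labels: np.ndarray
    noise_labels: np.ndarray
    tracks: list[TrackState] = field(default_factory=list)

    @property
    def models(self) -> list[WormModel]:
        return [t.model for t in self.tracks]


def read_frames(path: str | Path) -> list[np.ndarray]:
    """Read a directory of 8-bit PNG/TIFF frames in lexicographic order, or
    a single multi-page TIFF / image stack file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
    else:
        arr = np.asarray(iio.imread(path))
        frames = list(arr) if arr.ndim == 3 else [arr]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"mismatched frame shapes: {shapes}")
    return frames


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_poses_csv(tracks: Sequence[TrackState], path: str | Path) -> None:
    """Poses as CSV (frame, worm_id, point_index, row, col), with the
    coordinate convention stated in a header comment."""
    rows = []
    for tr in sorted(tracks, key=lambda t: t.worm_id):
        for frame in sorted(tr.poses):
            pts = tr.poses[frame].frame_points
            for i, (r, c) in enumerate(pts):
                rows.append((frame, tr.worm_id, i, float(r), float(c)))
    df = pd.DataFrame(rows, columns=["frame", "worm_id", "point_index", "row", "col"])
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        df.to_csv(fh, index=False)


def read_poses_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(
    frames: Sequence[np.ndarray] | str | Path,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Execute the full chain on a frame sequence.

    Stages: plate ROI over the whole sequence; per-frame worm segmentation;
    track/noise classification on the temporal union; per-track model
    estimation and forward/backward pose tracking. Deterministic for a given
    input and config.
    """
    config = config or RunConfig()
    if isinstance(frames, (str, Path)):
        frames = read_frames(frames)
    frames = [np.asarray(f) for f in frames]

    roi = extract_roi(frames, config.roi_threshold)
    log.info("stage=extract_roi frames=%d roi_px=%d", len(frames), int(roi.sum()))

    # Worms are dark in every frame they occupy, so the AND-composed ROI has
    # a hole along each worm's trail; fill enclosed holes before segmenting
    # so bodies inside the plate stay in the region of interest.
    roi_filled = ndimage.binary_fill_holes(roi)
    worm_masks = [segment_worms(f, roi_filled, config.worm_threshold) for f in frames]
    track_labels, noise_labels = find_tracks(
        frames, config.min_length, config.threshold_levels, roi_filled
    )
    n_tracks = int(track_labels.max())
    log.info("stage=find_tracks tracks=%d noise=%d", n_tracks,
             int(noise_labels.max()))

    tracks: list[TrackState] = []
    fallback = default_model(
        {"w_max": config.default_w_max, "w_min": config.default_w_min,
         "length": config.default_length}
    )
    for track_id in range(1, n_tracks + 1):
        region = track_labels == track_id
        track_masks = [m & region for m in worm_masks]
        if not any(m.any() for m in track_masks):
            continue
        sub = track_sequence(
            track_masks,
            default=fallback,
            scale=config.scale,
            tolerance_fraction=config.tolerance_fraction,
            similarity_threshold=config.similarity_threshold,
            weights=config.weights,
        )
        base = len(tracks)
        for tr in sub:
            tr.worm_id += base
            for pose in tr.poses.values():
                object.__setattr__(pose, "worm_id", tr.worm_id)
        tracks.extend(sub)
        log.info("stage=track track=%d worms=%d", track_id, len(sub))

    return PipelineResult(
        roi=roi, worm_masks=worm_masks, track_labels=track_labels,
        noise_labels=noise_labels, tracks=tracks,
    )
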