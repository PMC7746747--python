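"""Body reconstruction by disk dilation and the two IoU validation indices.

Worm bodies are recovered from 1-px skeletons or poses by dilating with a
disk whose radius is about half the body width (1 or 2 px for the imaging
scale assumed here, giving bodies 3 or 5 px wide). Index 1 is the IoU of a
predicted body against the body reconstructed from the ground-truth
skeleton — higher is closer. Index 2 is the IoU between the two predicted
bodies of worms in contact — lower means the predictions stay apart, which
is what a good skeletonisation of an aggregated blob should achieve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import disk
from scipy import ndimage

from .pose_tracking import (
    Pose,
    build_skeleton_graph,
    enumerate_cyclic_poses,
    enumerate_poses,
    filter_similar_poses,
    select_best_combination,
)
from .skeletonize import SkeletonMask, classic_skeleton, improved_skeleton, scale_mask
from .worm_model import WormModel, distance_map

__all__ = [
    "BodyMask",
    "ComparisonRow",
    "reconstruct_body",
    "iou",
    "index1",
    "index2",
    "compare_methods",
    "evaluation_radius",
]


@dataclass(frozen=True)
class BodyMask:
    """A body reconstructed from a skeleton/pose by disk dilation."""

    mask: np.ndarray
    radius: int


def evaluation_radius(model: WormModel) -> int:
    """Default dilation radius: the model's minimum half-width rounded and
    clipped to {1, 2}."""
    return int(np.clip(round(model.w_min), 1, 2))


def _as_pixels(skeleton, shape: tuple[int, int] | None) -> tuple[np.ndarray, tuple[int, int]]:
    if isinstance(skeleton, Pose):
        pts = np.rint(skeleton.frame_points).astype(int)
    else:
        arr = np.asarray(skeleton)
        if arr.dtype == bool:
            if shape is None:
                shape = arr.shape
            pts = np.argwhere(arr)
        else:
            pts = np.rint(arr).astype(int).reshape(-1, 2)
    if shape is None:
        shape = (int(pts[:, 0].max()) + 1, int(pts[:, 1].max()) + 1)
    return pts, shape


def reconstruct_body(
    skeleton, radius: int, shape: tuple[int, int] | None = None
) -> BodyMask:
    """Dilate a skeleton (boolean mask, (N, 2) pixel list, or Pose — poses
    are rounded to whole pixels first) with a discrete disk: a pixel belongs
    to the structuring element iff its center is within ``radius`` of the
    origin. Radius 1 turns a 1-px line into a 3-px-wide body; radius 2 into
    5 px."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    pts, shape = _as_pixels(skeleton, shape)
    body = np.zeros(shape, bool)
    inb = (
        (pts[:, 0] >= 0) & (pts[:, 0] < shape[0])
        & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1])
    )
    body[tuple(pts[inb].T)] = True
    if radius > 0 and body.any():
        body = ndimage.binary_dilation(body, structure=disk(radius))
    return BodyMask(mask=body, radius=radius)


def iou(a, b) -> float:
    """Jaccard coefficient |a AND b| / |a OR b| of two pixel sets; two empty
    masks score 0 by convention (an empty prediction is a miss, and means
    must not be poisoned by undefined values)."""
    ma = np.asarray(getattr(a, "mask", a), bool)
    mb = np.asarray(getattr(b, "mask", b), bool)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    union = int((ma | mb).sum())
    if union == 0:
        return 0.0
    return int((ma & mb).sum()) / union


def index1(predicted: BodyMask | np.ndarray, reference: BodyMask | np.ndarray) -> float:
    """Closeness of a predicted body to the ground-truth body reconstructed
    at the same radius. Higher is better."""
    return iou(predicted, reference)


def index2(body_worm1: BodyMask | np.ndarray, body_worm2: BodyMask | np.ndarray) -> float:
    """Overlap between two different worms' predicted bodies in the same
    frame. Lower is better — separated bodies score 0."""
    return iou(body_worm1, body_worm2)


# ---------------------------------------------------------------------------
# batch comparison harness


@dataclass(frozen=True)
class ComparisonRow:
    """Per-case summary in the shape of a method-comparison table."""

    case: str
    index: int  # 1 or 2
    n: int
    mean_new: float
    mean_classic: float
    sd_new: float
    sd_classic: float

    @property
    def improvement_pct(self) -> float:
        """Percentage-point improvement of the proposed method; index 1 is
        higher-is-better, index 2 lower-is-better."""
        if self.index == 1:
            return (self.mean_new - self.mean_classic) * 100
        return (self.mean_classic - self.mean_new) * 100


def _predict_poses(blob, models, backend: str, scale: int,
                   tolerance_fraction: float, similarity_threshold: float,
                   radius: int) -> list[Pose | None]:
    """Select one pose per worm from a blob with either skeleton backend."""
    if backend == "proposed":
        mode = "aggregated" if len(models) > 1 else "rolled"
        ref_model = (max(models, key=lambda m: m.w_max) if len(models) > 1
                     else models[0])
        comps, _ = improved_skeleton(blob, ref_model, mode=mode, scale=scale)
        union = np.zeros(comps[0].mask.shape, bool)
        for c in comps:
            union |= c.mask
        work_scale = scale
    elif backend == "classic":
        union = classic_skeleton(scale_mask(np.asarray(blob.mask, bool), scale))
        work_scale = scale
    else:
        raise ValueError(f"unknown backend {backend!r}")
    graph = build_skeleton_graph(SkeletonMask(union, work_scale))
    dmap = distance_map(scale_mask(np.asarray(blob.mask, bool), work_scale))
    offset = blob.offset
    cands = []
    for m in models:
        expected = m.length * work_scale
        poses = enumerate_poses(graph, expected, tolerance_fraction, offset)
        if graph.cycles:
            poses += enumerate_cyclic_poses(graph, expected, offset)
        cands.append(filter_similar_poses(poses, similarity_threshold, radius))
    if not any(cands):
        return [None] * len(models)
    assignment, _ = select_best_combination(
        cands, list(models), dmap, skeleton_mask=union
    )
    return assignment


def compare_methods(
    dataset,
    radius: int | None = None,
    scale: int = 3,
    tolerance_fraction: float = 0.25,
    similarity_threshold: float = 0.90,
    backends: tuple[str, str] = ("proposed", "classic"),
) -> tuple[list[ComparisonRow], pd.DataFrame]:
    """Run both skeleton backends over a labelled dataset and tabulate the
    two IoU indices per problematic case.

    ``dataset`` is an iterable of dicts with keys ``blob`` (a cropped Blob),
    ``truths`` (list of ground-truth skeleton pixel lists, full-frame
    coordinates), ``models`` (list of WormModel, one per worm), ``case``
    (case label), and optionally ``shape`` (full-frame shape). Per-pose
    index values are returned as a DataFrame so external statistics can be
    run downstream; summary rows mirror a mean/SD/improvement table.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    records = []
    for item_id, item in enumerate(dataset):
        blob, truths, models = item["blob"], item["truths"], item["models"]
        case = item.get("case", "unlabelled")
        shape = item.get("shape")
        if shape is None:
            top, left, h, w = blob.bbox
            shape = (top + h + 2, left + w + 2)
        rad = radius if radius is not None else evaluation_radius(models[0])
        refs = [reconstruct_body(np.asarray(t), rad, shape) for t in truths]
        per_backend: dict[str, list] = {}
        for backend in backends:
            poses = _predict_poses(
                blob, models, backend, scale, tolerance_fraction,
                similarity_threshold, rad,
            )
            bodies = [
                reconstruct_body(p, rad, shape) if p is not None else
                BodyMask(np.zeros(shape, bool), rad)
                for p in poses
            ]
            per_backend[backend] = bodies
            # index 1: match each prediction to its best ground truth
            used: set = set()
            for w_i, body in enumerate(bodies):
                scores = [
                    (iou(body, ref), r_i)
                    for r_i, ref in enumerate(refs) if r_i not in used
                ]
                val, r_i = max(scores)
                used.add(r_i)
                records.append(
                    dict(item=item_id, case=case, backend=backend, index=1,
                         worm=w_i, value=val)
                )
            if len(bodies) >= 2:
                for a in range(len(bodies)):
                    for b in range(a + 1, len(bodies)):
                        records.append(
                            dict(item=item_id, case=case, backend=backend,
                                 index=2, worm=-1,
                                 value=index2(bodies[a], bodies[b]))
                        )
    table = pd.DataFrame.from_records(records)
    rows = []
    for (case, idx), grp in table.groupby(["case", "index"]):
        piv = grp.pivot_table(index=["item", "worm"], columns="backend",
                              values="value")
        if not {"proposed", "classic"} <= set(piv.columns):
            continue
        rows.append(
            ComparisonRow(
                case=case, index=int(idx), n=len(piv),
                mean_new=float(piv["proposed"].mean()),
                mean_classic=float(piv["classic"].mean()),
                sd_new=float(piv["proposed"].std(ddof=0)),
                sd_classic=float(piv["classic"].std(ddof=0)),
            )
        )
    return rows, table
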