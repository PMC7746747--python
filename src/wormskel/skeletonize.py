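"""Classic thinning plus the width-aware background transform.

The background transform is the core of the method: foreground pixels whose
Euclidean distance to the background exceeds a per-worm width threshold are
flipped to background, iteratively until nothing more transforms. Where a
blob is wider than one worm's body — two worms in contact, or a body folded
onto itself — this carves a background line through the over-wide region so
that subsequent thinning produces one skeleton per body instead of a single
merged skeleton. Where every distance value already falls within the
expected width (the common, isolated-worm case) nothing is removed and the
result is exactly the classic skeleton.

Distance-map border convention: distances are measured to background
pixels visible inside the working crop, never to the area beyond it.
``border="array"`` (the default) uses the mask array as given, so the
background margin a blob crop carries is visible — the well-defined
reading of "distance to the closest background pixel". ``border="extend"``
restricts the window to the blob's tight bounding box, the convention of a
pipeline that hands around bare bounding-box subimages; it inflates
distances wherever the blob spans its crop and degenerates when no
background is visible at all, and is provided for comparison only (see
docs/methods.md for why neither convention can fully disconnect a merged
blob: every carved region is, by construction, surrounded by pixels within
the threshold distance of background, which survive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import thin

__all__ = [
    "SkeletonMask",
    "BackgroundTransformResult",
    "classic_skeleton",
    "scale_mask",
    "background_transform",
    "fill_small_skeleton_holes",
    "improved_skeleton",
]

_EIGHT = np.ones((3, 3), bool)


@dataclass(frozen=True)
class SkeletonMask:
    """A 1-px-wide thinning fixpoint, tagged with the working scale
    (1 = original resolution, 3 = default scaled space)."""

    mask: np.ndarray
    scale: int = 1

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class BackgroundTransformResult:
    """Outcome of the iterative background transform."""

    mask: np.ndarray
    iterations: int
    removed_per_iteration: tuple[int, ...] = field(default_factory=tuple)

    @property
    def removed_total(self) -> int:
        return int(sum(self.removed_per_iteration))


def classic_skeleton(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving morphological thinning iterated to idempotence.

    Component and hole counts of the input are preserved; the result is a
    1-px-wide 8-connected skeleton and a fixpoint of further thinning.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, bool)
    return thin(mask)


def scale_mask(mask: np.ndarray, factor: int = 3) -> np.ndarray:
    """Nearest-neighbour upscaling: each pixel becomes a factor x factor
    block. Binarity and connectivity are preserved; distance values in the
    scaled mask are approximately ``factor`` times the originals."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    mask = np.asarray(mask, bool)
    if factor == 1:
        return mask.copy()
    return np.repeat(np.repeat(mask, factor, axis=0), factor, axis=1)


def _window_distance(
    mask: np.ndarray, window: tuple[slice, slice] | None
) -> np.ndarray:
    """Euclidean distance map within a crop window.

    Distances are measured to background pixels visible *inside* the
    window; the area beyond it does not count as background (a body may
    continue past the crop). ``window=None`` uses the whole array — the
    in-array semantics of any distance transform applied to a cropped
    subimage.
    """
    if window is None:
        window = (slice(None), slice(None))
    sub = mask[window]
    d = np.zeros(mask.shape, float)
    if (~sub).any():
        d[window] = ndimage.distance_transform_edt(sub)
    else:
        # Degenerate: no background visible inside the crop, so every
        # distance is unbounded — wider than any threshold.
        d[window] = np.inf
    return d


def background_transform(
    mask: np.ndarray,
    width_threshold: float,
    border: str = "array",
) -> BackgroundTransformResult:
    """Iteratively flip to background every foreground pixel whose distance
    value is strictly greater than ``width_threshold``.

    Each round recomputes the distance map on the shrunken mask; the loop
    stops when a round removes nothing. The mask only ever shrinks, and with
    a constant threshold the recomputed distances can only shrink as well,
    so in practice one removal round reaches the fixpoint; the loop form is
    kept because the stopping rule is "no pixel transforms".
    """
    if width_threshold <= 0:
        raise ValueError("width_threshold must be > 0")
    m = np.asarray(mask, bool).copy()
    if border == "extend":
        rs, cs = np.nonzero(m)
        window = (
            (slice(rs.min(), rs.max() + 1), slice(cs.min(), cs.max() + 1))
            if len(rs)
            else None
        )
    elif border == "array":
        window = None
    else:
        raise ValueError(f"unknown border convention {border!r}")
    removed: list[int] = []
    while m.any():
        d = _window_distance(m, window)
        rm = m & (d > width_threshold)
        n = int(rm.sum())
        if n == 0:
            break
        m &= ~rm
        removed.append(n)
    return BackgroundTransformResult(
        mask=m, iterations=len(removed), removed_per_iteration=tuple(removed)
    )


def fill_small_skeleton_holes(
    skel: SkeletonMask | np.ndarray, max_hole_px: int = 4
) -> SkeletonMask:
    """Fill enclosed background holes of fewer than ``max_hole_px`` pixels in
    a skeleton and re-thin.

    Tiny loops left behind by an imperfectly carved background line would
    otherwise spawn many near-identical candidate poses. Holes are
    4-connected background components that do not touch the array border;
    holes of ``max_hole_px`` or more pixels are genuine (a rolled body's
    open centre) and are kept.
    """
    scale = skel.scale if isinstance(skel, SkeletonMask) else 1
    m = np.asarray(skel.mask if isinstance(skel, SkeletonMask) else skel, bool)
    bg_labels, n = ndimage.label(~m)  # 4-connectivity for background
    if n:
        border = np.zeros(m.shape, bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        border_ids = np.unique(bg_labels[border & ~m])
        sizes = ndimage.sum_labels(np.ones(m.shape), bg_labels, np.arange(1, n + 1))
        fill = np.zeros(n + 1, bool)
        for lab in range(1, n + 1):
            if lab not in border_ids and sizes[lab - 1] < max_hole_px:
                fill[lab] = True
        if fill.any():
            m = m | fill[bg_labels]
            m = classic_skeleton(m)
    return SkeletonMask(mask=m, scale=scale)


def _components(mask: np.ndarray) -> list[np.ndarray]:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    return [labels == i for i in range(1, n + 1)]


def improved_skeleton(
    blob,
    model,
    mode: str = "aggregated",
    scale: int = 3,
    max_hole_px: int = 4,
    border: str = "array",
) -> tuple[list[SkeletonMask], BackgroundTransformResult]:
    """Width-aware skeletonisation of one blob.

    Pipeline: upscale by ``scale`` -> background transform at threshold
    ``scale * w_max`` (aggregated mode, for multi-worm blobs) or
    ``scale * w_min`` (rolled mode, for a single coiled body) -> classic
    skeleton -> in rolled mode, fill skeleton holes smaller than
    ``max_hole_px`` and re-thin. The skeleton is returned split into
    8-connected components, in scaled-space coordinates with the scale
    recorded. If the transform removed nothing the single component is
    exactly the classic skeleton of the scaled blob.
    """
    if mode not in ("aggregated", "rolled"):
        raise ValueError(f"mode must be 'aggregated' or 'rolled', got {mode!r}")
    mask = np.asarray(getattr(blob, "mask", blob), bool)
    if not mask.any():
        raise ValueError("empty blob")
    threshold = scale * (model.w_max if mode == "aggregated" else model.w_min)
    big = scale_mask(mask, scale)
    result = background_transform(big, threshold, border=border)
    if not result.mask.any():
        raise ValueError(
            "blob vanished under the background transform; "
            "width model does not match this blob"
        )
    skel = classic_skeleton(result.mask)
    if mode == "rolled":
        skel = fill_small_skeleton_holes(SkeletonMask(skel, scale), max_hole_px).mask
    comps = [SkeletonMask(mask=c, scale=scale) for c in _components(skel)]
    return comps, result
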