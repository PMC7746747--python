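"""Candidate worm poses from skeleton graphs, scoring, and sequence tracking.

A skeleton is organised into a graph of endpoints (1 skeleton neighbour),
junctions (>= 3 neighbours) and branches (pixel runs between them); isolated
cycles — fully rolled bodies — are kept separately. Candidate poses are the
simple node-to-node paths whose pixel count is close to the worm's expected
length; for cycles, open walks around the loop. Near-duplicate candidates
are dropped when their dilated bodies overlap at least 90%, and the
remaining cross-combinations are scored against each worm's width/length
model and its previous pose; the minimum-cost combination, with a penalty
for skeleton pixels left uncovered, gives the per-frame pose of each worm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .segmentation import Blob, crop_blob
from .skeletonize import SkeletonMask, classic_skeleton, improved_skeleton, scale_mask
from .worm_model import WormModel, distance_map, estimate_worm_model

__all__ = [
    "Pose",
    "SkeletonGraph",
    "TrackState",
    "build_skeleton_graph",
    "enumerate_poses",
    "enumerate_cyclic_poses",
    "filter_similar_poses",
    "pose_cost",
    "select_best_combination",
    "track_sequence",
]

_NBRS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# poses


@dataclass(frozen=True)
class Pose:
    """An ordered pixel path for one worm at one frame.

    ``points`` are integer (row, col) pixels in the working-scale image;
    consecutive points are 8-adjacent and no pixel repeats. ``scale`` and
    ``offset`` place the working image in the original frame:
    ``frame_points`` are sub-pixel original-frame coordinates. A pose and
    its reversal are the same pose.
    """

    points: np.ndarray
    scale: int = 1
    offset: tuple[int, int] = (0, 0)
    frame: int | None = None
    worm_id: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, int))

    @property
    def length(self) -> int:
        return len(self.points)

    @property
    def frame_points(self) -> np.ndarray:
        """Original-frame sub-pixel coordinates (block-center mapping)."""
        p = self.points.astype(float)
        return (p - (self.scale - 1) / 2) / self.scale + np.asarray(self.offset)

    @property
    def arc_length(self) -> float:
        """Geometric path length in original-frame units (sum of inter-pixel
        steps; diagonal steps count sqrt(2)), as opposed to ``length`` which
        is the pixel-count convention used by the worm model."""
        fp = self.frame_points
        if len(fp) < 2:
            return 0.0
        return float(np.hypot(*np.diff(fp, axis=0).T).sum())

    def canonical_key(self) -> tuple:
        fwd = tuple(map(tuple, self.points))
        rev = tuple(reversed(fwd))
        return min(fwd, rev)

    def with_identity(self, frame: int | None, worm_id: int | None) -> "Pose":
        return Pose(self.points, self.scale, self.offset, frame, worm_id)

    def validate(self) -> None:
        p = self.points
        if len(p) != len({tuple(q) for q in p}):
            raise ValueError("pose repeats a pixel")
        if len(p) > 1:
            step = np.abs(np.diff(p, axis=0)).max(axis=1)
            if (step > 1).any() or (step == 0).any():
                raise ValueError("consecutive pose pixels must be 8-adjacent")


def _body_pixels(pose: Pose, radius: int) -> set[tuple[int, int]]:
    """Pixel set of the pose body: rounded frame coordinates dilated with a
    disk of the given radius."""
    pts = np.rint(pose.frame_points).astype(int)
    offs = np.argwhere(disk(radius)) - radius if radius > 0 else np.array([[0, 0]])
    body = pts[:, None, :] + offs[None, :, :]
    return set(map(tuple, body.reshape(-1, 2)))


def _body_iou(a: Pose, b: Pose, radius: int) -> float:
    pa, pb = _body_pixels(a, radius), _body_pixels(b, radius)
    union = len(pa | pb)
    return len(pa & pb) / union if union else 0.0


# ---------------------------------------------------------------------------
# skeleton graph


@dataclass(frozen=True)
class SkeletonGraph:
    """Endpoints/junctions plus branch pixel runs of a skeleton; components
    with neither endpoints nor junctions are recorded as cycles."""

    nodes: tuple[tuple[int, int], ...]
    node_kind: dict  # node -> "endpoint" | "junction" | "isolated"
    branches: tuple[tuple[tuple[int, int], tuple[int, int], tuple], ...]
    # each branch: (node_u, node_v, pixel run u..v inclusive)
    cycles: tuple[tuple, ...]  # ordered pixel loops
    scale: int = 1

    @property
    def endpoints(self) -> list[tuple[int, int]]:
        return [n for n in self.nodes if self.node_kind[n] == "endpoint"]

    @property
    def junctions(self) -> list[tuple[int, int]]:
        return [n for n in self.nodes if self.node_kind[n] == "junction"]


def _adjacency(pixels: set[tuple[int, int]]) -> dict:
    """8-adjacency between skeleton pixels, with diagonal shortcuts pruned:
    a diagonal link is dropped when the two pixels already share an
    orthogonal skeleton neighbour, so paths pass through it instead."""
    adj: dict = {p: [] for p in pixels}
    for r, c in pixels:
        for dr, dc in _NBRS8:
            q = (r + dr, c + dc)
            if q not in pixels:
                continue
            if dr and dc:
                if (r, c + dc) in pixels or (r + dr, c) in pixels:
                    continue
            adj[(r, c)].append(q)
    return adj


def build_skeleton_graph(skel: SkeletonMask | np.ndarray) -> SkeletonGraph:
    """Organise a thinned skeleton (possibly several components) into
    endpoints, junctions, branches and cycles."""
    scale = skel.scale if isinstance(skel, SkeletonMask) else 1
    mask = np.asarray(skel.mask if isinstance(skel, SkeletonMask) else skel, bool)
    pixels = set(map(tuple, np.argwhere(mask)))
    adj = _adjacency(pixels)
    deg = {p: len(adj[p]) for p in pixels}
    nodes = sorted(p for p in pixels if deg[p] != 2)
    kind = {
        p: ("isolated" if deg[p] == 0 else "endpoint" if deg[p] == 1 else "junction")
        for p in nodes
    }
    node_set = set(nodes)

    branches = []
    used = set()  # directed pixel pairs consumed by a branch walk
    for u in nodes:
        for first in sorted(adj[u]):
            if (u, first) in used:
                continue
            run = [u, first]
            used.add((u, first))
            prev, cur = u, first
            while cur not in node_set:
                nxt = [q for q in adj[cur] if q != prev]
                if not nxt:
                    break  # dead end without a node (should not happen)
                prev, cur = cur, nxt[0]
                run.append(cur)
            used.add((run[-1], run[-2]))
            branches.append((u, run[-1], tuple(run)))

    # components made purely of degree-2 pixels are cycles
    in_branch = {p for _, _, run in branches for p in run}
    cycles = []
    remaining = sorted(pixels - in_branch - node_set)
    seen: set = set()
    for start in remaining:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxt = [q for q in adj[cur] if q != prev and (q == start or q not in seen)]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            if cur == start:
                break
            loop.append(cur)
            seen.add(cur)
        cycles.append(tuple(loop))

    return SkeletonGraph(
        nodes=tuple(nodes),
        node_kind=kind,
        branches=tuple(branches),
        cycles=tuple(cycles),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# pose enumeration


def enumerate_poses(
    graph: SkeletonGraph,
    expected_length: float,
    tolerance_fraction: float = 0.25,
    offset: tuple[int, int] = (0, 0),
    max_poses: int = 500,
) -> list[Pose]:
    """All simple node-to-node paths whose pixel count is within
    ``tolerance_fraction * expected_length`` of ``expected_length``,
    reversal-deduplicated. Different poses may share branches (needed for
    aggregated blobs); within one pose no pixel repeats.
    """
    if expected_length <= 0:
        raise ValueError("expected_length must be > 0")
    lo = expected_length * (1 - tolerance_fraction)
    hi = expected_length * (1 + tolerance_fraction)

    incident: dict = {n: [] for n in graph.nodes}
    for b_idx, (u, v, run) in enumerate(graph.branches):
        incident[u].append((b_idx, v, run))
        if v != u:
            incident[v].append((b_idx, u, tuple(reversed(run))))

    out: dict = {}

    def dfs(node, path, used_branches, used_pixels):
        if len(out) >= max_poses:
            return
        if len(path) > hi:
            return
        if lo <= len(path) <= hi:
            pose = Pose(np.asarray(path), scale=graph.scale, offset=offset)
            out.setdefault(pose.canonical_key(), pose)
        for b_idx, other, run in incident[node]:
            if b_idx in used_branches:
                continue
            ext = run[1:]
            if used_pixels.intersection(ext[:-1] if other == path[0] else ext):
                continue
            if other == path[0] and len(ext) > 1:
                continue  # closing back onto the start pixel
            dfs(other, path + list(ext), used_branches | {b_idx},
                used_pixels | set(ext))

    for start in graph.nodes:
        dfs(start, [start], set(), {start})
    if len(out) >= max_poses:
        warnings.warn(f"pose enumeration capped at {max_poses} candidates")
    return sorted(out.values(), key=lambda p: (-p.length, p.canonical_key()))


def enumerate_cyclic_poses(
    graph: SkeletonGraph,
    expected_length: float,
    offset: tuple[int, int] = (0, 0),
    stride: int = 2,
    seed_points: Iterable[tuple[int, int]] | None = None,
) -> list[Pose]:
    """Open poses from endpoint-free components: walk each cycle from
    sampled start pixels for ``expected_length`` pixels.

    When a previous pose is available its pixels seed the start points
    (skeleton points overlapping the earlier pose); otherwise starts are
    sampled every ``stride`` pixels around the loop. Walks longer than the
    loop are impossible (a simple path cannot revisit pixels) and yield
    nothing.
    """
    want = int(round(expected_length))
    poses: dict = {}
    seeds = {tuple(p) for p in seed_points} if seed_points is not None else None
    for loop in graph.cycles:
        n = len(loop)
        if want > n or want < 2:
            continue
        if seeds is not None:
            starts = [i for i, p in enumerate(loop) if p in seeds]
            if not starts:
                starts = list(range(0, n, stride))
        else:
            starts = list(range(0, n, stride))
        for s in starts:
            walk = [loop[(s + k) % n] for k in range(want)]
            pose = Pose(np.asarray(walk), scale=graph.scale, offset=offset)
            poses.setdefault(pose.canonical_key(), pose)
    return sorted(poses.values(), key=lambda p: (-p.length, p.canonical_key()))


def filter_similar_poses(
    poses: Sequence[Pose],
    overlap_threshold: float = 0.90,
    radius: int = 2,
    max_poses: int = 50,
) -> list[Pose]:
    """Greedy de-duplication: longest first, a pose is dropped when its
    dilated-body IoU with an already retained pose reaches the threshold.
    Bodies (not raw 1-px paths) are compared so near-parallel centerlines
    register as overlapping."""
    ordered = sorted(poses, key=lambda p: (-p.length, p.canonical_key()))
    kept: list[Pose] = []
    kept_bodies: list[set] = []
    for pose in ordered:
        body = _body_pixels(pose, radius)
        dup = False
        for other in kept_bodies:
            union = len(body | other)
            if union and len(body & other) / union >= overlap_threshold:
                dup = True
                break
        if not dup:
            kept.append(pose)
            kept_bodies.append(body)
            if len(kept) >= max_poses:
                break
    return kept


# ---------------------------------------------------------------------------
# scoring and selection


def pose_cost(
    pose: Pose,
    model: WormModel,
    dmap: np.ndarray,
    previous: Pose | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    radius: int | None = None,
) -> float:
    """Cost of one candidate pose under a worm model.

    Three criteria: relative deviation of pose length from the model length;
    deviation of the mean distance value along the pose from the model's
    mid half-width, normalised by w_max; and one minus the body IoU with the
    worm's previous pose (omitted when there is none). ``dmap`` is the
    distance map of the working-scale blob (before carving), so widths along
    the pose are measured on the real body.
    """
    w_len, w_wid, w_prev = weights
    length = pose.length / pose.scale
    cost = w_len * abs(length - model.length) / model.length
    mean_w = float(dmap[tuple(pose.points.T)].mean()) / pose.scale
    mid_w = (model.w_max + model.w_min) / 2
    cost += w_wid * abs(mean_w - mid_w) / model.w_max
    if previous is not None:
        if radius is None:
            radius = int(np.clip(round(model.w_min), 1, 2))
        cost += w_prev * (1.0 - _body_iou(pose, previous, radius))
    return float(cost)


def select_best_combination(
    candidates: Sequence[Sequence[Pose]],
    models: Sequence[WormModel],
    dmap: np.ndarray,
    previous_poses: Sequence[Pose | None] | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    coverage_weight: float = 1.0,
    skeleton_mask: np.ndarray | None = None,
    max_combinations: int = 10_000,
) -> tuple[list[Pose | None], float]:
    """Exhaustively score all cross-combinations of per-worm candidates and
    return the minimum-cost assignment.

    Total cost = sum of pose costs + ``coverage_weight`` times the fraction
    of skeleton pixels not covered by any assigned pose. Worms with no
    candidates are marked lost (None). Ties break toward larger total
    covered length, then lexicographic pixel order.
    """
    n = len(candidates)
    if previous_poses is None:
        previous_poses = [None] * n
    if not any(candidates):
        raise ValueError("at least one worm must have at least one candidate")

    skel_pixels: set = (
        set(map(tuple, np.argwhere(skeleton_mask))) if skeleton_mask is not None else set()
    )

    live = [i for i in range(n) if candidates[i]]
    costs = {
        (i, j): pose_cost(p, models[i], dmap, previous_poses[i], weights)
        for i in live
        for j, p in enumerate(candidates[i])
    }
    total = int(np.prod([len(candidates[i]) for i in live]))
    if total > max_combinations:
        warnings.warn(
            f"{total} pose combinations; evaluating the first {max_combinations}"
        )

    best = None
    for k, combo in enumerate(product(*(range(len(candidates[i])) for i in live))):
        if k >= max_combinations:
            break
        poses = [candidates[i][j] for i, j in zip(live, combo)]
        cost = sum(costs[(i, j)] for i, j in zip(live, combo))
        covered_len = sum(p.length for p in poses)
        if skel_pixels:
            covered = set()
            for p in poses:
                covered.update(map(tuple, p.points))
            cost += coverage_weight * (
                len(skel_pixels - covered) / len(skel_pixels)
            )
        key = (cost, -covered_len, tuple(p.canonical_key() for p in poses))
        if best is None or key < best[0]:
            best = (key, poses)
    assignment: list[Pose | None] = [None] * n
    for i, p in zip(live, best[1]):
        assignment[i] = p
    return assignment, float(best[0][0])


# ---------------------------------------------------------------------------
# sequence tracking


@dataclass
class TrackState:
    """One worm's identity: its model, per-frame poses and status flags."""

    worm_id: int
    model: WormModel
    poses: dict = field(default_factory=dict)  # frame -> Pose
    status: dict = field(default_factory=dict)  # frame -> str

    def pose_at(self, frame: int) -> Pose | None:
        return self.poses.get(frame)


def _frame_blobs(mask: np.ndarray, min_area: int = 3) -> list[Blob]:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    blobs = []
    for lab in range(1, n + 1):
        if int((labels == lab).sum()) >= min_area:
            blobs.append(crop_blob(mask, lab, labels, blob_id=lab))
    return blobs


def _is_simple_worm(blob: Blob) -> bool:
    """A separate, non-self-occluded worm: skeleton is one open path."""
    skel = classic_skeleton(blob.mask)
    if int(skel.sum()) < 3:
        return False
    g = build_skeleton_graph(skel)
    return (
        len(g.cycles) == 0
        and len(g.junctions) == 0
        and len(g.endpoints) == 2
        and len(g.branches) == 1
    )


def _path_pose(blob: Blob) -> Pose:
    g = build_skeleton_graph(classic_skeleton(blob.mask))
    run = max(g.branches, key=lambda b: len(b[2]))[2]
    return Pose(np.asarray(run), scale=1, offset=blob.offset)


def _blob_for_worm(blobs: list[Blob], prev: Pose, radius: int = 2) -> int | None:
    """Blob containing (most of) the worm's previous pose body; nearest blob
    by pixel distance to the pose when nothing overlaps (fast motion)."""
    body = np.asarray(sorted(_body_pixels(prev, radius)))
    best, best_hits = None, 0
    for k, blob in enumerate(blobs):
        t, l = blob.offset
        local = body - (t, l)
        ok = (
            (local[:, 0] >= 0)
            & (local[:, 0] < blob.mask.shape[0])
            & (local[:, 1] >= 0)
            & (local[:, 1] < blob.mask.shape[1])
        )
        hits = int(blob.mask[tuple(local[ok].T)].sum()) if ok.any() else 0
        if hits > best_hits:
            best, best_hits = k, hits
    if best is not None:
        return best
    pts = prev.frame_points
    dists = []
    for blob in blobs:
        t, l = blob.offset
        pix = np.argwhere(blob.mask) + (t, l)
        d = np.hypot(
            *(pix[:, None, :] - pts[None, :, :]).transpose(2, 0, 1)
        ).min()
        dists.append(d)
    return int(np.argmin(dists)) if dists else None


def _candidates_for_worm(
    graph: SkeletonGraph,
    model: WormModel,
    offset: tuple[int, int],
    tolerance_fraction: float,
    previous: Pose | None,
    similarity_threshold: float,
    radius: int,
) -> list[Pose]:
    expected = model.length * graph.scale
    poses = enumerate_poses(graph, expected, tolerance_fraction, offset)
    if graph.cycles:
        seeds = None
        if previous is not None:
            prev_pts = np.rint(previous.frame_points).astype(int)
            scaled = prev_pts * graph.scale - np.asarray(offset) * graph.scale
            seeds = map(tuple, scaled + (graph.scale - 1) // 2)
        poses += enumerate_cyclic_poses(graph, expected, offset, seed_points=seeds)
    return filter_similar_poses(poses, similarity_threshold, radius)


def track_sequence(
    masks: Sequence[np.ndarray],
    initial_models: Sequence[WormModel] | None = None,
    default: WormModel | None = None,
    scale: int = 3,
    tolerance_fraction: float = 0.25,
    similarity_threshold: float = 0.90,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    rolled_length_factor: float = 0.7,
) -> list[TrackState]:
    """Track every worm of one track across a sequence of binary worm masks.

    The tracker finds a reference frame where all worms are separate and not
    self-occluded (each blob skeletonises to a single open path), estimates
    each worm's model there, then propagates identities forward and backward
    from it. Single-worm blobs whose skeleton closes into a cycle or falls
    well short of the model length are re-skeletonised in rolled mode
    (minimum-width threshold); multi-worm blobs in aggregated mode
    (maximum-width threshold); candidate poses are scored against the model
    and the worm's previous pose.
    """
    masks = [np.asarray(m, bool) for m in masks]
    if not masks:
        raise ValueError("empty sequence")
    per_frame_blobs = [_frame_blobs(m) for m in masks]

    n_worms = max((len(b) for b in per_frame_blobs), default=0)
    ref = None
    for t, blobs in enumerate(per_frame_blobs):
        if len(blobs) == n_worms and n_worms > 0 and all(map(_is_simple_worm, blobs)):
            ref = t
            break
    if ref is None:
        if default is None and initial_models is None:
            raise ValueError(
                "no frame with all worms separate; provide default_model output"
            )
        ref = int(np.argmax([len(b) for b in per_frame_blobs]))

    ref_blobs = sorted(
        per_frame_blobs[ref], key=lambda b: (b.bbox[0], b.bbox[1])
    )
    if initial_models is not None:
        models = list(initial_models)
        n_worms = len(models)
    else:
        models = []
        for i, blob in enumerate(ref_blobs):
            try:
                models.append(estimate_worm_model(blob, worm_id=i, source_frame=ref))
            except ValueError:
                if default is None:
                    raise
                models.append(default)
    tracks = [TrackState(worm_id=i, model=models[i]) for i in range(n_worms)]

    for i, blob in enumerate(ref_blobs[:n_worms]):
        pose = _path_pose(blob).with_identity(ref, i)
        tracks[i].poses[ref] = pose
        tracks[i].status[ref] = "separate"

    order = list(range(ref + 1, len(masks))) + list(range(ref - 1, -1, -1))
    for t in order:
        prev_t = t - 1 if t > ref else t + 1
        blobs = per_frame_blobs[t]
        if not blobs:
            for tr in tracks:
                tr.status[t] = "lost"
            continue
        # assign each worm to a blob via its previous pose
        groups: dict[int, list[int]] = {}
        for tr in tracks:
            prev = tr.pose_at(prev_t)
            if prev is None:
                tr.status[t] = "lost"
                continue
            k = _blob_for_worm(blobs, prev)
            groups.setdefault(k, []).append(tr.worm_id)
        for k, worm_ids in groups.items():
            blob = blobs[k]
            prevs = [tracks[i].pose_at(prev_t) for i in worm_ids]
            mods = [tracks[i].model for i in worm_ids]
            radius = int(np.clip(round(min(m.w_min for m in mods)), 1, 2))
            if len(worm_ids) == 1 and _is_simple_worm(blob):
                skel = classic_skeleton(blob.mask)
                n_skel = int(skel.sum())
                if n_skel >= rolled_length_factor * mods[0].length:
                    i = worm_ids[0]
                    tracks[i].poses[t] = _path_pose(blob).with_identity(t, i)
                    tracks[i].status[t] = "separate"
                    continue
            mode = "rolled" if len(worm_ids) == 1 else "aggregated"
            try:
                comps, _ = improved_skeleton(blob, mods[0] if mode == "rolled"
                                             else max(mods, key=lambda m: m.w_max),
                                             mode=mode, scale=scale)
            except ValueError:
                for i in worm_ids:
                    tracks[i].status[t] = "lost"
                continue
            union = np.zeros(comps[0].mask.shape, bool)
            for c in comps:
                union |= c.mask
            graph = build_skeleton_graph(SkeletonMask(union, scale))
            offset = blob.offset
            dmap = distance_map(scale_mask(blob.mask, scale))
            cands = [
                _candidates_for_worm(
                    graph, tracks[i].model, offset, tolerance_fraction,
                    tracks[i].pose_at(prev_t), similarity_threshold, radius,
                )
                for i in worm_ids
            ]
            if not any(cands):
                for i in worm_ids:
                    tracks[i].status[t] = "lost"
                continue
            assignment, _ = select_best_combination(
                cands,
                [tracks[i].model for i in worm_ids],
                dmap,
                previous_poses=[tracks[i].pose_at(prev_t) for i in worm_ids],
                weights=weights,
                skeleton_mask=union,
            )
            for i, pose in zip(worm_ids, assignment):
                if pose is None:
                    tracks[i].status[t] = "lost"
                else:
                    tracks[i].poses[t] = pose.with_identity(t, i)
                    tracks[i].status[t] = mode
    return tracks
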