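"""Skeleton graphs, pose enumeration/filtering/scoring, combination
selection, and sequence tracking."""

import numpy as np
import pytest

from wormskel import (
    Pose,
    SkeletonMask,
    WormModel,
    WormSpec,
    build_skeleton_graph,
    classic_skeleton,
    crop_blob,
    crossing_sequence,
    distance_map,
    enumerate_cyclic_poses,
    enumerate_poses,
    filter_similar_poses,
    generate_coiled_worm,
    generate_worm,
    pose_cost,
    select_best_combination,
    track_sequence,
)
from wormskel.pose_tracking import _body_iou

# ---------------------------------------------------------------------------
# helpers


def mask_from_pixels(pixels, shape=(20, 20)):
    m = np.zeros(shape, bool)
    for r, c in pixels:
        m[r, c] = True
    return m


def line_mask(n=12):
    return mask_from_pixels([(5, 3 + i) for i in range(n)])


def t_mask():
    pixels = [(5, 3 + i) for i in range(9)] + [(5 + j, 7) for j in range(1, 6)]
    return mask_from_pixels(pixels)


def x_mask(arm=6):
    """Diagonal X: four arms meeting at one centre pixel."""
    c = 8
    pixels = {(c, c)}
    for k in range(1, arm + 1):
        pixels |= {(c - k, c - k), (c - k, c + k), (c + k, c - k), (c + k, c + k)}
    return mask_from_pixels(pixels)


def brute_force_paths(mask, lo, hi):
    """All simple node-to-node pixel paths with length in [lo, hi], found by
    plain DFS over the raw pixel adjacency — the enumeration oracle."""
    from wormskel.pose_tracking import _adjacency

    pixels = set(map(tuple, np.argwhere(mask)))
    adj = _adjacency(pixels)
    deg = {p: len(adj[p]) for p in pixels}
    nodes = [p for p in pixels if deg[p] != 2]
    found = set()

    def walk(path, seen):
        cur = path[-1]
        if len(path) > hi:
            return
        if cur in nodes and len(path) >= 2 and lo <= len(path) <= hi:
            fwd = tuple(path)
            found.add(min(fwd, tuple(reversed(fwd))))
        for q in adj[cur]:
            if q not in seen:
                walk(path + [q], seen | {q})

    for start in nodes:
        walk([start], {start})
    return found


# ---------------------------------------------------------------------------
# graph construction


class TestBuildSkeletonGraph:
    def test_straight_line(self):
        g = build_skeleton_graph(line_mask(12))
        assert len(g.endpoints) == 2
        assert len(g.junctions) == 0
        assert len(g.branches) == 1
        assert len(g.branches[0][2]) == 12
        assert len(g.cycles) == 0

    def test_t_shape(self):
        g = build_skeleton_graph(t_mask())
        assert len(g.endpoints) == 3
        assert len(g.junctions) == 1
        assert len(g.branches) == 3
        # every skeleton pixel belongs to exactly one branch (junction shared)
        runs = [set(b[2]) for b in g.branches]
        junction = set(g.junctions)
        all_px = set.union(*runs)
        assert all_px == set(map(tuple, np.argwhere(t_mask())))
        for i in range(3):
            for j in range(i + 1, 3):
                assert runs[i] & runs[j] <= junction

    def test_closed_ring(self):
        mask, _ = generate_coiled_worm(8, 1.2, 1.0, (35, 35))
        g = build_skeleton_graph(classic_skeleton(mask))
        assert len(g.endpoints) == 0 and len(g.junctions) == 0
        assert len(g.cycles) == 1
        loop = g.cycles[0]
        # the loop is a closed 8-connected walk without repeats
        assert len(set(loop)) == len(loop)
        arr = np.asarray(loop + (loop[0],))
        assert (np.abs(np.diff(arr, axis=0)).max(axis=1) == 1).all()


# ---------------------------------------------------------------------------
# enumeration


class TestEnumeratePoses:
    def test_line_of_exact_length_gives_one_pose(self):
        g = build_skeleton_graph(line_mask(12))
        poses = enumerate_poses(g, expected_length=12, tolerance_fraction=0.25)
        assert len(poses) == 1
        poses[0].validate()
        assert poses[0].length == 12

    def test_too_short_line_gives_nothing(self):
        g = build_skeleton_graph(line_mask(5))
        assert enumerate_poses(g, 12, 0.25) == []

    @pytest.mark.parametrize(
        "maker,expected,tol",
        [(x_mask, 13, 0.25), (t_mask, 9, 0.4), (x_mask, 13, 0.6)],
    )
    def test_matches_brute_force_oracle(self, maker, expected, tol):
        """Exact set equality with a raw-pixel DFS on small graphs."""
        mask = maker()
        g = build_skeleton_graph(mask)
        assert len(g.nodes) <= 8
        got = {p.canonical_key() for p in enumerate_poses(g, expected, tol)}
        want = brute_force_paths(
            mask, expected * (1 - tol), expected * (1 + tol)
        )
        assert got == want

    def test_x_shape_straight_through_paths(self):
        """On an X, the full-diagonal expected length admits both
        straight-through paths and the bent arm pairs of equal length."""
        g = build_skeleton_graph(x_mask(6))
        poses = enumerate_poses(g, expected_length=13, tolerance_fraction=0.05)
        # any two of the four arms join into a 13-px path: C(4,2) = 6
        assert len(poses) == 6
        for p in poses:
            p.validate()
            assert p.length == 13

    def test_poses_may_share_branches(self):
        g = build_skeleton_graph(x_mask(6))
        poses = enumerate_poses(g, 13, 0.05)
        pix = [set(map(tuple, p.points)) for p in poses]
        assert pix[0] & pix[1]  # overlapping candidates coexist


class TestEnumerateCyclicPoses:
    def test_ring_walks_cover_circumference(self):
        mask, _ = generate_coiled_worm(8, 1.2, 1.0, (35, 35))
        g = build_skeleton_graph(classic_skeleton(mask))
        n = len(g.cycles[0])
        poses = enumerate_cyclic_poses(g, expected_length=n)
        assert poses
        for p in poses:
            p.validate()
            assert p.length == n

    def test_expected_longer_than_cycle_gives_nothing(self):
        mask, _ = generate_coiled_worm(8, 1.2, 1.0, (35, 35))
        g = build_skeleton_graph(classic_skeleton(mask))
        assert enumerate_cyclic_poses(g, 10 * len(g.cycles[0])) == []

    def test_seeded_starts_reduce_candidates(self):
        mask, _ = generate_coiled_worm(8, 1.2, 1.0, (35, 35))
        g = build_skeleton_graph(classic_skeleton(mask))
        n = len(g.cycles[0])
        seeded = enumerate_cyclic_poses(
            g, n - 4, seed_points=[g.cycles[0][0]]
        )
        free = enumerate_cyclic_poses(g, n - 4)
        assert len(seeded) <= len(free)
        assert len(seeded) >= 1


# ---------------------------------------------------------------------------
# filtering and scoring


def straight_pose(row, cols, offset=(0, 0)):
    return Pose(np.array([(row, c) for c in cols]), scale=1, offset=offset)


class TestFilterSimilarPoses:
    def test_exact_duplicates_collapse(self):
        a = straight_pose(5, range(3, 15))
        b = straight_pose(5, range(3, 15))
        assert len(filter_similar_poses([a, b])) == 1

    def test_disjoint_poses_survive(self):
        a = straight_pose(5, range(3, 15))
        b = straight_pose(15, range(3, 15))
        out = filter_similar_poses([a, b])
        assert len(out) == 2

    def test_output_is_subset_below_threshold(self):
        rng = np.random.default_rng(3)
        poses = [
            straight_pose(5 + int(rng.integers(0, 3)), range(3, 15 + int(rng.integers(0, 4))))
            for _ in range(12)
        ]
        out = filter_similar_poses(poses, overlap_threshold=0.90, radius=2)
        keys = {p.canonical_key() for p in poses}
        assert all(p.canonical_key() in keys for p in out)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert _body_iou(out[i], out[j], 2) < 0.90

    def test_ninety_five_percent_overlap_is_dropped(self):
        a = straight_pose(5, range(0, 40))
        b = straight_pose(5, range(0, 39))  # bodies share ~97% of pixels
        assert len(filter_similar_poses([a, b])) == 1


class TestPoseCost:
    def setup_method(self):
        spec = WormSpec.straight((10, 5), (10, 35), half_width=1.5)
        self.mask, _ = generate_worm(spec, (21, 41))
        self.blob = crop_blob(self.mask)
        self.dmap = distance_map(self.blob.mask)
        skel = classic_skeleton(self.blob.mask)
        g = build_skeleton_graph(SkeletonMask(skel, 1))
        self.pose = enumerate_poses(g, 28, 0.25)[0]

    def test_exact_match_costs_zero(self):
        n = self.pose.length
        mean_w = float(self.dmap[tuple(self.pose.points.T)].mean())
        model = WormModel(w_max=mean_w, w_min=mean_w, length=n)
        cost = pose_cost(self.pose, model, self.dmap, previous=self.pose)
        assert cost == pytest.approx(0.0, abs=1e-9)

    def test_length_term_is_linear(self):
        base = WormModel(w_max=2.0, w_min=1.5, length=self.pose.length)
        c0 = pose_cost(self.pose, base, self.dmap, weights=(1, 0, 0))
        m1 = WormModel(w_max=2.0, w_min=1.5, length=self.pose.length + 8)
        m2 = WormModel(w_max=2.0, w_min=1.5, length=self.pose.length + 16)
        c1 = pose_cost(self.pose, m1, self.dmap, weights=(1, 0, 0))
        c2 = pose_cost(self.pose, m2, self.dmap, weights=(1, 0, 0))
        assert c0 == pytest.approx(0.0)
        assert c2 / c1 == pytest.approx(2 * m1.length / m2.length, rel=1e-6)

    def test_previous_pose_term_rewards_overlap(self):
        model = WormModel(w_max=2.0, w_min=1.5, length=self.pose.length)
        same = pose_cost(self.pose, model, self.dmap, previous=self.pose)
        far = Pose(self.pose.points + (6, 0), scale=1, offset=self.pose.offset)
        moved = pose_cost(self.pose, model, self.dmap, previous=far)
        assert moved > same


class TestSelectBestCombination:
    def test_single_candidate_returned(self):
        pose = straight_pose(5, range(3, 15))
        model = WormModel(2.0, 1.5, 12)
        dmap = np.ones((20, 20))
        sel, cost = select_best_combination([[pose]], [model], dmap)
        assert sel == [pose]

    def test_worm_without_candidates_is_lost(self):
        pose = straight_pose(5, range(3, 15))
        model = WormModel(2.0, 1.5, 12)
        sel, _ = select_best_combination(
            [[pose], []], [model, model], np.ones((20, 20))
        )
        assert sel[0] == pose and sel[1] is None

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        """Selection equals the minimum over all cross-combinations computed
        independently, for 2 worms x <= 4 candidates."""
        from itertools import product

        rng = np.random.default_rng(seed)
        dmap = distance_map(line_mask(14) | t_mask()) + 1.0
        cands = []
        for _ in range(2):
            k = int(rng.integers(1, 5))
            cands.append(
                [
                    straight_pose(
                        int(rng.integers(2, 12)),
                        range(2, 2 + int(rng.integers(8, 14))),
                        offset=(0, 0),
                    )
                    for _ in range(k)
                ]
            )
        models = [WormModel(2.0, 1.5, 12), WormModel(2.0, 1.5, 10)]
        sel, got_cost = select_best_combination(cands, models, dmap)
        best = min(
            sum(pose_cost(p, m, dmap) for p, m in zip(combo, models))
            for combo in product(*cands)
        )
        assert got_cost == pytest.approx(best)

    def test_coverage_penalty_prefers_spanning_assignments(self):
        """On an X-blob two distinct straight-through paths beat assigning
        both worms the same path: the former covers all four arms."""
        mask = x_mask(6)
        g = build_skeleton_graph(mask)
        poses = enumerate_poses(g, 13, 0.05)
        model = WormModel(w_max=1.0, w_min=1.0, length=13)
        dmap = np.ones(mask.shape)
        sel, _ = select_best_combination(
            [poses, poses], [model, model], dmap, skeleton_mask=mask
        )
        pix0 = set(map(tuple, sel[0].points))
        pix1 = set(map(tuple, sel[1].points))
        assert pix0 | pix1 == set(map(tuple, np.argwhere(mask)))

    def test_tie_break_is_deterministic(self):
        a = straight_pose(5, range(3, 15))
        b = straight_pose(9, range(3, 15))
        model = WormModel(2.0, 1.5, 12)
        dmap = np.full((20, 20), 1.75)
        runs = [
            select_best_combination([[a, b], [a, b]], [model, model], dmap)[0]
            for _ in range(3)
        ]
        assert all(r == runs[0] for r in runs)

    def test_no_candidates_anywhere_rejected(self):
        with pytest.raises(ValueError):
            select_best_combination([[], []], [WormModel(2, 1, 10)] * 2,
                                    np.ones((5, 5)))


# ---------------------------------------------------------------------------
# tracking


class TestTrackSequence:
    def single_worm_masks(self, n=5):
        masks = []
        for t in range(n):
            spec = WormSpec.sinusoidal(
                (14.0 + 2 * t, 8.0), 28, 2.0, 24, 0.4, half_width=1.5
            )
            masks.append(generate_worm(spec, (48, 48))[0])
        return masks

    def test_single_worm_pose_is_classic_skeleton_path(self):
        masks = self.single_worm_masks()
        tracks = track_sequence(masks)
        assert len(tracks) == 1
        tr = tracks[0]
        for t, mask in enumerate(masks):
            pose = tr.pose_at(t)
            assert pose is not None
            assert tr.status[t] == "separate"
            skel = classic_skeleton(crop_blob(mask).mask)
            assert pose.length == int(skel.sum())

    def test_tracking_is_deterministic(self):
        masks, _ = crossing_sequence(2)
        a = track_sequence(masks)
        b = track_sequence(masks)
        for ta, tb in zip(a, b):
            assert ta.poses.keys() == tb.poses.keys()
            for f in ta.poses:
                assert (ta.poses[f].points == tb.poses[f].points).all()

    def test_crossing_preserves_identity(self):
        masks, truths = crossing_sequence(0)
        tracks = track_sequence(masks)
        assert len(tracks) == 2
        from wormskel import iou, reconstruct_body

        shape = masks[0].shape
        for frame in (0, len(masks) - 1):
            for tr in tracks:
                body = reconstruct_body(tr.pose_at(frame), 2, shape)
                scores = [
                    iou(body, reconstruct_body(k, 2, shape))
                    for k in truths[frame]
                ]
                assert int(np.argmax(scores)) == tr.worm_id

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            track_sequence([])
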