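"""Synthetic worm masks, ground-truth skeletons, and plate image sequences.

Adult C. elegans imaged on a backlit 55 mm plate project to roughly 20-40
pixels of body length and 3-5 pixels of body width, as dark (intensity ~0)
shapes on a bright plate region (intensity ~48) surrounded by black. The
generators here emulate exactly that geometry so that every stage of the
pipeline — segmentation, width/length model estimation, the width-aware
skeletonisation and pose tracking — can be exercised against known ground
truth without any recorded data.

A worm is modelled as a tube of constant half-width around a continuous
planar centerline. Rasterisation uses pixel-center semantics: a pixel is
foreground iff its center lies within ``half_width`` of the centerline,
which makes sub-pixel half-widths (e.g. 1.37) meaningful and matches the
distance-transform reading of width used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WormSpec",
    "SceneSpec",
    "generate_worm",
    "generate_parallel_pair",
    "generate_coiled_worm",
    "generate_sequence",
    "render_scene",
    "ground_truth_frame",
    "parallel_pair_scene",
    "crossing_sequence",
]

_CURVE_STEP = 0.25  # centerline sampling step, px
_SKEL_STEP = 0.5  # ground-truth rasterisation step, px


@dataclass(frozen=True)
class WormSpec:
    """A single worm: a continuous centerline plus a tube half-width.

    ``points`` are (row, col) control points of the centerline polyline in
    pixel units. Sinusoidal and straight constructors are provided; any
    polyline is accepted.
    """

    points: tuple[tuple[float, float], ...]
    half_width: float = 1.5
    kind: str = "straight"

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError(f"half_width must be >= 1, got {self.half_width}")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.arc_length < 4 * self.half_width:
            raise ValueError(
                f"centerline arc length {self.arc_length:.1f} < 4 * half_width"
            )

    @property
    def arc_length(self) -> float:
        p = np.asarray(self.points, float)
        return float(np.hypot(*np.diff(p, axis=0).T).sum())

    @classmethod
    def straight(
        cls,
        start: tuple[float, float],
        end: tuple[float, float],
        half_width: float = 1.5,
    ) -> "WormSpec":
        return cls(points=(tuple(start), tuple(end)), half_width=half_width,
                   kind="straight")

    @classmethod
    def sinusoidal(
        cls,
        start: tuple[float, float],
        length: float,
        amplitude: float,
        wavelength: float,
        phase: float = 0.0,
        half_width: float = 1.5,
        angle: float = 0.0,
        n_points: int = 120,
    ) -> "WormSpec":
        """Sinusoidal centerline of given along-axis ``length`` starting at
        ``start``, undulating with ``amplitude``/``wavelength``/``phase``,
        with the travel axis rotated by ``angle`` radians from the +col
        direction."""
        t = np.linspace(0.0, length, n_points)
        off = amplitude * np.sin(2 * np.pi * t / wavelength + phase)
        ca, sa = np.cos(angle), np.sin(angle)
        rows = start[0] + t * sa + off * ca
        cols = start[1] + t * ca - off * sa
        pts = tuple((float(r), float(c)) for r, c in zip(rows, cols))
        return cls(points=pts, half_width=half_width, kind="sinusoidal")

    def sampled(self, step: float = _CURVE_STEP) -> np.ndarray:
        """Densely resampled centerline, (N, 2) float array of (row, col)."""
        p = np.asarray(self.points, float)
        seg = np.hypot(*np.diff(p, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(np.ceil(s[-1] / step)) + 1, 2)
        si = np.linspace(0.0, s[-1], n)
        rows = np.interp(si, s, p[:, 0])
        cols = np.interp(si, s, p[:, 1])
        return np.stack([rows, cols], axis=1)

    def translated(self, dr: float, dc: float) -> "WormSpec":
        pts = tuple((r + dr, c + dc) for r, c in self.points)
        return WormSpec(points=pts, half_width=self.half_width, kind=self.kind)


def _curve_distance(curve: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Distance from every pixel center to a densely sampled curve.

    Brute force over sample points; canvases here are small, and this is
    deliberately the simplest possible rasterisation oracle.
    """
    rr = np.arange(shape[0], dtype=float)
    cc = np.arange(shape[1], dtype=float)
    # chunk over curve samples to bound memory
    d2 = np.full(shape, np.inf)
    for i in range(0, len(curve), 256):
        chunk = curve[i : i + 256]
        dr = rr[:, None, None] - chunk[None, None, :, 0]
        dc = cc[None, :, None] - chunk[None, None, :, 1]
        d2 = np.minimum(d2, (dr * dr + dc * dc).min(axis=2))
    return np.sqrt(d2)


def _rasterise_skeleton(curve: np.ndarray) -> np.ndarray:
    """8-connected, 1-px-wide rasterisation of a continuous curve.

    The curve is walked at sub-pixel steps; consecutive duplicates are
    dropped, so successive emitted pixels differ by at most one in each
    coordinate (8-adjacency).
    """
    px = np.rint(curve).astype(int)
    keep = np.ones(len(px), bool)
    keep[1:] = np.any(px[1:] != px[:-1], axis=1)
    px = px[keep]
    # drop staircase corners: a pixel whose two chain neighbours are already
    # 8-adjacent to each other adds nothing
    chain = list(map(tuple, px))
    i = 1
    while i < len(chain) - 1:
        if max(abs(chain[i - 1][0] - chain[i + 1][0]),
               abs(chain[i - 1][1] - chain[i + 1][1])) <= 1:
            del chain[i]
        else:
            i += 1
    return np.asarray(chain)


def _check_inside(curve: np.ndarray, half_width: float,
                  shape: tuple[int, int]) -> None:
    lo = curve.min(axis=0) - half_width
    hi = curve.max(axis=0) + half_width
    if (lo < -0.5).any() or hi[0] > shape[0] - 0.5 or hi[1] > shape[1] - 0.5:
        raise ValueError(
            f"worm (extent {lo}..{hi}) does not fit canvas {shape}"
        )


def generate_worm(
    spec: WormSpec, canvas: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Render one worm.

    Returns ``(mask, skeleton)`` where ``mask`` is a boolean canvas-shaped
    array (pixel centers within ``half_width`` of the centerline) and
    ``skeleton`` is the (N, 2) integer pixel list of the rasterised true
    centerline, ordered head to tail.
    """
    curve = spec.sampled()
    _check_inside(curve, spec.half_width, canvas)
    mask = _curve_distance(curve, canvas) <= spec.half_width
    skel = _rasterise_skeleton(spec.sampled(_SKEL_STEP))
    return mask, skel


def generate_parallel_pair(
    gap: float,
    spec: WormSpec,
    canvas: tuple[int, int],
    stagger: float = 0.0,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Two congruent worms travelling in parallel.

    The two centerlines are the given spec offset perpendicular to its mean
    direction by ``+-(half_width + gap/2)``, so the centerline separation is
    ``2*half_width + gap`` and the continuous tube boundaries are ``gap``
    apart. ``stagger`` slides the second worm along the travel direction.
    For ``gap <= 1`` the rasterised union forms a single connected blob
    (the generator centres the pair on a half-pixel boundary to guarantee
    contact at sub-pixel gaps).

    Returns ``(union mask, [skeleton1, skeleton2], labels)`` where
    ``labels`` is an int array with 0 background, 1 and 2 the two worms
    (worm 1 wins ties on shared pixels).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    curve = spec.sampled()
    d = curve[-1] - curve[0]
    d = d / np.hypot(*d)
    nrm = np.array([-d[1], d[0]])
    sep = 2 * spec.half_width + gap

    # Snap the pair midline to a half-pixel position along the normal so
    # that tube contact survives pixel-center rasterisation.
    mid = curve.mean(axis=0)
    proj = float(mid @ nrm)
    shift = (np.floor(proj) + 0.5 - proj) * nrm

    s1 = spec.translated(*(+nrm * sep / 2 + shift))
    s2 = spec.translated(*(-nrm * sep / 2 + shift + d * stagger))
    m1, k1 = generate_worm(s1, canvas)
    m2, k2 = generate_worm(s2, canvas)
    labels = np.zeros(canvas, np.int32)
    labels[m2] = 2
    labels[m1] = 1
    return m1 | m2, [k1, k2], labels


def generate_coiled_worm(
    inner_radius: float,
    half_width: float,
    arc_fraction: float,
    canvas: tuple[int, int],
    center: tuple[float, float] | None = None,
    phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Annular-arc worm around a circular centerline.

    ``arc_fraction`` = 1 yields a fully closed ring whose skeleton has no
    endpoints — the fully rolled posture.
    """
    if not 0 < arc_fraction <= 1:
        raise ValueError("arc_fraction must be in (0, 1]")
    if half_width >= inner_radius - 1:
        raise ValueError("annulus degenerate: half_width >= inner_radius - 1")
    if center is None:
        center = ((canvas[0] - 1) / 2, (canvas[1] - 1) / 2)
    n = max(int(np.ceil(2 * np.pi * inner_radius * arc_fraction / _CURVE_STEP)), 8)
    th = phase + np.linspace(0.0, 2 * np.pi * arc_fraction, n)
    curve = np.stack(
        [center[0] + inner_radius * np.sin(th),
         center[1] + inner_radius * np.cos(th)], axis=1
    )
    _check_inside(curve, half_width, canvas)
    mask = _curve_distance(curve, canvas) <= half_width
    ns = max(int(np.ceil(2 * np.pi * inner_radius * arc_fraction / _SKEL_STEP)), 8)
    ths = phase + np.linspace(0.0, 2 * np.pi * arc_fraction, ns)
    sk_curve = np.stack(
        [center[0] + inner_radius * np.sin(ths),
         center[1] + inner_radius * np.cos(ths)], axis=1
    )
    skel = _rasterise_skeleton(sk_curve)
    if arc_fraction == 1 and np.all(skel[0] == skel[-1]) and len(skel) > 1:
        skel = skel[:-1]  # closed loop: do not repeat the seam pixel
    return mask, skel


@dataclass(frozen=True)
class SceneSpec:
    """A plate scene: worms plus speck noise on a bright circular plate."""

    canvas: tuple[int, int]
    worms: tuple[WormSpec, ...]
    noise_specks: tuple[tuple[tuple[float, float], float], ...] = ()
    background_level: int = 48
    worm_level: int = 0
    plate_margin: float = 2.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "canvas": list(self.canvas),
                "worms": [
                    {"points": [list(p) for p in w.points],
                     "half_width": w.half_width, "kind": w.kind}
                    for w in self.worms
                ],
                "noise_specks": [
                    {"center": list(c), "radius": r} for c, r in self.noise_specks
                ],
                "background_level": self.background_level,
                "worm_level": self.worm_level,
                "plate_margin": self.plate_margin,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        d = json.loads(text)
        worms = tuple(
            WormSpec(points=tuple(tuple(p) for p in w["points"]),
                     half_width=w["half_width"], kind=w.get("kind", "straight"))
            for w in d["worms"]
        )
        specks = tuple(
            (tuple(s["center"]), s["radius"]) for s in d.get("noise_specks", ())
        )
        return cls(
            canvas=tuple(d["canvas"]), worms=worms, noise_specks=specks,
            background_level=d.get("background_level", 48),
            worm_level=d.get("worm_level", 0),
            plate_margin=d.get("plate_margin", 2.0),
            seed=d.get("seed", 0),
        )


def _plate_mask(scene: SceneSpec) -> np.ndarray:
    h, w = scene.canvas
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    radius = min(h, w) / 2 - scene.plate_margin
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2


def render_scene(
    scene: SceneSpec, worms: Sequence[WormSpec] | None = None
) -> np.ndarray:
    """Render a single 8-bit frame: bright plate disk on black surround,
    worms and noise specks at ``worm_level``."""
    frame = np.zeros(scene.canvas, np.uint8)
    plate = _plate_mask(scene)
    frame[plate] = scene.background_level
    for w in worms if worms is not None else scene.worms:
        mask, _ = generate_worm(w, scene.canvas)
        frame[mask & plate] = scene.worm_level
    for center, radius in scene.noise_specks:
        rr, cc = np.mgrid[0 : scene.canvas[0], 0 : scene.canvas[1]]
        speck = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
        frame[speck & plate] = scene.worm_level
    return frame


def ground_truth_frame(
    worms: Sequence[WormSpec], canvas: tuple[int, int]
) -> list[np.ndarray]:
    """Ground-truth skeleton pixel lists for each worm of a frame."""
    return [generate_worm(w, canvas)[1] for w in worms]


def generate_sequence(
    scene: SceneSpec,
    n_frames: int = 30,
    motion: Sequence[Sequence[tuple[float, float]]] | None = None,
) -> tuple[np.ndarray, list[list[np.ndarray]]]:
    """Render a frame stack with per-worm displacement schedules.

    ``motion[w][t]`` is the (drow, dcol) displacement of worm ``w`` at frame
    ``t`` relative to its scene position; ``None`` renders a static scene.
    Output is fully determined by the scene spec and schedule.

    Returns ``(frames, truths)`` with ``frames`` a (T, H, W) uint8 stack and
    ``truths[t]`` the list of ground-truth skeletons (one per worm).
    """
    frames = []
    truths: list[list[np.ndarray]] = []
    for t in range(n_frames):
        worms = []
        for w_i, w in enumerate(scene.worms):
            if motion is None:
                worms.append(w)
            else:
                dr, dc = motion[w_i][t]
                worms.append(w.translated(dr, dc))
        frames.append(render_scene(scene, worms))
        truths.append(ground_truth_frame(worms, scene.canvas))
    return np.stack(frames), truths


# ---------------------------------------------------------------------------
# canonical study scenes


def parallel_pair_scene(
    seed: int, canvas: tuple[int, int] = (56, 64)
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, WormSpec]:
    """A seeded merged parallel-travel scene: two congruent straight worms
    in side-by-side contact, the configuration where classic thinning
    returns one shared skeleton for both bodies.

    Worm length, half-width, contact gap, longitudinal stagger, position
    jitter, and travel axis (image row or column direction) vary with the
    seed; the pair travels along an image axis, as in a parallel-travel
    crop. Returns ``(mask, [skeleton1, skeleton2], labels, spec)``.
    """
    rng = np.random.default_rng(seed)
    length = float(rng.uniform(28, 38))
    half_width = float(rng.choice([1.25, 1.5, 1.75]))
    gap = float(rng.uniform(0.0, 1.0))
    stagger = float(rng.uniform(0.0, 6.0))
    vertical = bool(rng.integers(2))
    r0 = canvas[0] / 2 + float(rng.uniform(-3, 3))
    c0 = (canvas[1] - length - stagger) / 2 + float(rng.uniform(-2, 2))
    if vertical:
        spec = WormSpec.straight((c0, r0), (c0 + length, r0), half_width)
        cv = (canvas[1], canvas[0])
        mask, skels, labels = generate_parallel_pair(gap, spec, cv, stagger)
        return mask.T, [k[:, ::-1] for k in skels], labels.T, spec
    spec = WormSpec.straight((r0, c0), (r0, c0 + length), half_width)
    mask, skels, labels = generate_parallel_pair(gap, spec, canvas, stagger)
    return mask, skels, labels, spec


def crossing_sequence(
    seed: int,
    n_frames: int = 16,
    canvas: tuple[int, int] = (64, 56),
    step: float = 3.0,
) -> tuple[list[np.ndarray], list[list[np.ndarray]]]:
    """A seeded two-worm crossing: a horizontal worm sweeps down across a
    stationary vertical worm, merging into a single blob mid-sequence and
    separating again, with sinusoidal body shapes varying by seed.

    Returns ``(masks, truths)``: per-frame binary masks of the pair and the
    two ground-truth skeletons (index 0 = moving worm, 1 = stationary).
    """
    rng = np.random.default_rng(seed)
    amp = float(rng.uniform(1.0, 2.5))
    wav = float(rng.uniform(20, 35))
    phase = float(rng.uniform(0, 2 * np.pi))
    row0 = 10.0 + float(rng.uniform(-2, 2))
    col_b = canvas[1] / 2 + float(rng.uniform(-3, 3))
    masks, truths = [], []
    for t in range(n_frames):
        mover = WormSpec.sinusoidal(
            (row0 + step * t, 10.0), 30, amp, wav, phase, half_width=1.5
        )
        stayer = WormSpec.sinusoidal(
            (24.0, col_b), 22, amp, wav, phase + 1, half_width=1.5,
            angle=np.pi / 2,
        )
        ma, ka = generate_worm(mover, canvas)
        mb, kb = generate_worm(stayer, canvas)
        masks.append(ma | mb)
        truths.append([ka, kb])
    return masks, truths
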