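# wormskel

Width-aware skeletonisation and pose tracking for *C. elegans* plate
imaging.

## The problem

Lifespan and healthspan assays monitor tens of worms per Petri plate with a
camera at ~1 Hz. Each worm's *pose* — the ordered pixel path along its body
centerline — is recovered by thinning its segmented silhouette to a 1-px
skeleton. Classic thinning fails exactly where tracking is hardest: when two
worms travel in contact, cross, or a single worm coils onto itself, the
merged blob thins to one shared skeleton and identities are lost.

`wormskel` implements a distance-transform remedy. Each worm's width is
known from frames where it crawls alone, summarised in a per-worm model
(w_max, w_min, L): the maximum and minimum Euclidean distance-map values
along its skeleton (half-widths, in pixels) and its skeleton pixel count.
Inside a merged blob, any pixel whose distance to the background exceeds
the expected half-width cannot belong to a single body. The **background
transform** flips those pixels to background, iterating until no pixel
transforms:

    d(p) = min distance from p to a background pixel
    remove every foreground p with d(p) > w_thr,   w_thr = w_max (contact)
                                                         = w_min (coiled)

applied in a ×3-upscaled crop so the carved line is several pixels wide and
8-connected thinning cannot leak across it diagonally. Thinning the carved
blob turns the shared skeleton into a loop whose opposite arcs follow the
two bodies (or the turns of a coil). Candidate poses are enumerated as
simple paths between skeleton endpoints and junctions (or walks around
cycles), constrained to the expected length, de-duplicated at 90% body
overlap, and scored by

    cost = |len − L|/L + |w̄ − (w_max+w_min)/2|/w_max + (1 − IoU(body, previous body))

with the minimum-cost combination over all worms (plus a penalty for
uncovered skeleton) giving each worm's pose. When no pixel exceeds the
threshold — the common, isolated-worm case — the method returns exactly the
classic skeleton.

Validation uses bodies reconstructed from skeletons by disk dilation
(radius ≈ half the body width, giving 3- or 5-px-wide bodies) and two
Jaccard indices: **index 1**, IoU of a predicted body against the
ground-truth body (higher is better), and **index 2**, IoU between the two
predicted bodies of worms in contact (lower is better).

Everything is testable without recorded data: `wormskel.fixtures` generates
worm masks, merged pairs, coils, and whole plate sequences with exact
ground-truth centerlines at the scale the pipeline assumes (worms 20–40 px
long and 3–5 px wide, dark bodies near grey level 0 on a backlit plate near
level 48).

## Worked example

```python
import numpy as np
import wormskel as ws

# estimate a worm model from a frame where the worm crawls alone
spec = ws.WormSpec.sinusoidal((20.0, 8.0), 32, 2.0, 26, 0.5, half_width=1.5)
mask_iso, _ = ws.generate_worm(spec, (48, 48))
model = ws.estimate_worm_model(ws.crop_blob(mask_iso))

print(f"model: w_max={model.w_max:.2f} w_min={model.w_min:.2f} "
      f"length={model.length}")

# a merged parallel pair, and the width-aware skeleton of its blob
mask, skels, labels, pair_spec = ws.parallel_pair_scene(0)
blob = ws.crop_blob(mask)
comps, res = ws.improved_skeleton(blob, model, mode="aggregated", scale=3)
print(f"background transform removed {res.removed_total} scaled px "
      f"in {res.iterations} iteration(s)")
union = np.logical_or.reduce([c.mask for c in comps])
graph = ws.build_skeleton_graph(ws.SkeletonMask(union, 3))
print(f"skeleton graph: {len(graph.endpoints)} endpoints, "
      f"{len(graph.junctions)} junctions, {len(graph.branches)} branches")
```

prints:

    model: w_max=2.00 w_min=1.41 length=33
    background transform removed 576 scaled px in 1 iteration(s)
    skeleton graph: 3 endpoints, 3 junctions, 6 branches

The model says this worm is at most 2.00 × 2 px wide and 33 skeleton pixels
long. On the merged pair, 576 scaled pixels sat deeper than the 3 × 2.00
threshold — the contact seam — and were carved out, turning the single
merged line into a loop (junctions where the carve ends). Selecting one
pose per worm from that graph and comparing both backends at dilation
radius 2:

    proposed : index1 = 0.974, 0.632; index2 = 0.190
    classic  : index1 = 0.559, 0.629; index2 = 0.890

Under the classic skeleton both worms receive nearly the same line
(index 2 = 0.89, heavily overlapping bodies); under the width-aware
skeleton the two selected poses take opposite arcs of the carved loop
(index 2 = 0.19) and the first worm's pose tracks its true centerline far
more closely (0.97 vs 0.56).

The same machinery runs from the shell:

```sh
wormskel synth --scene scene.json --frames 30 --out frames/
wormskel run --frames frames/ --out results/
```

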