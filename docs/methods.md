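# Methods

This note documents the model behind `wormskel`, its tunable parameters,
what the synthetic generators do and do not emulate, the numerical choices
made where the design was open, and known limitations.

## The worm model and its estimation

A worm is summarised by three numbers estimated from a frame where it
crawls alone and un-occluded:

- `w_max`, `w_min` — the largest and smallest value of the exact Euclidean
  distance transform (`scipy.ndimage.distance_transform_edt`) sampled along
  the worm's classic skeleton. These are *half*-widths in pixels; a
  displayed body width is twice the stored value. Skeleton endpoints are
  included when taking the minimum, since the narrowest point of a worm
  silhouette is a body end.
- `length` — the skeleton pixel count.

For a tube of continuous half-width *r* rasterised by pixel centers, the
ridge of the distance map sits near *r* + 0.5 (the half-pixel comes from
measuring to the centers of the first background pixels); model-recovery
tests therefore check `w_max` against *r* + 0.5, within ±0.6 px. When a
worm appears isolated in several frames, the frame maximising skeleton
length (most extended posture) is used: curled postures under-estimate
length.

Pixel count systematically under-counts continuous arc length on oblique
bodies (a diagonal step covers √2 but counts 1; ≈ −11% for a circle).
`length` keeps the pixel-count convention because all length comparisons
in the pipeline are between pixel counts; `Pose.arc_length` exposes the
geometric sum-of-steps length for comparisons against continuous curves.

## The background transform

Given a blob crop and a width threshold `w_thr`, iterate: compute the
distance map; flip to background every foreground pixel with
`d > w_thr` (strictly — pixels exactly at the threshold survive); stop when
an iteration removes nothing. Multi-worm blobs use `w_thr = w_max`
(aggregated mode); single coiled worms use `w_thr = w_min` (rolled mode),
since a fold of a single body is narrower than a two-body contact. The
transform runs in a ×3 nearest-neighbour upscaled crop with the threshold
scaled accordingly, so the carved background line is at least ~3 scaled
pixels wide and 8-connected thinning cannot connect skeleton pixels
diagonally across it; with the adult maximum-width model the line is ~9
scaled pixels wide. Skeleton coordinates are mapped back to original-frame
units as `(scaled − (s−1)/2)/s`, sub-pixel precision that loses nothing at
the original resolution.

Two properties follow directly from the construction and are asserted in
the test suite:

- **Equivalence.** If no distance value exceeds the threshold, nothing is
  removed and the output *is* the classic skeleton of the scaled blob.
  This is the common case: an isolated worm's distances never exceed its
  own `w_max` (plus rasterisation slack), so the method degrades to the
  classic one exactly when the classic one suffices.
- **Monotone fixpoint.** The mask only shrinks, and re-running the
  transform on its own output removes nothing. With a constant threshold
  the loop converges after the first removal round — removal only grows
  the background, so recomputed distances only shrink — but the loop form
  is kept because the stopping rule is "no pixel transforms" and it
  tolerates per-round threshold schedules.

**What the carve can and cannot do.** Only pixels with `d > w_thr` are ever
removed, so every pixel within `w_thr` of visible background survives —
including a connected shell along the entire blob boundary. A carved
region is therefore always an interior hole: the transform *cannot*
disconnect a blob into separate components. What it does instead is
equally useful: on a two-worm contact the carved seam turns the single
merged skeleton line into a loop whose opposite arcs follow the two
bodies. Separation is then delivered at the *pose* level — the path
enumerator offers one arc per worm, and the selected poses overlap an
order of magnitude less than under the classic skeleton (mean index 2
≈ 0.1 vs ≈ 0.8 on merged-pair scenes). Component counting alone
understates what the transform achieves; body-overlap indices measure it.

**Border convention.** Distances are measured to background pixels visible
inside the working crop. The default (`border="array"`) uses the crop as
given — blob crops carry a 1-px background margin, making "distance to the
closest background pixel" well defined everywhere. `border="extend"`
restricts the window to the blob's tight bounding box, the convention of a
pipeline that passes around bare bounding-box subimages; it inflates
distances wherever the blob spans its crop, degenerates when no background
is visible inside the box at all (that case raises the width-mismatch
error), and is provided for comparison only.

## Rolled worms

A coiled body is recognised during tracking by its classic skeleton
closing into a cycle or falling well below the model length (factor 0.7,
configurable). Rolled-mode skeletonisation carves with `w_min` and then
fills skeleton holes of fewer than 4 pixels (4-connected enclosed
background components, counted at the working scale) before re-thinning:
tiny loops left by an imperfectly carved line would otherwise multiply
near-identical candidate poses. Holes of 4 px or more — the open centre of
a genuine coil — are kept. Hole filling applies only in rolled mode; in
aggregated mode the wider maximum-width line serves the same purpose.

## Pose enumeration, filtering, scoring

The skeleton is organised into a graph: endpoints (1 neighbour), junctions
(≥ 3), branches (pixel runs between them), and isolated cycles. Adjacency
prunes diagonal shortcuts (a diagonal link whose two pixels share an
orthogonal skeleton neighbour), so chains are minimal and junction degrees
meaningful.

- **Open poses**: all simple node-to-node paths whose pixel count is within
  a tolerance fraction (default 0.25) of the expected length; paths may
  share branches, no pixel repeats within one path, reversal duplicates
  are merged. The DFS prunes on the upper length bound and caps output at
  500 candidates.
- **Cyclic poses**: for endpoint-free components, open walks of the
  expected length around the cycle, started every 2 pixels — or, when the
  worm has a previous pose, from the skeleton pixels overlapping it.
- **Similarity filter**: greedy, longest first; a candidate is dropped
  when its disk-dilated body overlaps a retained one with IoU ≥ 0.90.
  Bodies, not raw 1-px paths, are compared, so near-parallel centerlines
  register as overlapping. At most 50 candidates per worm survive.
- **Cost**: `|len − L|/L + |w̄ − (w_max+w_min)/2|/w_max + (1 − IoU(body,
  previous body))`, equal weights by default, the width measured on the
  distance map of the *uncarved* scaled blob so poses along real bodies
  score well. The three criteria — length, width, history — are combined
  in the simplest convex form; weights are configurable.
- **Selection**: exhaustive scoring of all cross-combinations (capped at
  10,000 with a warning), plus a coverage penalty proportional to the
  fraction of skeleton pixels no assigned pose covers — this is what makes
  two worms take *different* arcs. Ties break toward larger covered
  length, then lexicographic pixel order, so selection is deterministic.

## Tracking

The tracker finds a reference frame where every worm is separate and
simple (one open skeleton path per blob), estimates models there, and
propagates identities forward and backward. Per frame, each worm is
assigned to the blob best overlapping its previous dilated body (nearest
blob when nothing overlaps); single-worm blobs use the classic skeleton
directly unless coiling is suspected; multi-worm blobs go through
aggregated-mode skeletonisation and combination selection with the
previous-pose term. Worms without candidates are flagged lost for that
frame. When no separate frame exists, a configured default model is used —
synchronised cultures make one default per plate reasonable.

## Segmentation front end

Backlit plates give near-binary images: plate ≈ 48, worms ≈ 0, surround
black, so thresholds are fixed: ROI = pixels > 35 in *every* frame of the
sequence, closed (3×3, one iteration) and reduced to the largest
8-connected component; worms = pixels < 24 inside the ROI. Because a worm
darkens every pixel it ever occupies, the AND-composed ROI carries a hole
along each worm's trail; the pipeline fills enclosed ROI holes before worm
segmentation. Track-vs-noise classification tries the threshold levels
{8, 16, 24, 32} on the temporal union of worm masks and keeps regions
whose skeleton reaches a minimum length (default: half the configured worm
length); everything else is noise. Foreground uses 8-connectivity,
background and holes 4-connectivity, throughout.

## Validation indices

Bodies are reconstructed from skeletons or poses by dilation with a
discrete disk (pixel in the element iff its center is within the radius),
radius = `round(w_min)` clipped to {1, 2} — radius 1 and 2 give 3- and
5-px-wide bodies. Poses in sub-pixel units are rounded to whole pixels
first; IoU is a pixel-set measure. IoU of two empty masks is defined as 0,
so an empty prediction scores worst and cannot poison a mean. Index 1 =
IoU(prediction, reference), higher is better; index 2 = IoU(prediction of
worm 1, prediction of worm 2), lower is better. `compare_methods` runs
both skeleton backends over a labelled dataset and emits per-case
mean/SD/improvement rows plus the per-pose table for downstream
statistics.

## Synthetic data

Generators model worms as constant-half-width tubes around continuous
centerlines (straight, sinusoidal, circular-arc), rasterised by the
pixel-center rule, rendered at intensity 0 on a 48-level plate disk on
black. They reproduce the geometry and contrast structure the method
assumes — sizes of 20–40 × 3–5 px, near-binary contrast, merged parallel
pairs, crossings, closed coils, speck noise — with exact ground-truth
centerlines. They do **not** emulate tapered body ends, intensity
gradients or blur (an optional Gaussian-blur switch exists but is off:
backlighting makes real frames nearly binary), agar texture,
eggs/condensation artefacts, or realistic locomotion dynamics (motion
schedules are kinematic translations). Passing tests therefore demonstrate
the algorithmic properties — equivalence, carving, pose separation,
identity preservation — under the stated geometry, not robustness to
photometric variation.

Canonical study scenes: `parallel_pair_scene` builds solidly merged
side-by-side straight pairs (seeded length 28–38 px, half-width 1.25–1.75,
boundary gap 0–1 px, stagger 0–6 px, horizontal or vertical travel axis);
the pair midline snaps to a half-pixel position because sub-pixel-gap
contact survives rasterisation only for favourable placements.
`crossing_sequence` sweeps a sinusoidal worm across a stationary one
(16 frames, 3 px/frame), merging mid-sequence and separating again.
Axis-aligned pair travel is a deliberate simplification; the method itself
is orientation-agnostic under the default border convention.

## Numerical choices and degenerate inputs

- Strict inequality for removal (`d > w_thr`).
- Working scale 3; scale 1 disables scaling entirely.
- Empty masks: classic skeleton of nothing is nothing; the background
  transform of an empty mask performs 0 iterations; a blob that vanishes
  under the transform (possible only in the degenerate tight-box case)
  raises a width-model-mismatch error rather than returning an empty
  skeleton.
- Blob crops carry a 1-px background margin; bounding boxes are recorded
  in full-frame coordinates; all files state the 0-based (row, col),
  origin-top-left convention in a header comment.
- Candidate caps (50 per worm, 10,000 combinations, 500 raw enumeration)
  bound worst-case blow-up on pathological skeletons; hitting a cap warns.
- Problem sizes in the test and acceptance suites — canvases ≤ 64 px,
  sequences ≤ 16 frames, 20-scene batches — are chosen as the smallest
  sizes at which every property is meaningfully exercised at the imaging
  scale the pipeline targets.

## Known limitations

- The background transform cannot split a blob into separate connected
  components (see above); claims of separation are pose-level, and
  evaluation should use the overlap indices, not component counts.
- More than ~3 worms in one blob multiplies candidate combinations
  quickly; the caps keep it tractable at the cost of exhaustiveness
  beyond them.
- No head/tail discrimination: a pose and its reversal are the same pose.
- Width models assume synchronised cultures; mixed-size populations would
  need per-worm thresholds from per-worm isolated frames (supported) and
  suffer when a worm is never isolated.
- Fixed thresholds presume controlled backlighting; frames from other
  rigs need recalibrated ROI/worm thresholds.
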