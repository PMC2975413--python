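# Methods

This note documents the models and numerical choices behind
`starchseg`, in the order the pipeline runs.

## Imaging model and assumptions

The pipeline assumes transmitted-light (bright-field) micrographs of
stained starch granules: dark, compact, round-to-mildly-elliptical
objects on a brighter, fairly uniform background, giving a bimodal
intensity histogram. Granules may touch or overlap; each granule is
solid (no holes). Input images are normalised to a 0–255 intensity
scale at load time (16-bit rescaled, RGB converted with ITU-R 601 luma
weights). Everything downstream is deterministic: identical input and
configuration reproduce identical output bit for bit.

## Thresholding

The iterative class-mean-midpoint scheme: starting from T₀ = image mean
(configurable), split pixels at T, compute class means μ₁ (pixels < T)
and μ₂ (pixels ≥ T), set T ← (μ₁+μ₂)/2, repeat until |ΔT| < ε.

* `threshold.eps` — stopping tolerance, intensity units. Default 0.2.
* Tie rule: a pixel exactly at T goes to the background class, so the
  two classes always partition the image.
* An empty class keeps its mean at the current T, which keeps the
  update defined on degenerate histograms; a constant image is reported
  as degenerate and yields an empty foreground with a warning.
* The scheme is global — one T per image. For the strongly bimodal
  histograms this pipeline targets, the fixed point lies between the
  modes; the suite checks it lands in the support gap whenever the two
  modes are disjoint.

## Chamfer distance

Two-pass (forward/backward raster) chamfer transform with the classical
integer weights (3, 4), divided by 3 so one orthogonal step costs 1.0.
Worst-case deviation from true Euclidean distance for (3,4)/3 is about
6% in the continuum; the suite bounds the observed error at 10% against
an exact nearest-background search. Pixels outside the image are
treated as background (a ring of zeros just outside the border), so
granules cut by the image edge get bounded ridges; consequently
distance 0 occurs exactly on background pixels, and a border foreground
pixel is at distance 1.

## Watershed

Meyer's priority-flood watershed (scikit-image implementation) on the
negated distance map, restricted to the foreground, seeded with one
marker per regional-maximum plateau (connected plateau components of
the distance map). 8-connectivity throughout, matching the diagonal
chamfer step. No pre-smoothing and no h-maxima suppression: the method
deliberately accepts oversegmentation here and repairs it downstream —
suppression heuristics would change what the later stages see.

## Region measurement and roundness

Per segment: area, centroid, intensity mean/variance (population),
equivalent diameter 2√(S/π), and perimeter by Moore boundary tracing of
the outer boundary (holes ignored; a single pixel falls back to its
unit-square boundary, 4).

Chain-code steps are weighted with the Vossepoel–Smeulders calibration
(0.980 orthogonal, 1.406 diagonal) rather than the naive 1/√2. The
naive weights overestimate smooth contours by ~5.5%, which drags a
digital disk's roundness down to ≈0.90 — exactly where the flagging
threshold's safety margin matters. With the calibrated weights a
digital disk of radius 15–60 measures R = 4πS/L² in roughly
[0.92, 1.00] (verified in the suite for integer and sub-pixel centres),
so the default threshold keeps its intended meaning: genuine granules
sit well above it, fragments well below.

* `roundness.threshold` — default 0.70; sensible range 0.70–0.75.
  Segments below it are flagged as oversegments outright.
* `min_area` — default 9 px. Sub-resolution slivers are flagged
  directly; they cannot host a meaningful critical point.
* A half-disk scores ≈0.746 — *above* the threshold — which is why
  roundness alone cannot identify all fragments and a second test is
  needed.

## Gradient vector flow and critical points

The GVF field (u, v) minimises

    E = ∬ μ(|∇u|² + |∇v|²) + |∇f|² ((u−f_x)² + (v−f_y)²) dx dy

where f is an edge map: the gradient magnitude of the Gaussian-smoothed
image (σ = `gvf.sigma`, default 1.5), normalised to [0,1], with
responses below `noise_floor` (default 0.1 of the maximum) zeroed.
The noise gate matters: residual camera noise otherwise anchors the
field inside granules, where the model expects the smooth extension of
the boundary data, and scrambles directions near stagnation points.

The minimiser satisfies the linear Euler–Lagrange system
μ∇²u = |∇f|²(u − f_x) (and the v analogue). Two solvers are provided:

* **direct** (default): the system is solved exactly as a sparse linear
  problem (5-point Laplacian, reflecting boundaries; one factorisation
  serves both components). This is the field the time-marching scheme
  converges to. It is the default because explicit diffusion with a
  stable step transports boundary information only ~√(n·μ·Δt) pixels:
  filling a granule of radius 30 would need tens of thousands of
  iterations.
* **iterative**: the classical explicit descent from (u,v) = ∇f with
  Δt = 1/(4μ + max|∇f|²), which keeps both the diffusion and reaction
  terms stable; the discretised energy (forward differences, so that
  its gradient is exactly the applied Laplacian) is non-increasing, and
  the suite asserts this. `gvf.mu` (0.1), `gvf.max_iter` (500) and
  `gvf.tol` (1e-3, largest per-pixel update) apply to this solver.

Inside a granule the converged field points outward toward the boundary
and vanishes at one interior stagnation point; a watershed fragment that
does not contain such a point is not a whole granule. The detector
scans a segment's own pixels within max(3, 0.5·equivalent radius) of
its centroid. A candidate qualifies when

1. its field magnitude lies within one pixel of an 8-neighbourhood
   local minimum (the sub-pixel stagnation point can discretise onto
   different pixels for the magnitude minimum and the direction
   pattern), and
2. for at least `critical.min_directions` (default 7, i.e. more than 6)
   of the 8 compass directions, the cosine similarity between the field
   sampled in that direction and the outward unit vector exceeds
   `critical.sim_threshold` (default 0.90). Similarities are clamped to
   [0, 1]: anti-parallel counts as 0, and a zero vector has similarity 0.

The 8 directions are sampled on a 2-px ring (`NEIGHBOR_STEP`), not at
the immediate neighbours: a half-pixel offset of the true stagnation
point tilts a 1-px sample by up to ~27°, past the 0.90 gate, while at
2 px the worst case is ~14°. Ties between candidates go to the higher
direction count, then the smaller magnitude, then raster order.

Segments that pass roundness *and* contain a critical point are **core
segments** (granules); everything else is an oversegment. A fragment
covering more than half of a granule can pass both tests and be
accepted as core — this residual failure mode is inherent to the
two-criterion rule.

## Merging

Merging is confined to an ROI: one 8-connected foreground blob and the
watershed segments inside it. Each member segment contributes the
feature vector

    (w₁·mean intensity, w₂·intensity variance, w₃·‖centroid − ROI centre‖)

with default weights (0.25, 0.25, 1.0) — the distance dominates because
only nearby segments should merge. Weights scale the coordinates, so
plain Euclidean distance in feature space realises the weighted metric.
The scalar centre distance cannot tell two cores at equal distance on
opposite sides of the ROI centre apart; `fcm.use_centroid_coords`
switches to the two centroid offsets instead. The features are
deliberately left in their raw units (intensity, intensity², pixels)
with the stated weights; the adjacency repair below absorbs most of the
sensitivity to this choice.

Fuzzy c-means (fuzzifier m = 2, tol 1e-4, ≤100 iterations) runs with
c = number of core segments, centres initialised at the core features;
cluster identity is tracked from initialisation. Each oversegment
adopts the label of the core whose cluster gives it maximal membership,
subject to an adjacency repair: if that core's territory (core plus
already-merged members) does not touch the oversegment, the adjacent
core with the next-highest membership is used. A datum coinciding with
a centre gets crisp membership there; memberships always row-normalise
to 1 and the objective is non-increasing (both asserted in the suite).
A blob containing oversegments but no core is left unmerged with a
warning — there is no principled parent to give its fragments to.
Merging never changes the foreground support, and in every blob with a
core the final granule count equals the core count.

## Synthetic scenes

The generator emulates the target imagery: n dark granules (disks, or
ellipses up to a given axis ratio, equal-area radius drawn from
`radius_range`) placed by rejection sampling so that centre distances
stay ≥ (1 − overlap_fraction)·(r_i + r_j); foreground/background
intensities 60/180; Gaussian blur σ = 1 px for soft edges; additive
Gaussian noise σ = 5 clipped to [0, 255]; 320×320 px by default. Truth
labels assign overlap pixels to the nearer centre, mirroring the
watershed's distance-based cut. Regeneration from the same spec is
bit-identical.

Overlaps are rendered by transmitted-light absorbance: each covering
granule multiplies the transmittance, so a two-granule lens is darker
than a single granule and every granule's rim stays visible through the
overlap. This is both the physically right model for stained granules
and essential to the method's premise: with flat two-level rendering a
mildly pinched pair of granules produces a single degenerate GVF
stagnation zone at the neck and *no* per-granule critical point, and no
detector threshold fixes that — the information simply is not in the
image. `overlap_darkening=False` restores the flat two-level model for
experiments that need it.

What the generator does **not** emulate: granule texture (hilum, growth
rings), uneven illumination, out-of-focus blur gradients, debris, and
clusters of three or more mutually overlapping granules are rare under
the placement rule. Passing the synthetic suite therefore demonstrates
the pipeline's mechanics (splitting, classification, merging) under the
stated imaging model, not robustness to every real-world artefact.

The scorer matches predicted to true granules greedily by IoU (1:1);
a granule counts as resolved at IoU ≥ 0.5. A predicted label that
majority-owns k ≥ 2 truth granules contributes k−1 merges; k ≥ 2
predicted labels whose own majority lies in one truth granule
contribute k−1 splits.

## Problem sizes in the test suite

The acceptance tests use 100 random histograms (thresholding oracle),
50 random blob masks at 128² (chamfer vs exact Euclidean), 50 seeded
single-granule images at 128² (critical-point recovery), and 50 seeded
scenes at 320² with 3–10 granules (end-to-end count recovery, required
≥90% correct). These sizes exercise the full parameter ranges the
generator defaults define while keeping a complete run of the suite
around a minute.

## Known limitations

* A fragment covering more than half a granule passes both tests and is
  counted as a granule (see above).
* The ROI-centre distance feature is ambiguous for symmetric blobs;
  the adjacency repair and the optional coordinate features mitigate
  but do not eliminate this.
* Heavily overlapping clusters (three or more granules sharing one
  blob, or overlap fractions well past 0.3) degrade both the watershed
  cut placement and critical-point separation.
* The global threshold assumes reasonably even illumination; strong
  vignetting would need flat-field correction upstream.
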