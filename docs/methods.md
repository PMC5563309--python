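# Methods

## The tracking model

Tracking operates on a *peak field*: up to five unit directions per
voxel, each optionally carrying an uncertainty half-angle α (radians).
Peaks are axial objects (±v equivalent); the tracker resolves the sign
at every step by choosing whichever sign of whichever peak has the
smallest angle to the incoming direction, and gives up when that angle
still exceeds `max_angle`.

The deterministic update is a convex blend of the incoming direction
`V_{n−1}` and the selected peak `V_n`,

    V_{n+1} = normalize( f·V_n + (1−f)·((1−g)·V_{n−1} + g·V_n) ),

with `f` the scalar map (FA, GFA or AFD) at the current voxel, clipped
to [0, 1] so the blend stays convex on maps that exceed 1, and `g` the
puncture weight. Because the result lies in the plane spanned by
`V_{n−1}` and `V_n`, between them, the per-step turn of an emitted
streamline never exceeds the angular gate — the post-hoc curvature check
in the test suite is a safety net, not a correction.

The probabilistic tracker replaces `V_n` by `θ(V_n, α)`, one uniform
draw from the spherical cap of half-angle α about `V_n`. The draw
happens **once** per step and is reused in both occurrences of the
symbol; drawing twice would decorrelate two appearances of the same
quantity. The cap sampler is the standard inverse-CDF construction
(`cos t` uniform on `[cos α, 1]`, azimuth uniform), so `E[d·V] =
(1+cos α)/2`. With α = 0 the sampler returns `V_n` exactly and consumes
no random numbers; under the shared per-streamline seed schedule the
probabilistic tracker is then bit-for-bit identical to the deterministic
one. In probabilistic mode the cone-perturbed direction is gated against
`max_angle` as well (the half-track ends when the perturbed direction
turns too sharply), which keeps the curvature bound valid in both modes.

Seeding draws `seeds_per_axis³` uniform positions in an axis-aligned
box. Each seed picks one of its voxel's peaks uniformly at random and is
propagated in both senses (±the initial direction); the two half-tracks
share the seed point. Stop criteria per half-track: mask below
threshold, no admissible peak, the next step would exceed `max_length`
(the streamline is kept, truncated), leaving the volume, or a degenerate
(zero) blend. Streamlines shorter than `min_length` are rejected and
tallied, so `emitted + rejected = seeds` always holds.

Scalar and mask values are read at the nearest voxel (a voxel's center
sits at integer continuous-voxel coordinates, and membership is
element-wise rounding); no interpolation, matching the per-voxel
semantics of the update rule.

### Parameters and defaults

| parameter | default | unit | role |
|---|---|---|---|
| `step_size` | 0.5 | mm | distance advanced per iteration |
| `max_angle` | 50 | deg | gate on each new direction |
| `mask_threshold` | 0.1 | map units | minimum scalar value to keep tracking |
| `puncture` (g) | 0.2 | — | incoming-vs-new direction weight |
| `min_length` / `max_length` | 10 / 200 | mm | validity span of a streamline |
| `seeds_per_axis` | 10 | — | 1000 seeds per run |
| `fwhm_fraction` (k) | 0.35 | — | fraction at which α is measured |

These are the conventional operating point for this family of real-time
trackers (a demonstrated corpus-callosum reconstruction uses exactly
this set); k = 0.35 is the permissive-but-stable cone fraction.

### RNG discipline

One master seed spawns an independent PCG64 stream per streamline index
(plus one for seed placement), so results are independent of evaluation
order and a bundle is reproducible byte-for-byte from `(inputs, params,
rng_seed)`.

## Uncertainty angles on the sphere

fODFs are real, even-degree spherical harmonics (45 coefficients at
`lmax = 8`; basis: `m<0 → √2·Im Y_l^{|m|}`, `m=0 → Y_l^0`, `m>0 →
√2·Re Y_l^m` — any self-consistent real symmetric convention works
since the phantom fixtures are authored with the same basis through the
least-squares `sf_to_sh`). They are evaluated on a subdivided
icosahedron: 642 vertices at level 3, antipodally symmetric by
construction, maximum edge ≈ 9.4°. This stands in for classic 724-vertex
symmetric spheres of equivalent resolution; sphere resolution is a free
parameter and bounds every angular error below.

Peaks are *strict* local maxima over the mesh adjacency — an isotropic
plateau yields no peaks rather than an arbitrary tie-break — deduplicated
over antipodes, thresholded at `relative_threshold` (default 0.5) of the
global max, and greedily pruned to `min_separation_angle` (default 25°).
Those two extraction defaults are conventional; nothing downstream is
sensitive to them on the phantoms.

α traversal: from the peak vertex, vertices are visited best-first by
angular distance to the peak (a heap over the adjacency); α is the
distance of the first vertex whose value drops below `k × peak`. This
"first below threshold, in distance order" rule is deterministic and is
the most literal reading of traversing neighbours until the fraction is
reached. If nothing within 90° drops below the fraction (near-isotropic
voxels), α caps at π/2 and the cone degrades gracefully to a hemisphere.
α is monotone non-increasing in k by construction (a vertex below a low
threshold is below every higher one).

## Phantoms

Three geometries embed a tube-shaped bundle (half-width 8.6 mm ≈ 5
voxels, a corpus-callosum-like thickness) in a 40³ grid at 1.72 mm
isotropic: straight (along x), curved (90° arc, radius 20 mm), and
crossing (two straight arms at 90°, two peaks per overlap voxel). FA is
0.8 inside / 0.05 outside — typical white matter over a background that
sits below the 0.1 tracking threshold.

The single-fiber kernel is Gaussian in angle, `exp(−θ²/2σ²)` with
σ = 20°, chosen because its fraction-crossing angle is analytic:
α(k) = σ√(2 ln(1/k)), e.g. 28.98° at k = 0.35 and the literal FWHM
half-width 1.1774σ at k = 0.5. That closed form is the independent
oracle for the mesh traversal (agreement required within one mesh edge)
and supplies exact α values to the phantom's peak field without
extraction. Crossing voxels store the unnormalized sum of the two arms'
kernels, so their peak values deliberately differ from single-fiber
voxels and exercise the relative threshold.

What the phantoms do *not* emulate: measurement noise on the SH
coefficients, partial-volume gradients at bundle borders, curving
crossings, or anatomy-scale geometry. Passing tests therefore establish
the correctness of the algorithms and their limit behaviors, not
reconstruction quality on acquired brains.

## Bundle comparison

A density map counts, per voxel, the number of *distinct* streamlines
visiting it (points are binned to nearest-center voxels and deduplicated
per streamline; valid because the 0.5 mm step is below the 1.72 mm voxel
size — a warning fires if a bundle violates that). The weighted Dice

    wDice = Σ_{v∈A∩B}(ρ_A+ρ_B) / (Σρ_A + Σρ_B)

is symmetric, bounded in [0, 1], equals 1 on identical maps, 0 on
disjoint supports, and reduces to binary Dice on 0/1 maps. No density
thresholding is applied before comparison. On the crossing phantom,
deterministic vs probabilistic (k = 0.35) bundles from the same
2×2×2-voxel seed box score ≈ 0.85 — the synthetic analog of the
published 81–93% online/offline agreement range, asserted in the suite
only as a loose stochastic bound (> 0.8 in ≥ 19/20 seeded repeats).

## Selection structures

The octree is built top-down over all streamline points (static data,
known a priori; no incremental insertion), bounds padded by 1e-6 mm,
leaf capacity 64, depth cap 8 — both knobs, with "level of
simplification" otherwise unspecified. Box membership is **closed**
(boundary points count as inside), and the brute-force oracle in the
tests implements the same convention. Slab filtering keeps segments by
interval overlap with the slab, not endpoint membership, so segments
piercing a thin slab survive — this is what a clipping shader would
display.

## Numerical choices and degenerate inputs

* Peak vectors on disk are renormalized on read when ‖v‖ deviates from 1
  by more than 1e-3 (files in the wild carry magnitudes); exact zeros
  mean "empty slot" and are preserved.
* Ties in peak selection break toward the lowest peak index; ties in
  sphere peak sorting are stable by value.
* `max_length` stops *before* the offending step (streamline kept);
  `min_length` rejects.
* Antiparallel blend cancellation (`‖blend‖ < 1e-12`) terminates the
  half-track.
* An empty tractogram is writable and readable; single-point streamlines
  are a write-time error.
* TrackVis stores float32: coordinates round-trip within 1e-4 mm at
  desk-scale extents, which is the tolerance used throughout.
* Tractogram provenance (full parameter record) travels in a `.trk.json`
  sidecar — the fixed TrackVis header has no free-text field of useful
  size.

## Problem sizes in the test suite

The suite validates tracking contracts on 1000 streamlines per phantom,
the bundle-agreement bound over 20 seeded repeats of 1000 seeds, octree
queries against a linear-scan oracle on a 25,000-streamline synthetic
tractogram (the scale recommended for interactive exploration) with 1000
random boxes, and cone statistics on 1e5 draws — sizes chosen so the
whole suite completes in minutes on one CPU while keeping every
stochastic bound comfortably powered.

## Known limitations

* Nearest-voxel sampling only; trilinear sampling of `f` is not
  implemented.
* No full-fODF probabilistic sampling — the cone model is the point of
  this package; an offline fODF tracker would be an external comparator.
* Single selection box; no exclusion boxes or segment-based filtering.
* No DWI simulation or SH noise model in the phantoms.
* Peak axes are fixed to world-RAS; files using voxel-axis conventions
  must be converted upstream.
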