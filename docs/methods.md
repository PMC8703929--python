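# Methods

## Overview

`nbvscan` plans recording poses for 3D wound reconstruction from surface
evidence alone: no volumetric occupancy grid and no prior model of the
scene. The planner's state is a labeled point cloud accumulated over
recording cycles; its two deficiency detectors — sampling density and range
discontinuity — drive two hypothesis generators whose candidates compete
under a single scalar score. A virtual depth camera closes the loop on
procedurally generated wound scenes.

The pipeline assumes a rigid scene (the patient does not move between
recordings), a range camera with pinhole geometry whose measurements are
dense within its field of view, and recordings that arrive roughly
pre-aligned in a common base frame (as robot odometry provides), so that
registration only corrects residual error.

## Classification

Within the wound's oriented bounding box (the covariance-aligned box over
the back-projected 2D wound rectangle of the first recording, inflated
10%), each point is classified per cycle:

* **edge**: a pixel of the current depth image whose range differs by more
  than `d_thr` from at least one 8-neighbor. Invalid (zero) neighbors count
  as discontinuities, so dropout boundaries also produce edges; out-of-image
  neighbors are skipped.
* **core / outlier**: a candidate (new in-box point or previously-outlier
  point) is core when strictly more than `n_thr` *other* points of the
  whole aligned cloud lie within radius `r`. Core status is permanent:
  density only grows as recordings accumulate.
* **frontier**: rebuilt each cycle as the core points within `r` of a
  remaining outlier. Frontier points removed from the core set one cycle
  are returned to it at the start of the next before reclassification, so
  core/outlier/frontier stays a partition (the alternative — leaving them
  permanently out of the core set — would let the frontier sets of
  successive cycles interact, which nothing in the procedure needs).

## Hypothesis generation

**Frontier clusters.** Every frontier point with a valid normal proposes a
sub-pose at `p + d_rec·n` with view axis `Z = −n`, `X = [0,0,1] × Z`
(falling back to `[0,1,0] × Z` when the view axis is vertical), `Y = Z × X`.
The 7-D features (position divided by `d_rec`, so both parts are O(1), and
unit quaternion canonicalized to `w ≥ 0` to avoid double-cover splits) are
k-means-clustered into `min_c + ⌊|F|/step_c⌋` clusters; each center, with
its orientation part renormalized, becomes a hypothesis of size `N_h` = the
member count.

**DPlanes.** Edge pixels of the current image are k-means-clustered on 2D
pixel coordinates with the same count scaling. A cluster whose largest
covariance eigenvalue exceeds `e_thr` times the middle one is line-like and
discarded; the rest are fitted by a RANSAC plane (inlier distance 2 mm,
1000 iterations, seeded). The plane normal is oriented into the hemisphere
facing the camera; if the normal is within the 80–90° band of the view
direction the orientation is undecidable and the plane is stored in both
orientations. Each live DPlane proposes a pose at `center + d_rec·normal`
viewing along `−normal`.

**DPlane lifecycle.** A DPlane bounds surface no recording has seen. Its
edge points carry overlap flags that only ever get set (idempotent growth):

* an **old** plane's edge point is flagged when *new surface* appears
  within `r` of it — a current-recording point farther than `r/2` from all
  prior-recording surface. A bare re-view of already-scanned surface
  therefore never retires a plane whose hidden side is still hidden; only
  actually scanning the bounded deficiency does. The `r/2` threshold sits
  above the sampling pitch (~0.3 mm) and residual alignment error, and
  below the density radius.
* a **new** plane is discarded immediately when ≥ `o_thr` of its edge
  points lie within `r` of prior-recording surface: its discontinuity
  bounds a region some earlier view already recorded (and this also
  suppresses per-cycle re-detections of a persisting discontinuity, whose
  old plane remains the canonical one).

A plane is deleted when flagged edge points reach the fraction `o_thr`.
An earlier implementation tested sidedness against the plane instead; that
fails geometrically, because a self-occlusion window plane contains the
grazing view rays, so the hidden surface hugs the plane and rim-side edge
points could never be flagged.

## Scoring and pose selection

    score = α·N_v + β·exp(−2 d) + γ·N_h

`N_v` counts frontier points that are inside the candidate's view frustum
and face the camera within the visibility cone (`dot(n, Z) ≤ −cos 60°`),
plus, for every DPlane whose center passes the same two checks, its full
edge-point count. `d` is the distance from the previous recording position
**in meters**: with millimeters the exponential would be identically zero
for any realistic motion and the β = 100 weight inert; in meters it
meaningfully rewards nearby poses (100 at 0 m, ≈55 at 0.3 m). Ranking is a
stable descending sort with deterministic tie-breaks (frontier-cluster
provenance first, then larger `N_h`, then insertion order).

Selection walks the ranked list: candidates within `proximity_min_dist` of
any previous recording position are skipped (this prevents the planner from
re-recording a surface it cannot actually improve from that direction);
a reachable candidate is returned; an unreachable one spawns a sphere-slice
of fallback poses — an azimuth × elevation grid on the sphere through the
candidate around its focus point, all aimed at the focus — scored with
`N_h = 0` (they come from no cluster), and the best reachable fallback is
taken. An exhausted list ends the recording process. Robot kinematics are
abstracted behind a pure `Pose -> bool` predicate; the analytic default
accepts a spherical shell of positions around a base point with the view
axis inside a cone of the toward-patient direction.

## Registration

Pairwise alignment is coarse-to-fine: FPFH descriptors (33-bin, radius 5×
the 20 mm coarse voxel) matched by mutual nearest neighbor and sample
consensus on 20 mm-voxel clouds, then point-to-plane ICP on 2 mm-voxel
clouds at 10 mm and finally 5 mm correspondence limits (convergence:
relative RMS change < 1e-6 or 50 iterations). Because recordings arrive
roughly pre-aligned, the identity is always kept as a rival initialization
and the better fine-ICP outcome wins by (fitness, inlier RMS); a spurious
feature-consensus fit between two noise-textured, nearly flat patches can
otherwise trap ICP in a flipped minimum. A result whose fitness falls below
`fitness_floor` is flagged failed.

Multiway alignment builds a pose graph — odometry edges between consecutive
recordings plus loop closures for every nonconsecutive pair that clears the
fitness floor — and minimizes edge residuals (rotation-vector part weighted
by a 500 mm lever arm) with a soft-L1 robust loss over per-recording rigid
transforms, the first recording fixed. Outputs are re-projected onto SO(3),
so transforms are exactly rigid. With one recording the result is the
identity; with two, the pairwise result.

## Virtual scanner and wound scenes

Rendering is a perspective-correct z-buffer rasterizer (1/z linear in
screen space): per pixel the nearest triangle hit along the optical axis,
zero outside [near, far]. Surface struck beyond 80° incidence returns no
measurement — the nearest hit still occludes, but the pixel is invalid —
emulating how structured light fails on near-grazing surfaces; without this
cutoff every oblique view mints slivers of unusably sparse samples that
keep the deficiency sets alive forever. The default intrinsics emulate the
physical scanner's sampling at desk scale: ~0.29 mm pixel pitch at the
650 mm stand-off (≈149 samples per 2 mm-radius disc, versus the 60
demanded — the same ~2.5× margin as the real device) with a field of view
(450×340 px, f = 2240 px → 130×98 mm at 650 mm) that covers a whole wound
in every view.

The crater is a surface of revolution: with profile parameter t ∈ [0, 1],
`r(t) = R(1−t) + b·sin(πt)`, `z(t) = −depth·(1−cos(πt))/2`, which reduces
to the cosine-bell bowl `z(r) = −depth(1+cos(πr/R))/2` at bulge b = 0.
Undermining sets `b = depth·tan(angle)` over an azimuth sector (raised-
cosine taper), forming a directional pocket whose ceiling lies beneath
intact skin — real wounds undermine directionally, and a full axisymmetric
undermined ring would need a recording from every azimuth, beyond any
few-view schedule. Tunneling cuts an orifice in the cavity floor and
attaches an inclined bore (35° below horizontal) behind it: the mouth rim
presents a frank range discontinuity while the interior is out of every
exterior line of sight. The mesh is a thin shell, and the renderer is
double-sided, so a camera behind a cavity wall records the wall's far side;
a solid-tissue scanner would instead see outer skin. Ground truth carries
the mesh, a per-triangle wound mask, and the wound's bounding rectangle in
a given view (standing in for a 2D wound detector).

What the scenes do **not** emulate: tissue color and reflectance, scanner
noise models (optional Gaussian depth noise is available but defaults off,
as real scanner noise of ~0.1 mm is far below every threshold used), patient
motion, and calibration error between color and range sensors. Passing
loop tests therefore demonstrate the planning logic under ideal sensing,
not robustness to real-device artifacts.

## Coverage metric

Reconstruction quality is measured against the scene's own mesh:
area-weighted random samples on the wound triangles are *accessible* when a
ray toward at least one of 25 exterior probe directions (top-down plus
rings at 15°, 40° and 65° polar) escapes the scene unobstructed, and
*covered* when strictly more than `n_thr` cloud points lie within `r` — the
same density rule the classifier enforces. Coverage is covered/accessible;
RMS is the covered samples' distance to the nearest cloud point.
Cloud-to-mesh distance uses a dense surface sampling (300k points) rather
than exact point-triangle projection; the ~0.1 mm bias this carries cancels
in the before/after comparisons it serves.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `d_thr` | 15 | mm | edge threshold on 8-neighbor depth difference |
| `r` | 2 | mm | density neighborhood radius |
| `n_thr` | 60 | count | neighbors required for a core point |
| `d_rec` | 650 | mm | recording stand-off distance |
| `alpha, beta, gamma` | 0.8, 100, 0.2 | — | score weights |
| `e_thr` | 10 | ratio | eigenvalue ratio rejecting line-like edge clusters |
| `o_thr` | 0.95 | fraction | overlap fraction retiring a DPlane |
| `perp_band_deg` | (80, 90) | deg | undecidable normal band → duplicate plane |
| `vis_cos_max` | cos 60° | — | visibility cone half-angle cosine |
| `min_c/step_c` (frontier) | 1 / 100 | — | cluster-count scaling for frontiers |
| `min_c/step_c` (edge) | 1 / 250 | — | scaling for edge pixels; chosen to yield 1–9 clusters at the 200–2000 edge pixels a recording produces |
| `voxel_fine/coarse/final` | 2 / 20 / 1 | mm | downsampling resolutions |
| `icp_coarse/fine_dist` | 10 / 5 | mm | ICP correspondence limits |
| `fitness_floor` | 0.2 | fraction | below this a pairwise result is failed |
| `bbox_inflation` | 0.10 | fraction | oriented-box safety margin |
| `proximity_min_dist` | 150 | mm | keep-away radius around past recordings |
| `sphere_cap_deg`, grid | 30, 12×4 | deg | sphere-slice fallback cap and grid |
| `max_cycles` | 10 | count | loop budget guard |

`proximity_min_dist` deserves a note: it is far above residual alignment
error and well below typical inter-view motion (300–600 mm). A much
smaller radius admits near-duplicate viewpoints, and because frontier
points near an occluded pocket remain visible (and thus keep scoring) from
views that cannot possibly densify the hidden surface below them, the
frontier pathway then starves the DPlane pathway indefinitely.

## Numerical choices and degeneracies

Voxel grids are anchored at the origin with half-open cells
(`floor(p/voxel)`); the output point is the cell centroid and remaining
attributes come from the cell's first point in input order. Normals are the
smallest-eigenvalue eigenvector of the neighborhood covariance, sign-fixed
toward the recording viewpoint; neighborhoods under 3 points flag the
normal invalid and exclude the point from hypothesis generation. A single
point (or all-identical points) is a degenerate extent for the oriented
box. K-means uses a fixed `random_state` and `n_init=10`; all consensus
loops draw from generators seeded from `ScanConfig.seed`, and two runs with
the same seed are bitwise identical.

## Limitations

* Greedy one-step lookahead: the score never anticipates what a view will
  reveal, only what is already catalogued as deficient.
* The visibility count treats a frontier point as servable by any pose that
  sees it inside the cone, even when the sparse surface below it is hidden
  from that pose; the proximity rule compensates only indirectly.
* Thin-shell backface rendering lets the simulator record hidden cavities
  from behind in ways a solid-tissue scanner could not; coverage of
  undermined pockets is accordingly optimistic.
* Termination on complex geometry is typically by the cycle budget or the
  reachability model, not by literal emptiness of the deficiency sets;
  grazing-incidence dropout boundaries always leave a few edge points.
* Registration assumes rough pre-alignment; there is no global relocalization
  if a recording arrives grossly mis-posed.
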