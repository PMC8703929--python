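# nbvscan

Next-best-view (NBV) planning and closed-loop simulation for 3D
reconstruction of chronic wounds.

Chronic wounds — pressure ulcers, venous and diabetic ulcers — can be deep,
undermined (cavities extending beneath intact skin) and tunneled, so no
single camera view captures the whole surface. A robot-mounted range scanner
must choose a *sequence* of recording poses that removes the remaining
surface deficiencies while staying reachable. `nbvscan` implements such a
surface-based NBV planner together with a virtual depth camera and
parametric wound scenes, so the entire recording loop runs at desk scale
without robot hardware.

## Method

Every recording cycle classifies each point of the aligned global cloud
inside the wound's oriented bounding box into one of four classes:

* **edge** — a depth-image pixel whose range differs from an 8-neighbor by
  more than d_thr = 15 mm (a discontinuity: self-occlusion or dropout);
* **core** — more than n_thr = 60 other points within r = 2 mm;
* **outlier** — a non-edge point failing the density demand;
* **frontier** — a core point within r of an outlier: the boundary between
  densely and sparsely sampled surface.

Deficiencies drive two hypothesis generators. Each frontier point proposes a
sub-pose at the recording distance d_rec = 650 mm along its surface normal,
looking back at the point; the 7-D (position, quaternion) features are
k-means-clustered and cluster centers become candidate poses. Edge pixels of
the current image are clustered in 2D; each sufficiently planar cluster is
fitted with a RANSAC plane — a **DPlane**, a bounded discontinuity plane
standing in front of surface no view has seen yet. DPlanes persist across
cycles until genuinely new surface appears next to their edge points, and
each live DPlane proposes a pose along its oriented normal.

Candidates are ranked by

    score = α·N_v + β·e^(−2d) + γ·N_h,     (α, β, γ) = (0.8, 100, 0.2)

where N_v counts deficiencies visible from the pose (a frontier point counts
1, a visible DPlane counts its edge points), d is the distance to the
previous recording position in meters, and N_h is the size of the generating
cluster. The best-ranked pose that is reachable (per a pluggable robot
reachability model) and not too close to a previous recording becomes the
next view; unreachable candidates fall back to a sphere-slice of nearby
poses aimed at the same focus. Recordings are registered coarse-to-fine
(FPFH correspondences, then point-to-plane ICP at 10 mm and 5 mm) and jointly
refined by pose-graph optimization. The loop stops when no hypothesis
remains or none is reachable; the final model is the 1 mm voxel-filtered
global cloud.

## Worked example

Scan a deep crater (opening radius 20 mm, depth 25 mm) with a 28° undermined
pocket over a 90°-wide sector — a morphology where the pocket ceiling is
invisible from above:

```python
from nbvscan import (ScanConfig, WoundSceneParams, always_reachable,
                     coverage_report, make_wound_mesh, run_loop)

scene = make_wound_mesh(WoundSceneParams(crater_radius=20.0, crater_depth=25.0,
                                         rim_undermining_angle=28.0,
                                         undermining_width_deg=45.0))
cfg = ScanConfig(max_cycles=6)
result = run_loop(scene, cfg, always_reachable())
for rep in result.reports:
    c = rep.counts
    print(f"cycle {rep.cycle}: core={c['core']:6d} outlier={c['outlier']:4d} "
          f"frontier={c['frontier']:4d} edge={c['edge']:4d} "
          f"dplanes={rep.n_dplanes} chose {rep.chosen_provenance}")
cov = coverage_report(scene, result.global_cloud, cfg, seed=1)
print(f"coverage of accessible wound surface: {cov.coverage:.1%}")
```

prints

```
cycle 0: core= 56233 outlier=1118 frontier= 980 edge= 517 dplanes=1 chose frontier_cluster
cycle 1: core=106669 outlier= 411 frontier= 662 edge=1108 dplanes=1 chose frontier_cluster
cycle 2: core=140042 outlier=  94 frontier= 398 edge=1884 dplanes=1 chose frontier_cluster
cycle 3: core=146249 outlier= 159 frontier= 522 edge=2302 dplanes=2 chose dplane
cycle 4: core=173640 outlier= 170 frontier= 478 edge=2964 dplanes=3 chose dplane
cycle 5: core=220914 outlier=  30 frontier= 289 edge=3470 dplanes=3 chose frontier_cluster
coverage of accessible wound surface: 97.7%
```

The first (top-down) view detects the pocket as a DPlane; frontier-driven
views densify the bowl; the DPlane-driven views at cycles 3–4 look under the
lip and scan the hidden ceiling. After six recordings, 97.7% of the
camera-accessible wound surface is sampled at the required density, and the
1 mm-filtered model (20 409 points) sits 0.19 mm RMS from the true surface.
A flat shallow wound instead terminates after a single recording with no
deficiencies, and a tunneled wound scanned under a restrictive reachability
model stops early with the tunnel's DPlane still standing — the planner's
honest report that part of the wound cannot be recorded.

A thin CLI wraps the library: `nbvscan simulate` (full loop on a synthetic
scene), `nbvscan analyze` (label one depth recording), `nbvscan plan`
(propose the next pose from a labeled cloud).

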