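# Methods

## Acquisition model

A 2-D LiDAR profiler sweeps a vertical fan of beams (elevation grid from
`start_angle` to `stop_angle` in steps of `beam_angular_interval`,
0.0029 rad at the 25 Hz sweep rate) while the plant rotates continuously
on a stage at `rotation_speed` (3°/s routine; the stage supports up to
80°/s for faster, sparser scans). The stage angle of sweep *i* is
ϕ = ω·(i/f + t₀) with ω the stage speed, f the sweep rate and t₀ the scan
start offset; all beams within a sweep share the sweep-start ϕ (the sweep
lasts 1/f = 40 ms, during which the stage moves 0.12° — below the ranging
noise at the working distance). Records convert to stage-centered
Cartesian coordinates via X = (D − R cos θ) cos ϕ, Y = (D − R cos θ) sin ϕ,
Z = h + R sin θ. Internal units are millimetres and radians throughout;
the CLI and config files accept degrees with a `_deg` key suffix.

Consequences used in the tests: azimuthal (radial) resolution
ω/f = 0.0021 rad at 3°/s and 25 Hz; vertical sampling spacing
0.0029·range (2.9 mm at 1 m); 120 s per full rotation; and
(radial resolution) × f × (rotation duration) = 2π exactly.

## Virtual scanner

Synthetic plants are built from a tapered stem on a pot plus parametric
blades. Each blade is a ruled surface around a planar midrib whose
tangent angle falls from the base inclination ψ₀ as
ψ(s) = ψ₀ − droop·90°·s^p (arclength fraction s ∈ [0,1]); the exponent
p concentrates the bend toward the tip, as on real maize where the
proximal half stays straight and the distal blade arches over. Lateral
ruling is horizontal with half-width `max_width`·profile(s)/2; the default
sine-arch profile sin(πs) tapers base and tip and gives the closed-form
area L·W·2/π (the ruled construction makes the area element
L·width(s) independent of droop, which the quadrature ground truth and the
Monte-Carlo oracle in the tests confirm). The facet elevation angle of
the ruled blade equals |ψ(s)|, so the ground-truth angular distribution is
a 1-D width-weighted quadrature over s.

Scanning exploits the fact that every beam of a sweep lies in the vertical
plane through the rotation axis at that sweep's stage angle: the scene
mesh is sliced by the plane, the cut segments are projected to (radial,
height) coordinates, and the beam fan is intersected with the segments;
the nearest hit beyond a 0.01 mm tolerance wins. This is exactly
nearest-hit ray casting against the triangulated scene (occlusion
included) organised per sweep. Gaussian noise with σ = 2 mm is added to
the range by default — the instrument's quoted 6 mm ranging precision read
as a ±3σ envelope; beams that hit nothing emit no record. An optional
axis-aligned room box provides realistic background returns. Plant
generation and ranging noise draw from independent streams spawned from
one seed, so the same plants can be re-scanned at other noise levels.

### Archetype parameters

Values were fixed once when the generator was designed, to reproduce the
species' described canopy geometry at desk scale:

- maize-like: 6–11 leaves alternating in a single vertical plane
  (planar architecture); regular internodes of 105–130 mm with ±15%
  phyllotactic jitter; blade length 200–280 mm scaled ×(1.25 − 0.4·relative
  height) so lower blades run longer; width 45–70 mm; base inclination
  ψ₀ ~ U(74°, 80°) with droop ~ U(0.35, 0.8) at exponent 3. This yields
  erectophile angular distributions that rise from low angles to a peak in
  the [70°, 80°) bin, the shape reported for greenhouse maize.
- sorghum-like: 5–10 leaves with azimuths spread in all directions,
  ψ₀ ~ U(50°, 75°), droop ~ U(0.3, 0.7) at exponent 2, giving the
  flatter 45–75° plateau described for sorghum.

The plants are deliberately smaller than a V11 greenhouse maize (~0.7–1.4 m
vs 1.6 m) and their blades short relative to internodes so that single
plants remain leaf-separable, which the real validation plants were. What
the synthetic study does **not** emulate: fine wrinkle structure at leaf
edges (below the instrument's resolution in any case), leaf sheaths,
tassels, multi-return/beam-divergence physics, and the leaf crowding of
late vegetative stages — so passing recovery tests bounds method error
under clean architecture, not performance on heavily occluded canopies.

## Processing pipeline

1. **Background removal** — keep points inside a closed axis-aligned box.
2. **Voxelization + density filter** — 10 mm voxels, drop voxels with
   fewer than 2 points (stray reflections and mixed-pixel edges have low
   local density). Both thresholds are heuristic and exposed in config.
3. **Pot/stem removal** — drop points within `stem_radius` of the rotation
   axis and everything at or below `pot_top_z`. The radial cutoff is
   constant with height by default, which slightly clips the base of upper
   leaves and under-clips near the pot on tapered stems; a linear taper
   option exists. The package default is 30 mm; the synthetic validation
   runs use 20 mm, sized to their 6–16 mm stems.
4. **Segmentation** — k-means (k-means++, 10 restarts, fixed seed,
   Euclidean on raw mm coordinates) with k = leaf count supplied by the
   operator; labels are renumbered bottom-to-top by centroid height. An
   optional (default-on) refinement pass follows: each cluster is reduced
   to its largest spatially connected body (10 mm voxels linked within
   29 mm) and every point is re-labelled by its nearest core, with points
   farther than 12 mm from every core dropped. This corrects the
   characteristic k-means failure of slicing a convex cell through a
   neighboring blade, which otherwise poisons that blade's surface fit.
5. **Surface fitting (LOWESS)** — per leaf, an orthonormal local frame is
   chosen by PCA (w = least-variance axis), keeping the height function
   w = f(u, v) well-posed for steep erectophile leaves; `frame_mode=
   "xy-plane"` reproduces fitting in the world XY plane for comparison.
   At each evaluation point the nearest ⌈bandwidth_fraction·n⌉ support
   points (default 0.3, capped at `max_neighbors` = 1000 so the fit stays
   local at full scan density) are tricube-weighted and a full quadratic
   is solved by weighted least squares; rank-deficient neighborhoods fall
   back to weighted linear, then weighted mean. One robustifying
   iteration discards support with height residuals beyond 6 scaled MADs.
   For tractability the support is first thinned to `max_support_points`
   (default 3000) on an even grid **in the (u, v) plane** — thinning in
   3-D or at random leaves near-duplicate picks because ranging noise
   thickens the cloud into a ~5 mm shell.
6. **Triangulation** — Delaunay on the support (u, v); convex-hull fill
   outside the blade outline is trimmed by an envelope rule: the u range
   is binned, the observed per-bin v extent (interpolated across empty
   bins, widened by a margin tied to the median triangulation edge) forms
   the outline, and triangles whose centroid leaves it are dropped.
   Interior triangles always survive: inside a blade a long edge marks an
   occlusion shadow that the smooth fitted surface should span. (A plain
   long-edge prune is unusable here: the rotating-sweep sampling is so
   anisotropic and clustered that the median nearest-neighbor spacing
   undershoots typical Delaunay edges severalfold.) Vertices are elevated
   to the fitted height and mapped back to world coordinates; triangle
   normals are oriented with non-negative Z (ties: +X).
7. **Traits** — leaf area = Σ triangle areas; total area = Σ leaves;
   inclination = angle to the horizontal of the principal direction of
   the mesh vertices within 20% of the leaf's span from the vertex
   nearest the stem axis (the attachment proxy); LAD = area-weighted
   histogram of arccos|n_z| in 10° bins, [80°, 90°] closed. Using |n_z|
   makes bins immune to normal-orientation flips. Validation statistics:
   R² as squared Pearson correlation of the pairs (1 − SSE/SST about the
   identity line available as an option) and MAE, also as a percentage of
   the reference mean. Plant-set LADs are averaged per plant, with the SD
   across plants.

## Numerical choices and degenerate inputs

- Intersection tolerance 0.01 mm along the beam; segments subtending no
  beam are skipped via per-segment beam-index intervals.
- Tricube weights are floored at 1e-6 so the farthest neighbor cannot
  zero the design row; coincident evaluation/neighborhood points fall
  back to uniform weights.
- Delaunay failures (collinear support) and empty prunes raise stage-named
  pipeline errors; zero-area triangles are dropped before normals.
- Leaf label ordering is deterministic (centroid height, stable argsort);
  the whole pipeline is a pure function of (input, config, seed) and the
  trait JSON is byte-identical across re-runs.
- The k-means restart seed is reduced modulo 2³¹ for scikit-learn.

## Problem sizes

The validation study uses ten plants scanned at the full routine sampling
geometry (0.0029 rad beams, 3°/s at 25 Hz → 3000 sweeps/rotation,
~1.2 M records per plant) with σ = 2 mm noise, processed end-to-end in
roughly half a minute per plant; the whole study runs in a few minutes on
one CPU. Reconstruction-accuracy unit tests use single-blade scans and
coarser stage speeds (24–60°/s), which the physical stage also supports.

## Known limitations

- k is operator-supplied (no automatic leaf counting), as on the
  instrument.
- The constant-radius stem filter removes the blade base inside the
  cutoff cylinder; with steep blades this costs a few percent of area and
  is the main systematic underestimate, mirroring the instrument's
  reported behaviour.
- Heavily crowded or non-upright plants are out of the validated regime;
  the refinement pass assumes blades are spatially separated bodies.
- The LOWESS surface is single-valued in the leaf frame; a blade curled
  past 90° of total bend relative to its PCA plane would fold.
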