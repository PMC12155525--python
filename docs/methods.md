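# Methods

## Pipeline model and assumptions

The package treats 3D semantic segmentation as a 2D problem plus
geometry. Its correctness rests on three assumptions: (i) the scan is a
single connected textured surface whose every vertex belongs to exactly
one of 28 classes; (ii) camera poses used for rendering are known
exactly at baking time, so the visibility of a vertex can be decided by
comparing its projected depth against the render's z-buffer; (iii) the
palatal rugae patch is rigid between the two scans being compared, while
teeth move rigidly and the remaining mucosa may deform. Assumption (iii)
is what makes the two-stage alignment identifiable: ICP on rugae
vertices removes the global pose difference, after which each tooth's
own registration isolates its orthodontic movement.

## Rendering

The renderer is a deliberate software rasterizer (pinhole projection,
screen-space barycentric fill, z-buffer) rather than an OpenGL/GPU path:
results are bit-reproducible across machines and runs, which the tests
and the baking stage rely on. Depth is interpolated affinely in screen
space; for the small triangles our meshes produce the deviation from
perspective-correct depth is far below the visibility tolerance.
Texture shading is Gouraud (per-vertex) under three lighting modes:

- `glow` — raw vertex colors, no shading;
- `ambient` — Lambertian with one directional light at infinity
  (default direction (0.35, 0.25, 1), i.e. slightly tilted overhead);
- `spot` — two point lights with inverse-square falloff and a
  per-render random intensity in [0.5, 1.5]; default positions are
  placed automatically above the scene at ±45° since nothing anatomical
  pins them.

Label images are flat and unlit; each covered pixel takes the palette
color of the face vertex with the largest barycentric weight. This
reproduces "no anti-aliasing" semantics exactly: a label image contains
only palette colors, and decoding is exact color matching (a mixed
color raises an error instead of being guessed to the nearest class).

Pose sampling is uniform in solid angle on a hemisphere cap with
elevation ≥ 15° (grazing views produce degenerate projections), camera
roll uniform in [0, 2π), hemisphere radius 2.5× the mesh bounding
radius, default image size 256² (128² in most experiments here), focal
length 1.1× the image width scaled by a perspective-jitter factor in
[0.85, 1.2]. None of these values is anatomically constrained; they are
configuration with these defaults. The sampler also accepts explicit
elevation/azimuth/roll bands to emulate a standardized acquisition
protocol (used by the training experiments, below).

## Label scheme

28 classes: 16 permanent teeth (including third molars), 10 primary
teeth, rugae, void. Void is black and absorbs gingiva *and* image
background by design — the background of a rendered view and unlabeled
mucosa are the same "not an object" class. Two colors are fixed by
convention (void `[0,0,0]`, right central incisor `[85,85,0]`); the
other 26 are assigned deterministically from the `{0,85,170,255}³`
lattice in a documented enumeration order. Only uniqueness and
stability matter; the specific values do not.

## Network

SegNet-style encoder–decoder. Encoder blocks are conv(3×3, same) + BN +
ReLU followed by 2×2 stride-2 max-pooling; the decoder mirrors them
with 2×2 stride-2 transposed convolutions + BN + ReLU and *additive*
skip connections from each encoder block's pre-pool feature map. A 3×3
conv produces per-pixel class scores normalised by softmax. Channel
attention is squeeze-excitation (global average pool → bottleneck MLP
with reduction ratio 8 → sigmoid gate); spatial attention pools the
channel axis (mean and max), convolves with a 7×7 kernel and gates each
position. The attention pair can sit at the encoder–decoder transition
(`center`) or on the final feature map before the classifier (`end`);
`none` reproduces the plain network exactly. Attention internals follow
the standard squeeze-excitation/CBAM designs; ratio and kernel size are
convention, not derived.

Two depth regimes: `encoder_layers=13` builds the full VGG-style
13-conv-layer encoder (5 pooling stages); the desk-scale default is a
4-block reduced encoder (widths 16/32/64/64, ~166k parameters) at
64–128 px inputs, which one CPU can train in minutes. The network is
implemented directly in NumPy with hand-written backward passes
(verified against finite differences in float64 and against scipy
correlation as a convolution oracle); Adam is the optimizer, loss is
unweighted per-pixel cross-entropy ("decay" is a multiplicative
per-epoch learning-rate factor). Class weighting exists as an opt-in
toggle (`class_weighted`) but is off by default. With batch size 1,
batch normalisation acts per-image (instance-like) during training and
uses running statistics in eval mode.

Data splitting is by scan, never by image: all projections of one scan
live in the same 80/10/10 split, so evaluation images always show
unseen scans.

## Baking

A vertex is visible in a view iff |projected depth − z-buffer| ≤ 1e-3 ×
the mesh bounding-box diagonal (the standard shadow-mapping test; the
tolerance absorbs the affine depth interpolation and pixel rounding).
Each visible vertex casts one vote per view for the predicted class at
its pixel; the final label is the per-vertex argmax with ties broken
toward the lowest label id (deterministic reruns). Vertices seen by no
camera fall back to void rather than inheriting a neighbour's label —
silent interpolation would hide coverage gaps; edge-propagation exists
behind a flag in `segment_components` consumers' hands, off by default.
Faces spanning two labels go to the majority label of their vertices.

## Motion estimation

Stage 0: if landmark sets are available, the two anatomical frames are
matched for rough initial positioning. The frame itself: the occlusal
plane passes through the two molar-cusp landmarks and the incisor edge;
z is its normal oriented away from the palate (decided by the raphae
points' side); the sagittal plane contains the least-squares raphae
midline and the occlusal normal; x is the planes' intersection oriented
anteriorly; y completes the right-handed frame; the origin is the
incisive papilla projected onto the occlusal plane.

Stage 1: point-to-point ICP (k-d tree correspondences, Kabsch/SVD fit
with reflection correction) on rugae vertices only; the resulting
transform moves the whole post scan. Optional trimming (drop the worst
fraction of correspondences) is available for noisy borders; default
0 — clean synthetic scans don't need it, and trimming is a robustness
knob, not a default behaviour.

Stage 2: per-tooth ICP, initialised at the centroid offset and
restarted from a fixed grid of coarse rotations (±10°, ±20° about each
axis) with the best short run refined to convergence. Point-to-point
ICP has a small capture range; without the restarts a tooth rotated
15–20° can converge to a local minimum. The restart grid is fixed, so
the procedure stays deterministic. The tooth's motion is the inverse of
its post→pre alignment, reported as a 4×4 matrix in rugae-aligned
pre-scan world coordinates and decomposed in the pre scan's anatomical
frame when landmarks are given (which makes the parameters invariant to
moving both scans rigidly — verified by an equivariance test).

### Euler decomposition sign convention

The decomposition uses β = −asin(R₃₁), γ = −atan2(R₃₂, R₃₃),
α = −atan2(R₂₁, R₁₁) on H = T·R_z(α)·R_y(β)·R_x(γ). These three
equations are exact inverses of the composition only under one
convention: rotations about x and z are clockwise-positive, the
rotation about y counterclockwise-positive. The module adopts exactly
that convention (documented once, in `motion.py`), making the round
trip exact to 1e-9 rather than matching printed formulas only up to
sign. Two-argument arctangents are used throughout because single-
argument ratios lose the quadrant when R₁₁ or R₃₃ is negative. The
|β| ≤ 90° arcsine branch is always taken — larger tooth rotations are
clinically implausible. At gimbal lock (|R₃₁| = 1) only α∓γ is
observable; γ is set to 0, the residual folded into α, and the result
flagged; reconstruction still reproduces H exactly.

## Synthetic arch generator

The generator emulates exactly the features the pipeline needs and no
more. A triangulated height field over an elliptical domain carries a
palate vault (4 mm deep), a rugae patch of 4 transverse sinusoidal
ridges (amplitude 0.5 mm) on the anterior midline, and one
superellipsoid-like bump per tooth class placed along a parabolic arch
(per-class width/depth/height presets, e.g. molars 10 mm wide and low,
incisors narrow and tall, ±5% size jitter). Each bump carries an
asymmetric cusp modulation; without it a tooth would be nearly
rotationally symmetric and per-tooth ICP would have a degenerate
optimum. Texture is pink mucosa vs whitish teeth with per-vertex noise;
the rugae share the mucosa color, so in `glow` renders they are
distinguishable only by position and in shaded renders by ridge
shadows. Defaults: 14 teeth (permanent dentition without third molars),
arch 46×48 mm, 3000 vertices, coordinates in mm.

What it does **not** emulate: real crown morphology, interdental
contacts and occlusal anatomy, gingival margins, scanner artefacts
(holes, specular dropouts), texture variation between patients, or
malocclusion. Consequently, passing tests demonstrate the geometric and
numerical correctness of the pipeline — projection/baking is lossless,
motion recovery is exact under the rigid-rugae assumption — but say
nothing about segmentation accuracy on clinical scans, which depends on
training data this package does not ship. Scanner noise
(`add_scan_noise`) and smooth mucosa deformation zeroed on the rugae
patch (`mucosa_wobble`) are available to stress the motion pipeline;
their magnitudes are plausible placeholders, not measured values.

## Experiment scales

Chosen so the full suite runs comfortably on one CPU:

- Known-transform motion verification: 14 teeth, 3000-vertex arch,
  rotations ≤ 15°, translations ≤ 3 mm; recovery tolerances 0.1° and
  0.01 mm (actual errors are ~1e-6° / 1e-14 mm).
- Baking closed loop: 100 label views at 128², majority vote, mean
  vertex IoU scored on vertices visible in ≥ 1 view.
- Dataset scale check: 100 scans × 100 views at 128² (10,000 pairs),
  1500-vertex meshes.
- Training smoke runs: 64² images rendered from a narrow anterior
  sector (elevation 55–80°, azimuth ±30°, roll ±9°, 1.7× radius —
  a standardized acquisition protocol that keeps the arch in a
  canonical orientation, appropriate for a 20-image training budget);
  2 scans × 10 views for training, an unseen scan for validation;
  reduced model, lr 1e-4, decay 0.995, batch 1, 250 epochs. Because
  synthetic scans differ only in size jitter and noise, "held-out scan"
  generalisation here is far easier than between patients; the run
  demonstrates that the architecture and training loop learn, not
  clinical-grade accuracy.

## Known limitations

- Point-to-point ICP assumes substantial shape overlap per tooth;
  motions far beyond the verified range (≫20° or beyond the restart
  grid's capture range) may converge to wrong minima.
- The depth-tolerance visibility test can leak a vote through a surface
  thinner than the tolerance (≈0.1 mm at default scales).
- Never-visible vertices become void; on closed meshes scanned from a
  hemisphere the underside is therefore all void by construction.
- The NumPy network favors reproducibility and inspectability over
  speed; the full 13-layer configuration at 256² is provided for
  completeness but is not practical to train without hours of CPU time.
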