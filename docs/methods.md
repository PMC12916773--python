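# Methods

## Design representation: RFFQM crease patterns

A transducer design is a rigidly and flat-foldable quadrilateral-mesh
(RFFQM) crease pattern on an `n × n` grid of internal degree-4 vertices
(default `n = 5`, configurable; tests use 2×2 and 3×3). The free variables
live on the L-shaped motif — the bottom row and left column of internal
vertices:

- two free sector angles per motif vertex (`2·(2n−1)` angles; 18 for
  `n = 5`), each in `(0.5°, 179.5°)`; the other two angles at each vertex
  follow from Kawasaki's condition (alternating sums equal 180°), which
  guarantees local flat foldability. A vertex whose two free angles
  coincide is rejected as degenerate: two opposite creases become
  collinear and its fold-angle transfer is singular.
- crease lengths along the bottom row and left column plus four boundary
  spokes (`2(n−1)+4` lengths; 12 for `n = 5`), in dimensionless design
  units that the area budget later maps to millimetres.

Motif vertices in odd rows are mirrored (their free pair is applied in
swapped order), so a uniform motif reproduces the classic Miura-ori with
its row-alternating zigzag exactly; `miura_reference(beta)` provides that
seed.

### Marching the interior

Every flat-foldable degree-4 vertex carries a signed fold-angle multiplier

```
mu = -sin((p + q)/2) / sin((q - p)/2),     p = theta_EN,  q = theta_NW,
```

relating the tangent half-angles of the fold angles of the vertical and
horizontal crease lines through it. Single-degree-of-freedom rigid
foldability of the whole mesh forces the multiplier field to be rank-1:
`mu[i,j] = mu[i,0]·mu[0,j] / mu[0,0]`. The interior is therefore marched
row by row: each interior vertex is placed at the intersection of the
north-going crease ray from below and the east-going ray from the left;
its panel angle `theta_WS` is then fixed by the geometry, `theta_EN`
follows from Kawasaki, and the remaining angle solves the multiplier
constraint in closed form, `tan(q/2) = tan(p/2)·(mu−1)/(mu+1)`. Any
negative ray parameter, out-of-range angle, singular multiplier or crease
intersection marks the motif infeasible; the optimizer maps that to the
finite penalty `1e6`. The transfer law and its branch were derived and
verified numerically against a brute-force spherical-linkage (rotation
closure) solver, which the test suite retains as an independent oracle.

### Boundary and mountain/valley assignment

Boundary spokes emanate from edge vertices in directions fixed by the
vertex angles; their lengths are chosen so that all endpoints lie exactly
on four axis-aligned lines forming a rectangle. Each side has one free
offset, anchored so that the motif's own spoke on that side keeps its
design length — Miura patterns are already rectangular and keep scale
factors of exactly 1, and the operation is idempotent.

Mountain/valley labels follow the Miura-class assignment: one label per
vertical crease polyline, alternating across columns; horizontal creases
alternate at every vertex (checkerboard in row+column). This is the unique
labeling (up to global reflection) for which the signed fold-angle field
closes the spherical linkage at every vertex on the folding branch
connected to Miura; Maekawa's count `|M − V| = 2` holds at every vertex.

## Rigid folding kinematics

The driving angle `rho` is the fold angle (dihedral deviation from flat)
of the south spoke of the lower-left vertex — the first crease of vertical
line 0. Because opposite creases at a flat-foldable vertex fold with equal
magnitude, each crease polyline carries one magnitude, and the rank-1
multiplier field propagates `tan(rho/2)` to every line analytically; the
whole fold-angle field is a smooth function of `rho` alone. Fold angles
stay strictly below 180°; `rho_max` (bisection on the fastest line, 0.5°
margin) bounds the admissible range.

The 3D embedding rotates panels breadth-first about shared creases
(valley = positive = moving panel lifts toward +z), anchored at the
lower-left panel. Consistency of the redundant (non-tree) creases is the
loop-closure check; the embedding additionally satisfies edge-length
preservation and panel planarity at the 1e-9 relative level, and the
signed dihedral of every crease equals its propagated fold angle.

## Global frame, scaling and constraints

Folded states are aligned so the least-squares plane of the four boundary
corners is parallel to z = 0 (normal up), the corner rectangle's long edge
runs along x (ties broken toward the anchor-panel edge) and the corner
centroid sits at the origin. One scalar `s` (mm per design unit) scales
the design so the xy-projected area at the shallowest design state
(`rho = 5°`) meets the 400 mm² budget exactly — small designs are scaled
up, large ones down; the projected area is the convex hull of the
projected vertices (a projected-facet-area sum is available as an
alternative). Four constraints are evaluated as worst cases over the
design states: dihedral ≤ 120°, all crease lengths within `(0.4, 2.0)`
design units (equivalently `(0.4 s, 2.0 s)` mm), z-extent ≤ 7 mm, corner
|z| ≤ 2 mm. Constraint violations are handled by the optimizer's extreme
barrier (+inf, never an incumbent), distinct from the finite marching
penalty.

## Acoustic forward model

Panels are subdivided into planar elements no wider than an eighth of a
wavelength (`element_cap ≤ c/(8 f_c)`, validated). The received field at a
grid point under Dirac excitation is the monopole superposition
`sum_e area_e/(2 pi r_e) · delta(t − r_e/c)` with fractional delays spread
linearly over the two bracketing samples of the `f_s` grid (a
nearest-sample mode and an optional cos θ obliquity factor exist for
sensitivity analysis). Defaults: `c = 1500 m/s`, `f_s = 50 MHz`,
`f_c = 2 MHz` — water/soft-tissue sound speed and a commercial 2 MHz piezo.
Excitation and electromechanical responses are unit-energy
Dolph-Chebyshev-windowed cosines (100 dB sidelobes); their duration
(`n_cycles = 3.7`) is set so the combined response has a −6 dB bandwidth
of 1.0 MHz, the modeled transducer bandwidth. The total impulse response
of state i is `A_i = h * h_e * h_er` (temporal convolution per pixel);
stacking the `S` states gives `A_bar` with one shared time window sized
from the farthest time of flight, and `A_tilde` normalizes columns to unit
L2 norm (all-zero columns are flagged, not normalized). Inter-facet
reflections, attenuation, dispersion and nonlinearity are not modeled.

Measurements follow `y = A_fine · x_fine + noise` with white Gaussian
noise scaled to an exact SNR in dB. Data generation and reconstruction
never share a grid: the fine (data) and coarse (reconstruction) grids
differ in pitch (80 vs 100 µm at full scale), and the two matrices are
distinct objects.

## Reconstruction

`x_hat = argmin ||A_tilde x − y_tilde||² + λ₁||x||₁ + λ₂ TV(x)` with
`y_tilde = y/||y||₂`, solved by Adam on joint random mini-batches of 1000
rows of `(A_tilde, y_tilde)` (sampled without replacement per epoch,
reshuffled, seeded), followed by clipping negatives to zero after every
step; the full-data objective is tracked every iteration and the solver
stops after 500 iterations without a relative improvement of 1e-10.
Defaults follow the design study: `λ₁ = λ₂ = 1e-4`, step size `2e-5`,
Adam `(0.9, 0.999, 1e-8)`; desk-scale tests raise the step size to `1e-3`
to `2e-3` so the small problems converge within seconds. TV is anisotropic
(forward differences, last difference omitted; subgradient zero at ties),
with an isotropic variant behind a flag; the same operator and 3D TV serve
`N³` voxel grids. The output is min-max normalized to [0, 1]. Quality
metrics: the plain Euclidean pixel-difference norm and standard SSIM
(11-point Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, data range 1),
implemented in-package and cross-checked against scikit-image in the
tests.

## Inverse design

The minimum-coherence objective is the mean squared off-diagonal Gram
entry of `A_tilde`, scaled by 100: bounded in [0, 100], 0 for orthonormal
columns, 100 for identical ones, computed blockwise so the `N²×N²` Gram
matrix is never materialized. The validation objective is the mean squared
reconstruction error over a training set of `K = 28` point-scatterer
images (1–10 points each; vessels deliberately excluded so generalization
can be probed on the test set of 4 point + 4 vessel images).

The optimizer is a hand-rolled MADS: the Miura seed is evaluated first; a
one-off Latin-hypercube SEARCH step (pool of 1e5 stratified points, a
budgeted slice actually evaluated) explores the box (angles in
`(10°, 170°)`, lengths in `(0.4, 2.0)`); poll iterations use 2D orthogonal
directions from a random Householder basis with opportunistic success,
mesh ×4 on success and ÷4 on failure, and a variable-neighborhood
perturbation step fires with probability 0.8 after failed polls.
Termination: mesh below 1e-5, the evaluation budget, or a wall-clock
budget. Evaluations are cached on the rounded design vector. The
sensitivity-field correlation (histogram, mean and variance of absolute
Pearson correlations between TIR columns) quantifies how periodic a
design's acoustic code is.

## Synthetic data

Targets are scenes — point coordinates with amplitudes, or vessel
polylines from a correlated random walk with branching — rasterized on any
grid, so the fine and coarse renderings derive from one ground truth.
Vessels are connected by construction with a foreground fraction of a few
percent; all targets are in [0, 1] with a 10% sparsity cap. The generators
emulate sparse optoacoustic absorption maps (isolated absorbers,
vessel-like structures); they do not model speckle, diffuse background
absorption, or acoustic heterogeneity, so passing tests demonstrate the
recovery mechanism on idealized sparse scenes, not clinical performance.

## Desk-scale study conditions

The full-scale studies (5×5 grid, 100×100-pixel fields of view, 1e5-point
sampling pools, ~1e6-evaluation optimizations) are too heavy for a test
run, so the package fixes two reduced conditions and uses them throughout
tests and the acceptance script:

- **Optimization toy**: 2×2 internal grid (12 design variables), 20 mm FOV
  at 1 mm pitch (20×20 pixels), four folding states {10°, 20°, 30°, 40°},
  `f_c = 0.5 MHz`, `f_s = 10 MHz`, 200-evaluation MADS runs. The frequency
  keeps the FOV about seven wavelengths wide; much coarser and the Miura
  correlation distribution collapses toward 1, erasing the
  coherence-variance contrast the design study is about.
- **Reconstruction toy**: 3×3 internal grid, `f_c = 2 MHz`,
  `f_s = 25 MHz`, 5 mm FOV with 250 µm reconstruction and 200 µm data
  pitches, four folding states. The reconstruction pixel must stay well
  below the wavelength (as in the full-scale 100 µm ≈ λ/7.5 setting):
  with pixels of order λ the sub-pixel offset between the two
  inverse-crime grids shifts arrivals by most of a period and even the
  exact minimizer ghosts. The fixed reference transducer is a
  decorrelated feasible design (a seeded ±8° asymmetric deformation of
  the Miura motif); Miura itself reconstructs poorly — its periodic
  sensitivity field produces mirror ghosts, which is precisely the
  motivation for coherence-based design.

## Known limitations

- The marching construction covers the Miura-connected branch of the
  RFFQM class; other mountain/valley classes and branch choices are out
  of scope.
- The acoustic model is a far-field monopole superposition without
  inter-facet reflections or shadowing; strongly folded states are
  therefore modeled optimistically.
- The MADS implementation is a compact re-creation (no surrogate models,
  no parallel evaluation) intended for desk-scale budgets.
- Reported desk-scale quantities are not comparable in magnitude to
  full-scale studies; only the qualitative relations (coherence reduction,
  correlation-variance reduction, noise monotonicity, imperfection
  insensitivity) transfer.
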