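# Methods

`mpilocate` simulates source localization for a planar-scanning magnetic
particle imaging (MPI) system: magnetic-nanoparticle (MNP) sources inside a
voxelized calculation volume are magnetized by a z-directed excitation
field, the induced dipole fields are sampled by a rectangular XY sensor
array above the volume, and the source distribution is reconstructed from
those readings by an L1 (basis-pursuit) inverse solver. The package's
purpose is to study how the excitation field design — constant bias versus
a per-layer gradient ("multiple Z scan") — changes localization accuracy
with source depth.

## Forward model

Each in-mask voxel k at position r_P,k carries a dipole moment

    m_k = kappa · B(z_k) · ẑ,        B(z) = g·z + b,

i.e. a constant-susceptibility (linear) response to the local applied
field. Physically the MNP magnetization follows the Langevin law, which is
linear with slope 1/3 at small fields; that slope, the particle volume and
the susceptibility are folded into the single coupling constant `kappa`
(default 1, arbitrary units), because every reported metric — location
error, average deviation, local-maxima counts — is invariant to the global
scale of the system. The solver's two tunable scales (μ, δ) are defined
relative to the data (see below), so this choice is consequence-free.

A sensor at r_S,j with unit direction n_S reads the dipole-field
projection

    A[j,k] = (μ0/4π) · (3 (m_k·d̂) d̂ − m_k) / ‖d‖³ · n_S,
    d = r_S,j − r_P,k,

assembled densely over all sensor/voxel pairs. Interfaces use cm and mT;
geometry converts to metres internally with μ0/4π = 1e−7 T·m/A. The sensor
direction is +ẑ (the plane normal): for planar XY scanning above the
object the normal component is the natural measurand; the source text of
the system being modeled does not state it. Readings are noise-free by
assumption (`noisy_field_map` exists as an exploratory hook only). Dense
storage is guarded by a configurable entry budget (warning above 2^28
entries); the studies here run on coarsened grids well below it.

## Geometry conventions

Grids are node-inclusive: a 6.0 cm extent at 0.1 cm spacing has 61 nodes
per axis, so printed coordinates such as [1.5, 1.8, 1.0] fall exactly on
nodes. Coordinates are physical cm, origin at the volume's minimum corner,
with linear voxel ordering x-fastest, then y, then z (ties in any argmax
break to the lowest linear index). Sensor planes are concentric with the
volume footprint. The anatomical (mouse-brain) calculation volume of the
original study is not reproducible — its MRI-derived mask was never
published — so the package provides an ellipsoidal stand-in (default
bounding box 5 × 4 × 1.5 cm, semi-axes bbox/2): results on it are trend
statements only, never absolute comparisons.

## Inverse solver

The reconstruction solves min ‖u‖₁ s.t. Au = f with u ≥ 0 by the
linearized Bregman iteration

    v ← v + Aᵀ(f − A u),    u ← δ·shrink(v, μ),    u ← max(u, 0),

from u = v = 0, where shrink is the soft threshold (dead zone |v| ≤ μ,
outer branches δ(v∓μ)). Positivity is enforced by projection inside the
iteration; particle concentrations are nonnegative. Defaults:

* δ = 1/σ_max(A)², with σ_max estimated by 100 power iterations from a
  fixed all-ones start (bit-reproducible). This is the standard stable
  step for the linearized iteration.
* μ = 0.05 · max|Aᵀf|. Relative to the data scale, which makes the whole
  solution path invariant to joint rescaling of A and f.
* Stopping: |res_k − res_{k−1}| < tol (default 1e−6), res = ‖f−Au‖/‖f‖,
  with two guards discovered during implementation: the test is skipped
  while the iterate has not moved (early on, every component of v can sit
  in the dead zone, freezing the residual at 1 with zero change), and an
  optional `min_iter` floor rides out transient plateaus (with large μ
  the residual decays geometrically onto a plateau between support
  changes, and the plain rule quits there). Hitting `max_iter` (default
  100 000) returns `converged=False` with the iterate, not an exception.

Two operating regimes matter. With the small default μ the limit problem
is ‖u‖₁ + ‖u‖₂²/(2μδ) with a dominant ℓ2 term — minimum-norm-like,
smooth, fast, and the regime in which all simulation studies here run.
With μ large (exact-regularization regime, μδ ≳ 10·‖u‖∞) the iteration
converges to the true basis-pursuit solution — this is verified directly
against scipy's LP solver on small random instances — but convergence is
orders of magnitude slower and the stall rule needs the `min_iter` guard.
The LP comparisons screen instances to those where the LP recovers the
planted support, since the equivalence presumes a unique basis-pursuit
optimum; near-degenerate draws test tie-breaking, not the solver.

The non-linearized Bregman scheme (full subproblem minimization per step,
with the Bregman distance D_J^P(u,v) = J(u) − J(v) − ⟨P, u−v⟩) is
documented in `bregman.py` for reference; the linearized variant is the
one exercised.

## Gradient scan ("multiple Z scan")

Under a constant field the lead field decays monotonically with depth, so
deep sources are reconstructed poorly. The on-axis response of a voxel at
height z to a sensor at height z_s is

    R(z) ∝ (g·z + b) / (z_s − z)³,

and setting dR/dz = 0 at a chosen layer height z_t gives the closed form

    g = −3b / (z_s + 2·z_t),

derived in the on-axis approximation (sensor directly above the voxel);
off-axis sensors inherit the same g, which is what makes "one gradient per
layer" possible. For layers in the lower part of the volume the applied
field changes sign inside the volume (zero crossing at (z_s + 2 z_t)/3) —
the extremum is created by the sign change, not by magnitude. Layer
heights are evenly spaced from the volume top to z = 0:
z_L = (n−L)·H/(n−1), L = 1..n. The multiple Z scan stacks the per-layer
lead fields row-wise into one system; the constant-field "multiple scan"
analogously stacks planes at several heights with g = 0. Stationarity of
the signed response is used without a second-derivative filter; in the
on-axis form the signed and magnitude readings give the same g.

## Metrics

Average deviation = Σ|D_inv − D_ori|/N over the N in-mask voxels, with
both distributions max-normalized first (amplitudes are arbitrary-scale;
normalization makes the number comparable across configurations).
Location error = ‖argmax(D_ori) − argmax(D_inv)‖₂ in cm. Display
thresholds (fractions 0.3 / 0.15 / 0.5 of the maximum) apply to figures
and local-maxima search only, never before metric computation.
Local maxima are voxels ≥ all 26-connected in-mask neighbours and
≥ t·max, with equal-valued plateaus coalesced to their lowest-linear-index
voxel — an explicit definition chosen so that multi-source
distinguishability is testable.

## Study configurations and problem sizes

All bundled studies run on coarsened grids chosen so a full reproduction
(tests plus acceptance script) completes in minutes on one CPU:

* **Plane sweep** (constant field): ellipsoid stand-in at 0.25 cm spacing
  (979 voxels), 6 × 5 cm planes at 0.5 cm interval (143 sensors), heights
  2.5–6.0 cm, bias 0.5 mT, Gaussian source at [1.5, 1.8, 1.0] with
  σ = 0.1 cm. Checks: deviation non-decreasing with plane height; the
  stacked multiple scan within 10 % of the closest plane.
* **Depth comparison**: same stand-in, plane fixed at 2.5 cm, five layers.
  Because the original anatomical mask is unpublished, the paper-style
  off-axis source line does not fit inside the ellipsoid; sources sit on
  the stand-in's vertical axis at z = 1.25 / 0.75 / 0.25 cm
  (shallow/middle/deep), σ = 0.1 cm. Check: multiple-Z-scan location
  error ≤ constant-field location error at depth.
* **Single-source recovery**: 6 × 6 × 5 cm cuboid at 0.5 cm spacing
  (1859 voxels), 8 × 8 cm plane at 0.5 cm interval (289 sensors) at
  height 6 cm, source σ = 0.3 cm at the top-layer node [3, 3, 5]. The
  argmax must land on the true node. The source sits in the top layer
  deliberately: at this sensor density the exact basis-pursuit solution
  itself is surface-biased for interior depths (verified with the LP
  oracle — argmax at z = 5 even for true z = 4), so exact constant-field
  argmax recovery is only attainable near the sensors. That is precisely
  the limitation the gradient scan exists to address, and matches the
  observation that a constant field localizes well only close to the
  sensor plane.
* **Multisource separation**: same cuboid, ten layers, three σ = 0.1 cm
  sources at [1,1,2], [3,3,3], [5,5,4]. Check: exactly three local maxima
  at threshold 0.15 under the multiple Z scan (they land on the exact
  true nodes); the constant field's count is recorded alongside (it
  scatters into more).

The gradient-scan configurations tighten the solver to tol 1e−8 with a
30 000-iteration cap: stacked multi-layer systems converge more slowly
and the 1e−6 stall rule quits on a plateau there (at 1e−6 only two of the
three multisource maxima have emerged). Constant-field configurations
keep the 1e−6 default. With these settings every reconstruction in the
bundled studies is deterministic — there is no randomness anywhere in the
default pipeline.

## What the synthetic scenes do and do not emulate

The generator reproduces the study conditions: voxelized homogeneous
volumes, Gaussian concentration profiles, regular planar sensor arrays,
ideal z-directed excitation, and noise-free readings. It does not emulate
sensor noise (set to zero by assumption), Langevin saturation at large
fields (linear response only), coil-field inhomogeneity, frequency-domain
MPI physics, or anatomical geometry. Passing tests therefore demonstrate
correctness of the forward/inverse machinery and the depth-encoding
mechanism under idealized conditions — not performance on measured data.

## Numerical choices and degenerate inputs

Degenerate inputs are rejected with explanatory errors: non-divisible
grid extents, sources outside the volume, sensors coincident with voxels,
zero bias in the gradient design (no finite gradient yields an interior
stationary point), layers above the sensor plane, all-zero field maps in
the residual (an all-zero field map short-circuits to u = 0). NaN/Inf in
the iteration aborts with the iteration index. Comparisons between the
vectorized lead field and the brute-force dipole transcription are
relative (1e−12) on entries ≥ 1e−3 of the matrix scale and absolute
(≤ 1e−13 of scale) on near-cancelling entries, where a relative
comparison is meaningless.

## Known limitations

* The solver's small-μ default yields minimum-norm-flavoured solutions;
  exact basis-pursuit behavior requires a larger μ and far more
  iterations. The studies' conclusions (depth trends, separation) live in
  the small-μ regime.
* The stall stopping rule is a heuristic; on stacked systems it can stop
  on plateaus (hence the per-study tol/max_iter settings).
* The ellipsoid stand-in is not anatomy; its numbers are trends.
* Absolute field values in tesla are arbitrary up to the coupling scale
  `kappa`; only scale-free quantities should be compared.
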