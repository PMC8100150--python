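# mpilocate

Source localization for planar-scanning magnetic particle imaging (MPI),
in simulation: a dipole lead-field forward model, an L1 (basis-pursuit)
inverse solver based on the linearized Bregman iteration, and a
gradient-field depth-encoding scheme — the **multiple Z scan** — that
improves localization of magnetic-nanoparticle (MNP) sources far from the
sensors.

## The problem

An MPI system magnetizes MNP tracers with an applied field and senses the
induced dipole fields on an XY scanning plane above the object. Writing
the voxelized tracer distribution as u and the sensor readings as f, the
detection is linear,

    f = A u,        A[j,k] = (μ0/4π) (3 (m_k·d̂) d̂ − m_k)/‖d‖³ · n_S,

with d = r_S,j − r_P,k and a constant-susceptibility moment
m_k = κ·B(z_k)·ẑ responding to the z-directed excitation B(z) = g·z + b.
Recovering u from f is ill-posed; the solver computes

    min ‖u‖₁  s.t.  A u = f,  u ≥ 0

by the linearized Bregman iteration (v ← v + Aᵀ(f − Au),
u ← δ·shrink(v, μ), positivity projection).

With a constant field (g = 0) the lead field decays as the inverse cube
of sensor–voxel distance, so reconstructions are biased toward the
sensors and deep sources localize poorly. The multiple Z scan instead
solves, for each of n depth layers, the gradient that places the on-axis
lead-field extremum at that layer,

    g_L = −3b / (z_s + 2 z_L),

and stacks the n lead fields into one system, so every depth is
preferentially weighted by some block. Localization quality is scored by
the **location error** ‖argmax(D_ori) − argmax(D_inv)‖₂ (cm) and the
**average deviation** Σ|D_inv − D_ori|/N on max-normalized distributions.

## Worked example

Constant field versus multiple Z scan for three source depths inside an
ellipsoidal volume (an anatomical stand-in), sensors 0.5 cm apart on a
6 × 5 cm plane at height 2.5 cm:

```python
from mpilocate import make_brain_stand_in, run_gradient_scan_experiment

grid = make_brain_stand_in([5.0, 4.0, 1.5], spacing=0.25)
table, maxima = run_gradient_scan_experiment(
    grid,
    centers=[[2.5, 2.0, 1.25], [2.5, 2.0, 0.75], [2.5, 2.0, 0.25]],
    sigma=0.1, plane_extent=[6, 5], interval=0.5, sensor_z=2.5,
    n_layers=5, bias=0.5, threshold=0.3,
    solver={"tol": 1e-8, "max_iter": 30000})
print(table[["method", "scan", "location_error", "average_deviation"]]
      .to_string(index=False))
```

```
         method          scan  location_error  average_deviation
 constant field [2.5 2.  1.2]        0.250000           0.005254
 constant field [2.5 2.  0.8]        0.750000           0.071316
 constant field [2.5 2.  0.2]        2.165064           0.204045
multiple Z scan [2.5 2.  1.2]        0.000000           0.002078
multiple Z scan [2.5 2.  0.8]        0.000000           0.004065
multiple Z scan [2.5 2.  0.2]        0.000000           0.007910
```

The constant field localizes the shallow source to within one voxel
(0.25 cm) but drifts by 2.2 cm for the deepest source, while the
gradient-field multiple Z scan pins all three depths exactly — the
depth-encoding at work. The same machinery is available piecewise
(`build_lead_field`, `multiple_z_scan_lead_field`,
`SourceLocalization(...).fit()` returning a results object with residual
history and a `summary()`), and from the command line:

```bash
mpilocate plan --layers 10 --bias 0.5 --sensor-z 6 --bem-height 5
mpilocate reproduce --which multisource --out results/multisource
```

See `docs/methods.md` for the model assumptions, solver parameters
(μ, δ, stopping rule) and the limitations of the synthetic scenes.

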