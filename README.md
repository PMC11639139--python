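# gridcalib

Grid cells in the rodent medial entorhinal cortex fire on a hexagonal
lattice of locations — but the lattice is not immutable: squeezing a
familiar square cage into a rectangle compresses the grid along the same
axis, and trapezoidal cages shear it and bend its orientation and
wavelength from the wide to the narrow end. `gridcalib` implements a
circuit-level explanation of these *grid distortions*: a continuous
attractor network (CAN) of grid cells, driven by velocity for path
integration, receives a Hebbian calibration input from place cells that
are themselves conjunctions of *wall distance cells* (simplified boundary
vector / border cells). Trained in a square cage, the calibration anchors
the grid to the boundaries; transferred to a deformed cage, the same
anchoring reproduces the observed distortions. The package is aimed at
computational neuroscientists who want to re-run, probe or extend these
experiments without a robotics stack: all inputs are synthetic (polygonal
cages and seeded correlated-random-walk trajectories).

## The model in brief

Every population obeys the same rate dynamics

```
tau ds/dt + s = max(w·s + B + 1, 0)
```

- **WDCs** — two vectors of `n` neurons encode distances to two reference
  walls; peak placements follow either a uniform rule `p_i = l·i/n` or a
  recursive rule realizing a density profile `f(x) = exp(2 ln(0.1) x)`
  (denser near the wall), with spans scaled to fixed cage extents
  (option ii) or to the local width through the agent (option i).
- **PCs** — the AND conjunction of one x- and one y-vector WDC; the
  disinhibition gate's steady state is `max(i1 + i2 − 1, 0)`.
- **GCs** — an `n×n` twisted-torus CAN with center-surround connectivity
  and four preferred-direction subpopulations; velocity input translates
  the bump lattice (path integration).
- **Calibration** — Hebbian weights `dw/dt = (α − w)/τ` for positive
  coactivation `α = s_i·r_j/r_max − 0.05`, feeding `b_j = k Σ_i w_ij s_i`
  back to the grid module.
- **Velocity transform** — for linear cage deformations the matrix
  `D = [[s_x sinψ, −s_x cosψ], [−s_y sinφ, s_y cosφ]]` remaps true to
  agent-frame velocity so path integration and calibration agree.

Distortions are quantified on time-accumulated rate maps via the spatial
autocorrelogram: ellipticity of the inner-peak ellipse, grid orientation,
Fourier mean wavelength, and mean nearest-peak distance; stability via
firing-profile MSE against the neuron-sheet pattern and the per-location
firing variance VAR. See `docs/methods.md` for assumptions, parameters and
limitations.

## Worked example

Train the calibration circuit in a 30-unit square and transfer the agent
to the default isosceles trapezoid (tall side 30, short side 10):

```python
from gridcalib import builtin_scenarios, run_test, run_training, scaled

cfg = scaled(builtin_scenarios()["trapezoid_linear"],
             n_train=350_000, n_test=400_000)
trained = run_training(cfg)
print(trained.train_result.metrics())
test = run_test(cfg, trained)
print(test.metrics())
```

prints (a few minutes per phase on one CPU; metrics are medians over six
recorded grid cells):

```
GridMetrics(ellipticity=0.5385456402480471, orientation_deg=-0.20443438808374736,
            mean_wavelength=4.009591060649248, mean_nearest_peak_distance=4.401111247941987)
GridMetrics(ellipticity=0.7438759816269147, orientation_deg=23.721041915297107,
            mean_wavelength=4.0715572973813945, mean_nearest_peak_distance=5.4285872933813675)
```

The square-trained grid is the attractor's intrinsic lattice (a hexagonal
grid compressed by √3/2 along one axis — ellipticity ~0.54, axis aligned
with the cage). In the trapezoid the velocity transform is the pure shear
`D = [[1, 0], [−1/3, 1]]`: the measured ellipticity rises to ~0.74 and the
near-horizontal axis rotates by ~24°, the linear distortion seen when
animals move from square to trapezoidal enclosures.

The same workflow is scriptable from a shell:

```
gridcalib run --scenario trapezoid_linear --seed 0 --scale ci --out out/
gridcalib analyze --ratemap out/test_rate_map.tsv --half left:0,15.9 --half right:10.5,25.5
gridcalib validate-wdc --density exponential --n 130
```

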