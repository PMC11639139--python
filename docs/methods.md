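# Methods

`gridcalib` simulates a boundary-driven calibration circuit for grid cells
and the analysis used to study grid distortions in deformed cages. This
note records the model, the numerical choices, and what the synthetic
setting does and does not establish.

## Model overview

Four rate-coded populations interact at a fixed step `dt = 0.01 s`:

1. **Wall distance cells (WDCs).** Two vectors of `n` neurons encode the
   perpendicular distances to two reference walls that meet at the origin.
   Each neuron has a preferred distance (*peak*); its rate relaxes toward 1
   when the current distance falls in its activation region and toward 0
   otherwise, with `tau = 50 ms`. Peaks are placed uniformly (`p_i =
   l·i/n`) or by a recursive rule realizing a target density `f(x) = c1·
   exp(c2·x)` on the normalized distance; the default exponential profile
   satisfies `f(0) = 1`, `f(0.5) = 0.1`, mirroring the denser packing of
   boundary-tuned cells at short range. Spans scale either with the fixed
   wall-to-wall extents (option ii) or with the local cage width through
   the agent's position (option i), in which case peak loci bend toward the
   narrow end of a tapering cage. The recursion freezes the density at each
   interval's left end; the mean relative deviation between realized
   (reciprocal-spacing) and target density quantifies that approximation
   (~1.3% for 130 cells with the exponential profile).

2. **Place cells (PCs).** Every pair of one x-vector and one y-vector WDC
   feeds an AND gate; the steady state of the 8-neuron disinhibition
   circuit is `max(i1 + i2 - 1, 0)`, and all experiments use that closed
   form (the circuit itself is simulated in tests and matches within 0.02
   over the unit square).

3. **Grid-cell attractor.** An `n_g x n_g` sheet of rate neurons
   (`tau = 100 ms`, update `tau ds/dt + s = max(w s + B + 1, 0)`) on a
   twisted torus `(x, y) ~ (x+1, y) ~ (x+1/2, y+1)`, with an isotropic
   difference-of-Gaussians surround kernel and four interleaved
   preferred-direction subpopulations whose outgoing weights are shifted
   one neuron along their direction. Velocity enters additively as
   `B_v = gain * (e_i . v)`. The commensurate bump lattice on this torus is
   a triangular lattice stretched 2/sqrt(3) along the sheet y-axis, so the
   spatial autocorrelogram of a single cell has eccentricity 0.5 rather
   than 0 — matching the distinctly elliptical "undistorted" grids this
   model family produces in a square cage. The module is seeded on that
   lattice and settled with zero input, which makes the initial grid
   orientation and phase deterministic.

4. **Hebbian calibration.** Coactivation `alpha_ij = s_i r_j / r_max -
   0.05` drives PC→GC weights toward `alpha` where positive with
   `tau = 10 ms` (equal to the step, i.e. an exact jump); the calibration
   input is `b_j = k * sum_i w_ij s_i` with `k = 0.05` by default and
   `k = 3` when the velocity transform cannot express a distortion.

A hard-coded linear map `D` converts true velocity to agent-frame velocity
when the test cage is a linear deformation of the training square (valid
for option ii with constant density); `g = h` as linear maps, and the map
sends every PC's test-cage peak to its training-cage peak. Each scale
factor is the training/test ratio of the extent that governs that
coordinate's peak placement; a `literal_eq15` switch restores the
published pairing of subscripts, which breaks the round-trip property.

## Numerical choices

- **Kernel constants** (free parameters of the attractor family): bump
  period `lam = n_g / 4` neurons, `beta = 5.33 / lam^2`, `gamma = 1.05
  beta`, amplitude 12, direction shift 1 neuron. Chosen so that (a) the
  seeded lattice is the stable pattern, (b) the velocity response is
  linear within ~5% over the speed band the agent uses. `n_g = 40`
  (period 10) is the single simulation profile; coarser sheets pin the
  lattice and distort the velocity response.
- **Matrix-free connectivity.** The recurrent operator is applied as FFT
  convolutions on the plain-torus double cover (second copy of the sheet
  shifted by `n_g/2` rows); it agrees with the explicitly constructed
  weight matrix to 5e-6 and avoids streaming an `n_g^4` matrix every step.
- **Gain calibration.** The per-axis path-integration gain is measured at
  a small probe drive and refined once, targeting one bump-lattice period
  of sheet drift per grid spacing (default 5.3 length units) travelled.
- **Activity stabilization.** The purely additive rate equation has no
  bounded response to strong localized input. When the population mean
  exceeds 1.2x its input-free level the rates are rescaled divisively —
  the same stabilization the classic attractor implementations apply.
  It never engages in velocity-only operation.
- **Calibration-input normalization.** The calibration sum is capped at a
  reference input mass of 2 (divisive normalization): dense radius-mode
  configurations with hundreds of co-active PCs then vote with their mean
  rather than a population-size-dependent sum. Sparse nearest-mode
  configurations stay below the cap and are unaffected. Without this the
  summed drive reaches ~10x the network baseline and destroys the lattice
  during training.
- **Rate maps.** Square bins (0.75 units by default, 0.5 at full scale)
  over the cage bounding box; the first 20% of each phase is excluded from
  accumulation (pre-anchoring transient). Six grid cells at distinct sheet
  phases are recorded per run; reported metrics are per-metric medians over
  the cells (all cells see the same lattice, so this only reduces
  estimator variance). Autocorrelograms are Pearson
  -normalized per displacement with a minimum overlap of 20 bins.
- **Metrics.** Ellipticity: least-squares centered conic through the six
  inner autocorrelogram peaks (sub-bin refined), eccentricity of that
  ellipse. Orientation: angle of the inner peak folded nearest the
  horizontal. Mean wavelength: amplitude-weighted mean reciprocal
  frequency of the Hann-windowed DFT of the square-cropped autocorrelogram
  (without the window, leakage weighted by the diverging 1/f factor biases
  the estimate by 5–20%); the DC term is excluded. VAR: the cage bounding
  box is divided into square segments (200^2 at full scale, coarser for
  short runs so each segment collects several visits); the rate is sampled
  once per segment *encounter* and the population variance per segment is
  averaged over segments with at least two encounters. Profiles: mean
  firing in 50 bins of relative distance (distance to the nearest peak
  divided by the mean neighboring-peak distance) over [0, 1.5]; the sheet
  profile averages over periodic-sheet snapshots.

## Synthetic trajectories and odometry error

The agent is a correlated random walk (heading diffusion 2.5 rad/sqrt(s),
speed a clipped Gaussian around 2.2 units/s within [1.2, 3.2]) with
reflective walls, replacing a robot simulation. The narrow speed band is
deliberate: it keeps the attractor's velocity drive inside its linear
range, and covers a 20-unit cage's 20x20 occupancy grid comfortably within
5e5 steps. Real rodent or robot motion has pauses, accelerations and
heading biases that this walk does not reproduce; conclusions about
coverage-dependent statistics therefore transfer only qualitatively.

Path-integration error, which the calibration circuit exists to correct,
is modelled as an Ornstein–Uhlenbeck velocity error (default sd 0.1
units/s, correlation time 5 s) added to the velocity *input* only — true
positions are unaffected. White per-step noise would be averaged away by
the 100 ms membrane time constant; slowly varying bias is what makes
uncorrected integration drift, as with real odometry. In the stability
scenario the calibrated and uncalibrated runs share the identical
trajectory and noise realization.

## Scaled-down regime

Full-scale runs (3.2e6–5e6 steps) reproduce the published protocol
lengths; the test suite and the acceptance script run 0.35–0.4e6-step
phases, at which the accumulated field geometry is close to, but
measurably noisier than, its long-run limit (the training-square
ellipticity approaches ~0.55 from above as accumulation grows). Per-half
statistics on restricted maps carry the largest estimator noise
(orientation ±1–2 degrees, wavelength ±0.1). The stability comparison is
run where its statistics discriminate: drift must blur the uncalibrated
field without erasing it (a fully washed field is flat and shows *low*
per-place variance), and the calibrated arm's own correction jitter sets
a floor that weak drift cannot beat.

## Known limitations

- The calibration anchoring at `k = 0.05` is weak relative to this
  attractor's stiffness: its phase-correction rate is a few thousandths of
  a length unit per second, so odometry error beyond ~0.02 units/s leaves
  residual jitter comparable to the drift it corrects at compact run
  lengths.
- WDC rates decay with a 50 ms constant after the agent leaves a field, so
  a trailing tail of place cells stays active; with dense radius-mode
  populations this smears the calibration drive along the path.
- The analytic AND shortcut ignores gate transients (the circuit lags a
  step input by roughly 10 membrane time constants).
- Only two reference walls drive the WDCs; cages are convex polygons with
  those walls meeting at the origin.
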