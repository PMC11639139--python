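"""Scenario runner: training and test phases of the calibration experiments.

A scenario trains the PC -> GC calibration weights in a square cage and
then lets the agent traverse a test cage with frozen weights, recording one
grid cell's firing over space.  The per-step loop is: wall distances ->
WDC relaxation -> analytic AND map -> Hebbian step (training only) ->
calibration drive -> (transformed) velocity drive -> one grid-attractor
Euler step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .environment import Environment, make_environment
from .grid import GridModule, make_grid_module, step_grid, velocity_to_input
from .plasticity import (
    ALPHA_TH_DEFAULT,
    CalibrationWeights,
    fused_calibration_step,
)
from .trajectory import Trajectory, simulate_trajectory
from .velocity_transform import TransformSpec, build_transform
from .wdc import DensitySpec, PeakTable, WDCVector, wdc_step

log = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    name: str
    train_env: tuple
    test_env: tuple | None
    n_wdc: int = 15
    density_kind: str = "constant"
    option: str = "ii"
    activation: str = "nearest"
    activation_r: float = 1.0
    k_train: float = 0.05
    k_test: float = 0.05
    dt: float = 0.01
    n_train: int = 3_200_000
    n_test: int = 3_200_000
    seed: int = 0
    calibration: bool = True
    velocity_transform: str = "auto"  # auto | identity | literal_eq15
    n_g: int = 40
    k_bumps: int = 4
    spacing: float = 5.3
    bin_size: float = 0.75
    #: odometry error fed to the grid module (true positions unaffected):
    #: an Ornstein-Uhlenbeck velocity error with stationary sd (units/s)
    #: and correlation time (s).  White noise would be averaged away by the
    #: 100 ms membrane time constant; slowly varying bias is what makes
    #: uncorrected path integration drift, as with a real robot's odometry.
    odometry_noise_sd: float = 0.0
    odometry_noise_tau: float = 5.0
    motion: dict = field(default_factory=dict)
    snapshot_every: int = 0
    map_burnin_frac: float = 0.2
    #: record the tracked cell's rate relative to the population maximum;
    #: removes the global-activity modulation that dense calibration drive
    #: imprints on raw rates
    track_normalized: bool = False
    stabilize_gate: float = 1.2
    #: divisive normalization of the calibration drive: the summed PC input
    #: is rescaled to at most this reference mass, so dense-place-cell
    #: configurations vote with their mean rather than their (population-
    #: size-dependent) sum.  Sparse nearest-activation configurations never
    #: exceed the reference and are unaffected.
    pc_input_mass: float = 2.0
    #: number of grid cells whose firing is recorded (cells at distinct
    #: sheet phases are statistically equivalent, so per-cell metrics can
    #: be aggregated to cut estimator variance)
    track_cells: int = 6

    def density(self) -> DensitySpec:
        return DensitySpec(self.density_kind)

    def make_train_env(self) -> Environment:
        return make_environment(*self.train_env)

    def make_test_env(self) -> Environment:
        return make_environment(*(self.test_env or self.train_env))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["train_env"] = tuple(d["train_env"])
        if d.get("test_env"):
            d["test_env"] = tuple(d["test_env"])
        return cls(**d)

    def manifest(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass
class PhaseResult:
    positions: np.ndarray
    firing: np.ndarray          # first tracked cell's rate per step
    rate_map: analysis.RateMap  # first tracked cell's map
    sheet_snapshots: list
    gm: GridModule
    weights: CalibrationWeights
    env: Environment
    firing_all: np.ndarray = None   # (k, n_steps) all tracked cells
    rate_maps: list = None          # one RateMap per tracked cell

    def metrics(self, **kwargs) -> analysis.GridMetrics:
        """Median grid metrics over the tracked cells.

        Every grid cell sees the same lattice at a different phase, so the
        per-cell metrics estimate the same quantities; the median discards
        cells whose map happens to defeat the peak detection.  Cells whose
        metrics are undefined are skipped (at least one must survive).
        """
        return aggregate_metrics(self.rate_maps, **kwargs)


def aggregate_metrics(rate_maps, restrict=None) -> analysis.GridMetrics:
    """Per-metric medians: each statistic uses every cell where it is
    defined (an ellipse fit failing on one cell's map does not discard
    that cell's wavelength estimate)."""
    pools: dict[str, list] = {
        "ellipticity": [], "orientation_deg": [],
        "mean_wavelength": [], "mean_nearest_peak_distance": [],
    }
    for rm in rate_maps:
        if restrict is not None:
            rm = rm.restrict_x(*restrict)
        try:
            ac = analysis.autocorrelogram(rm)
        except ValueError as err:
            log.info("cell autocorrelogram skipped: %s", err)
            continue
        try:
            pools["mean_wavelength"].append(analysis.mean_wavelength(ac))
        except ValueError as err:
            log.info("cell wavelength skipped: %s", err)
        try:
            ring = analysis.inner_peaks(analysis.autocorr_peaks(ac), 6)
            pools["ellipticity"].append(analysis.ellipticity(ring))
            pools["orientation_deg"].append(analysis.orientation(ring))
        except (ValueError, IndexError) as err:
            log.info("cell ellipse/orientation skipped: %s", err)
        try:
            v = rm.smoothed(1.0)
            fp = analysis.detect_peaks(
                v, dx=rm.dx, dy=rm.dy, smoothing=0.0, min_separation=2.0,
                threshold=0.3 * np.nanmax(v),
                origin=(rm.x_centers[0], rm.y_centers[0]),
            )
            pools["mean_nearest_peak_distance"].append(
                analysis.mean_nearest_peak_distance(fp)
            )
        except (ValueError, IndexError) as err:
            log.info("cell peak distance skipped: %s", err)
    if not any(pools.values()):
        raise ValueError("no tracked cell yielded defined grid metrics")
    med = {
        f: float(np.median(v)) if v else float("nan")
        for f, v in pools.items()
    }
    return analysis.GridMetrics(**med)


@dataclass
class TrainedState:
    config: ScenarioConfig
    gm: GridModule
    weights: CalibrationWeights
    train_result: PhaseResult


def _phase_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def _span_arrays(env: Environment, pos: np.ndarray, option: str):
    """Per-step spans (l_x, l_y) for the whole trajectory, vectorized."""
    n = len(pos)
    if option == "ii":
        return (np.full(n, env.lx_max), np.full(n, env.ly_max))
    spans = []
    for wall in ("x", "y"):
        a = env.wall_angle(wall)
        u = np.array([np.cos(a), np.sin(a)])
        d_near = np.abs(pos[:, 0] * u[1] - pos[:, 1] * u[0])
        q, w = env.opposing_wall_line(wall)
        rel = pos - q
        d_far = np.abs(rel[:, 0] * w[1] - rel[:, 1] * w[0])
        spans.append(d_near + d_far)
    return spans[0], spans[1]


def run_phase(
    cfg: ScenarioConfig,
    env: Environment,
    gm: GridModule,
    weights: CalibrationWeights,
    n_steps: int,
    seed_salt: int,
    learn: bool,
    k: float,
    transform: TransformSpec | None = None,
    track_cell: int | None = None,
) -> PhaseResult:
    """Simulate one traversal phase and accumulate the tracked cell's map."""
    dt = cfg.dt
    traj = simulate_trajectory(
        env, n_steps + 1, dt=dt, motion=cfg.motion,
        seed=_phase_seed(cfg.seed, seed_salt),
    )
    pos = traj.positions
    vel = traj.velocities
    d_x, d_y = env.signed_wall_coords(pos[:, 0], pos[:, 1])
    lx, ly = _span_arrays(env, pos, cfg.option)

    if cfg.odometry_noise_sd > 0:
        rng = np.random.default_rng(_phase_seed(cfg.seed, seed_salt + 7))
        a = dt / cfg.odometry_noise_tau
        kick = cfg.odometry_noise_sd * np.sqrt(2.0 * a)
        err = np.empty_like(vel)
        e = rng.normal(0.0, cfg.odometry_noise_sd, size=2)
        for t in range(len(vel)):
            e = e * (1.0 - a) + kick * rng.normal(size=2)
            err[t] = e
        vel = vel + err
    if transform is not None:
        vel = vel @ transform.D.T

    density = cfg.density()
    # x-vector peaks scale with the wall_y extent (l_y), y-vector with l_x
    table_x = PeakTable(density, cfg.n_wdc, env.ly_max,
                        l_min=float(ly.min()) if cfg.option == "i" else None)
    table_y = PeakTable(density, cfg.n_wdc, env.lx_max,
                        l_min=float(lx.min()) if cfg.option == "i" else None)
    xv = WDCVector(axis="x", peaks=table_x(env.ly_max),
                   activation=cfg.activation, r=cfg.activation_r)
    yv = WDCVector(axis="y", peaks=table_y(env.lx_max),
                   activation=cfg.activation, r=cfg.activation_r)
    scales = cfg.option == "i"
    learn_factor = min(dt / weights.tau, 1.0)

    weights.k = k
    gm.stabilize_gate = cfg.stabilize_gate
    normalized = cfg.track_normalized
    if track_cell is None:
        n4 = gm.n_g // 4
        anchors = [(2 * n4, 2 * n4), (n4, n4), (3 * n4, n4), (n4, 3 * n4),
                   (3 * n4, 3 * n4), (2 * n4, n4)]
        track_ids = np.array(
            [gm.neuron_id(i, j)
             for i, j in anchors[: max(1, cfg.track_cells)]]
        )
    else:
        track_ids = np.array([track_cell])
    firing = np.empty((len(track_ids), n_steps))
    snaps = []
    a_th = ALPHA_TH_DEFAULT
    nw = cfg.n_wdc
    W = weights.W

    for t in range(n_steps):
        if scales:
            xv.peaks = table_x(ly[t])
            yv.peaks = table_y(lx[t])
        wdc_step(xv, d_x[t], dt)
        wdc_step(yv, d_y[t], dt)

        # analytic AND map over the WDC pairs with nonzero conjunction
        # (s_ij = max(x_i + y_j - 1, 0) > 0 needs x_i > 1 - max(y))
        ax = np.flatnonzero(xv.state > 1.0 - yv.state.max())
        ay = np.flatnonzero(yv.state > 1.0 - xv.state.max())
        b_c = None
        if ax.size and ay.size:
            s_blk = xv.state[ax, None] + yv.state[None, ay] - 1.0
            rows_i, cols_j = np.nonzero(s_blk > 0.0)
            if rows_i.size:
                flat = ax[rows_i] * nw + ay[cols_j]
                s_act = s_blk[rows_i, cols_j].astype(np.float32)
                r = gm.pop.s
                r_max = float(r.max())
                r_rel = r * (1.0 / r_max) if (learn and r_max > 0) else None
                mass = float(s_act.sum())
                scale = k * min(1.0, cfg.pc_input_mass / mass)
                b = fused_calibration_step(
                    W, flat, s_act, r_rel, a_th, learn_factor,
                    learn and r_max > 0, scale,
                )
                if cfg.calibration:
                    b_c = b

        B_v = velocity_to_input(gm, vel[t])
        step_grid(gm, B_v, b_c, dt)
        if normalized:
            m = float(gm.pop.s.max())
            firing[:, t] = gm.pop.s[track_ids] / m if m > 0 else 0.0
        else:
            firing[:, t] = gm.pop.s[track_ids]
        if cfg.snapshot_every and t % cfg.snapshot_every == 0 and t > 0:
            snaps.append(gm.rates_as_sheet().copy())
        if t % 50_000 == 0 and t > 0:
            log.info("step %d: r_max=%.3f W_sum=%.1f", t, gm.pop.s.max(),
                     float(W.sum()))
            if not np.isfinite(gm.pop.s).all() or gm.pop.s.max() > 1e3:
                raise RuntimeError("grid rates diverged; aborting phase")

    x0, y0 = env.vertices.min(axis=0)
    x1, y1 = env.vertices.max(axis=0)
    # drop the settling-in fraction of the phase: before weights and phase
    # anchoring stabilize, the accumulated field is incomplete and noisy
    skip = int(cfg.map_burnin_frac * n_steps)
    rate_maps = [
        analysis.accumulate_rate_map(
            pos[skip:], f[skip:], (x0, x1, y0, y1), bin_size=cfg.bin_size
        )
        for f in firing
    ]
    return PhaseResult(
        positions=pos[skip:], firing=firing[0, skip:], rate_map=rate_maps[0],
        sheet_snapshots=snaps, gm=gm, weights=weights, env=env,
        firing_all=firing[:, skip:], rate_maps=rate_maps,
    )


def resolve_transform(
    cfg: ScenarioConfig, train_env: Environment, test_env: Environment
) -> TransformSpec | None:
    """The velocity transform for the test phase, or None for identity.

    The linear map is only valid under option (ii) with constant density;
    otherwise (mode "auto") the transform falls back to the identity and
    the raised test gain ``k_test`` must carry the distortion.
    """
    mode = cfg.velocity_transform
    if mode == "identity":
        return None
    convention = "literal" if mode == "literal_eq15" else "auto"
    if cfg.option == "ii" and cfg.density_kind == "constant":
        T = build_transform(train_env, test_env, convention=convention)
        log.info("velocity transform D = %s", T.D.tolist())
        return T
    if mode == "literal_eq15":
        raise ValueError(
            "linear velocity transform requires option (ii) and constant "
            "density; raise k_test and use the identity transform instead"
        )
    log.info("transform assumptions violated; using identity with k_test=%g",
             cfg.k_test)
    return None


def run_training(cfg: ScenarioConfig) -> TrainedState:
    """Build the grid module and train the calibration weights."""
    env = cfg.make_train_env()
    gm = make_grid_module(
        n_g=cfg.n_g, k_bumps=cfg.k_bumps, spacing=cfg.spacing, dt=cfg.dt
    )
    weights = CalibrationWeights(cfg.n_wdc**2, gm.n_cells, k=cfg.k_train)
    res = run_phase(
        cfg, env, gm, weights, cfg.n_train, seed_salt=1,
        learn=cfg.calibration, k=cfg.k_train,
    )
    if not cfg.calibration:
        assert float(weights.W.sum()) == 0.0
    return TrainedState(config=cfg, gm=gm, weights=weights, train_result=res)


def run_test(cfg: ScenarioConfig, trained: TrainedState) -> PhaseResult:
    """Traverse the test cage with frozen weights; returns maps and series."""
    train_env = cfg.make_train_env()
    env = cfg.make_test_env()
    T = resolve_transform(cfg, train_env, env)
    k = cfg.k_test if T is None else cfg.k_train
    return run_phase(
        cfg, env, trained.gm, trained.weights, cfg.n_test, seed_salt=2,
        learn=False, k=k, transform=T,
    )


# ---------------------------------------------------------------------------
# built-in scenarios (printed parameters; design defaults elsewhere)

FULL_SCALE = {"n_g": 40, "bin_size": 0.5}
CI_SCALE = {"n_g": 40, "bin_size": 0.75}


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    return {
        "stability": ScenarioConfig(
            name="stability",
            train_env=("square", 20.0),
            test_env=None,
            n_wdc=15,
            n_train=5_000_000,
            n_test=0,
            odometry_noise_sd=0.1,
            snapshot_every=1000,
        ),
        "rectangles": ScenarioConfig(
            name="rectangles",
            train_env=("square", 20.0),
            test_env=("rectangle", 10.0, 20.0),
            n_wdc=15,
        ),
        "trapezoid_linear": ScenarioConfig(
            name="trapezoid_linear",
            train_env=("square", 30.0),
            test_env=("isosceles_trapezoid", 30.0, 30.0, 10.0),
            n_wdc=25,
            k_train=0.05,
            k_test=0.05,
        ),
        "trapezoid_nonlinear": ScenarioConfig(
            name="trapezoid_nonlinear",
            train_env=("square", 30.0),
            test_env=("isosceles_trapezoid", 30.0, 30.0, 10.0),
            n_wdc=130,
            density_kind="exponential",
            option="i",
            activation="radius",
            activation_r=1.0,
            k_train=0.05,
            k_test=3.0,
        ),
        "pc_scaling": ScenarioConfig(
            name="pc_scaling",
            train_env=("square", 20.0),
            test_env=None,
            n_wdc=15,
        ),
        "pc_wall_move": ScenarioConfig(
            name="pc_wall_move",
            train_env=("rectangle", 20.0, 20.0),
            test_env=("rectangle", 20.0, 15.0),
            n_wdc=15,
        ),
    }


def scaled(cfg: ScenarioConfig, scale: str = "ci",
           n_train: int | None = None, n_test: int | None = None
           ) -> ScenarioConfig:
    """A copy of a scenario at the compact simulation scale.

    The compact profile (n_g = 24, coarser maps, 1e5-scale iteration
    counts) preserves every qualitative property of the full profile and is
    what the test-suite regressions and the acceptance script run.
    """
    over = dict(CI_SCALE if scale == "ci" else FULL_SCALE)
    if scale == "ci":
        over["n_train"] = n_train if n_train is not None else 300_000
        over["n_test"] = n_test if n_test is not None else 300_000
    else:
        if n_train is not None:
            over["n_train"] = n_train
        if n_test is not None:
            over["n_test"] = n_test
    return dataclasses.replace(cfg, **over)


def run_stability(
    cfg: ScenarioConfig, calibration: bool, segments: int = 200
) -> dict:
    """The stability experiment: traverse the square while training.

    Returns the field/sheet profile MSE and the per-location firing
    variance VAR of the tracked grid cell, plus the underlying results.
    ``segments`` sets the VAR grid; scaled-down runs need coarser segments
    so each cell collects several independent visits.
    """
    cfg = dataclasses.replace(cfg, calibration=calibration)
    if not cfg.snapshot_every:
        cfg = dataclasses.replace(cfg, snapshot_every=1000)
    trained = run_training(cfg)
    res = trained.train_result
    env = res.env
    x0, y0 = env.vertices.min(axis=0)
    x1, y1 = env.vertices.max(axis=0)
    fp = analysis.field_profile(res.rate_map)
    sp = analysis.sheet_profile(res.sheet_snapshots)
    return {
        "mse": analysis.profile_mse(fp, sp),
        "var": analysis.firing_variance(
            res.positions, res.firing, (x0, x1, y0, y1), segments=segments
        ),
        "result": res,
        "field_profile": fp,
        "sheet_profile": sp,
    }
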