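"""Synthetic agent trajectories: a seeded correlated random walk in a cage.

The walk replaces a physical robot: heading evolves by Gaussian increments,
speed is a clipped Gaussian, and the agent reflects off walls.  Only two
features matter downstream: the cage is covered densely, and velocities are
smooth enough for the attractor network to integrate.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np

from .environment import Environment

#: Defaults tuned so a 20-unit square is fully covered (20x20 occupancy
#: bins) well within 5e5 steps at dt = 0.01 s.  The speed distribution is
#: kept narrow: the attractor integrates velocities most faithfully inside
#: a band of drive strengths, and a rodent-like cruising gait does not need
#: near-zero or extreme speeds.
DEFAULT_MOTION = {"speed_mean": 2.2, "speed_sd": 0.5, "turn_sd": 2.5}


@dataclass(frozen=True)
class Trajectory:
    """Positions and velocities of the agent at a fixed time step.

    ``velocities[t] = (positions[t+1] - positions[t]) / dt``; the velocity
    sequence is one entry shorter than the position sequence (empty for a
    single-step trajectory).
    """

    dt: float
    positions: np.ndarray   # (n, 2)
    velocities: np.ndarray  # (n - 1, 2)
    seed: int

    def __len__(self) -> int:
        return len(self.positions)

    # -- I/O: tab-separated table with a header line carrying dt and seed --

    def to_tsv(self, path) -> None:
        n = len(self.positions)
        v = np.vstack([self.velocities, np.zeros((1, 2))]) if n else self.velocities
        t = np.arange(n) * self.dt
        table = np.column_stack([t, self.positions, v[:n]])
        header = f"dt={self.dt!r} seed={self.seed}\nt\tx\ty\tvx\tvy"
        np.savetxt(path, table, delimiter="\t", header=header, comments="# ")

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        if hasattr(path, "read"):
            text = path.read()
        else:
            with open(path) as fh:
                text = fh.read()
        first = text.splitlines()[0].lstrip("# ").split()
        meta = dict(kv.split("=") for kv in first)
        data = np.loadtxt(io.StringIO(text), skiprows=2, ndmin=2)
        pos = data[:, 1:3]
        dt = float(meta["dt"])
        vel = (pos[1:] - pos[:-1]) / dt
        return cls(dt=dt, positions=pos, velocities=vel, seed=int(meta["seed"]))


def _inside(env: Environment, p) -> bool:
    # cheap convex-polygon test: p must be on the inner side of every edge
    verts = env.vertices
    k = len(verts)
    for i in range(k):
        a = verts[i]
        b = verts[(i + 1) % k]
        cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
        if cross < 0:
            return False
    return True


def _reflect_heading(env: Environment, p, heading: float) -> float:
    """Reflect a heading off the nearest violated (or nearest) wall."""
    verts = env.vertices
    k = len(verts)
    best_i, best_d = 0, np.inf
    for i in range(k):
        a = verts[i]
        b = verts[(i + 1) % k]
        e = b - a
        L = math.hypot(e[0], e[1])
        d = abs(e[0] * (p[1] - a[1]) - e[1] * (p[0] - a[0])) / L
        if d < best_d:
            best_d, best_i = d, i
    a = verts[best_i]
    b = verts[(best_i + 1) % k]
    wall_angle = math.atan2(b[1] - a[1], b[0] - a[0])
    return 2.0 * wall_angle - heading


def simulate_trajectory(
    env: Environment,
    n_steps: int,
    dt: float = 0.01,
    motion: dict | None = None,
    seed: int = 0,
    start: tuple[float, float] | None = None,
) -> Trajectory:
    """Simulate a correlated random walk inside ``env``.

    Parameters
    ----------
    n_steps : number of positions to generate (>= 1).
    dt : step length in seconds.
    motion : dict with ``speed_mean`` (units/s), ``speed_sd`` and
        ``turn_sd`` (rad / sqrt(s)); missing keys fall back to defaults.
    seed : RNG seed; identical seeds give bitwise-identical trajectories.
    start : optional start position, default the cage centroid.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if env.polygon.area <= 0:
        raise ValueError("degenerate environment")
    m = dict(DEFAULT_MOTION)
    if motion:
        m.update(motion)

    rng = np.random.default_rng(seed)
    if start is None:
        c = env.polygon.centroid
        p = np.array([c.x, c.y])
    else:
        p = np.asarray(start, dtype=float)
        if not _inside(env, p):
            raise ValueError("start position outside the cage")

    heading = rng.uniform(0.0, 2.0 * math.pi)
    sqrt_dt = math.sqrt(dt)
    turns = rng.normal(0.0, m["turn_sd"] * sqrt_dt, size=n_steps)
    speeds = np.clip(
        rng.normal(m["speed_mean"], m["speed_sd"], size=n_steps),
        0.55 * m["speed_mean"],
        1.45 * m["speed_mean"],
    )

    pos = np.empty((n_steps, 2))
    pos[0] = p
    for t in range(1, n_steps):
        heading += turns[t]
        step = speeds[t] * dt
        for _ in range(8):
            cand = pos[t - 1] + step * np.array(
                [math.cos(heading), math.sin(heading)]
            )
            if _inside(env, cand):
                break
            heading = _reflect_heading(env, cand, heading)
        else:
            cand = pos[t - 1]  # cornered: stay put this step
        pos[t] = cand

    vel = (pos[1:] - pos[:-1]) / dt
    return Trajectory(dt=dt, positions=pos, velocities=vel, seed=seed)
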