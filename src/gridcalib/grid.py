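"""Continuous-attractor grid-cell module on a twisted torus.

``n x n`` rate neurons live on the unit sheet with the twisted-torus
identification ``(x, y) ~ (x + 1, y) ~ (x + 1/2, y + 1)``.  Connectivity is
a translation-invariant inhibitory-surround kernel whose outgoing weights
are shifted along each neuron's preferred direction (four interleaved
subpopulations: E, N, W, S), and every neuron receives a constant
excitatory baseline plus a velocity-modulated input.  A triangular bump
lattice forms and constant velocity input translates it — path integration.

The commensurate bump lattice on this torus is a regular triangular lattice
stretched by 2/sqrt(3) along the sheet y-axis (basis ``(1/k, 0)`` and
``(1/2k, 1/k)`` for ``k`` bumps per row).  The module is always initialized
on that lattice and briefly settled with zero velocity, which makes the
initial grid orientation and phase deterministic.  The stretch carries into
space: the spatial firing lattice of a single cell is a hexagonal lattice
compressed by sqrt(3)/2 along one axis, i.e. its autocorrelogram hexagon
has eccentricity 0.5 rather than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Population, step_rates

#: Preferred directions of the four interleaved subpopulations.
_DIRS = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])


def _torus_displacement(d: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) on the twisted torus (sheet units)."""
    d = np.asarray(d, dtype=float)
    best = None
    best_n = None
    for b in (-1, 0, 1):
        dy = d[..., 1] + b
        dx = d[..., 0] + 0.5 * b
        dx = dx - np.round(dx)
        n2 = dx * dx + dy * dy
        if best is None:
            best = np.stack([dx, dy], axis=-1)
            best_n = n2
        else:
            take = n2 < best_n
            best[take] = np.stack([dx, dy], axis=-1)[take]
            best_n = np.where(take, n2, best_n)
    return best


def build_grid_weights(
    n_g: int,
    k_bumps: int = 4,
    shift: float = 1.0,
    gamma_ratio: float = 1.05,
    amplitude: float = 12.0,
    beta_coef: float = 5.33,
) -> np.ndarray:
    """Recurrent weight matrix of the twisted-torus attractor.

    The kernel is the classic inhibitory-surround difference of Gaussians
    ``W0(d) = A * (exp(-g*|d|^2) - exp(-b*|d|^2))`` with ``b = beta_coef / lam^2``,
    ``g = gamma_ratio * b`` and ``lam = n_g / k_bumps`` the bump period in
    neuron units; outgoing weights of a neuron with preferred direction
    ``e`` are centered at ``shift`` neurons along ``e``.  Entry ``[i, j]``
    is the weight from presynaptic ``j`` onto postsynaptic ``i``.
    """
    if n_g < 16:
        raise ValueError("need n_g >= 16 for a usable bump lattice")
    if n_g % 4:
        raise ValueError("n_g must be a multiple of 4 (direction tiling + twist)")
    lam = n_g / k_bumps
    beta = beta_coef / lam**2
    gamma = gamma_ratio * beta

    ii, jj = np.meshgrid(np.arange(n_g), np.arange(n_g), indexing="ij")
    pos = np.stack([ii.ravel(), jj.ravel()], axis=-1) / n_g  # sheet units
    dir_idx = (ii.ravel() % 2) + 2 * (jj.ravel() % 2)
    dirs = _DIRS[dir_idx]

    # displacement from presynaptic j (shifted along its direction) to i
    d = pos[:, None, :] - pos[None, :, :] - (shift / n_g) * dirs[None, :, :]
    d = _torus_displacement(d) * n_g  # neuron units
    r2 = np.einsum("ijk,ijk->ij", d, d)
    w = amplitude * (np.exp(-gamma * r2) - np.exp(-beta * r2))
    if not np.all(np.isfinite(w)):
        raise ValueError("kernel parameters produced non-finite weights")
    return w.astype(np.float32)


class GridConnectivity:
    """Matrix-free application of the twisted-torus connectivity.

    The recurrent operator is a sum of four translation-invariant kernels
    (one per preferred-direction class), so ``w @ s`` is evaluated as FFT
    convolutions on the plain-torus double cover of the twisted torus
    (second copy of the sheet shifted by ``n/2`` rows).  Exactly equivalent
    to the dense matrix of :func:`build_grid_weights` (the kernel decays to
    zero well inside the cover), but touches kilobytes instead of the
    O(n_g^4) matrix — the dense form is quadratic in memory and its
    streaming dominates simulation time.
    """

    def __init__(
        self,
        n_g: int,
        k_bumps: int = 4,
        shift: float = 1.0,
        gamma_ratio: float = 1.05,
        amplitude: float = 12.0,
        beta_coef: float = 5.33,
    ):
        if n_g < 16:
            raise ValueError("need n_g >= 16 for a usable bump lattice")
        if n_g % 4:
            raise ValueError("n_g must be a multiple of 4")
        from scipy import fft as sfft

        self._fft = sfft
        self.n_g = n_g
        self.shape = (n_g * n_g, n_g * n_g)
        self.dtype = np.dtype(np.float32)
        lam = n_g / k_bumps
        beta = beta_coef / lam**2
        gamma = gamma_ratio * beta
        di = np.arange(n_g)[:, None]
        dj = np.arange(2 * n_g)[None, :]
        self._Kf = []
        for e in _DIRS:
            dxs = ((di - shift * e[0]) / n_g + 0.5) % 1.0 - 0.5
            dys = ((dj - shift * e[1]) / n_g + 1.0) % 2.0 - 1.0
            r2 = (dxs * n_g) ** 2 + (dys * n_g) ** 2
            K = amplitude * (np.exp(-gamma * r2) - np.exp(-beta * r2))
            if not np.all(np.isfinite(K)):
                raise ValueError("kernel parameters produced non-finite weights")
            self._Kf.append(sfft.rfft2(K.astype(np.float32)))
        ii, jj = np.meshgrid(np.arange(n_g), np.arange(n_g), indexing="ij")
        self._masks = [(ii % 2) + 2 * (jj % 2) == c for c in range(4)]

    def __matmul__(self, s: np.ndarray) -> np.ndarray:
        n = self.n_g
        S = s.reshape(n, n)
        acc = None
        lifted = np.empty((n, 2 * n), dtype=np.float32)
        for c in range(4):
            sc = np.where(self._masks[c], S, 0.0).astype(np.float32)
            lifted[:, :n] = sc
            lifted[:, n:] = np.roll(sc, n // 2, axis=0)
            Sf = self._fft.rfft2(lifted)
            Sf *= self._Kf[c]
            acc = Sf if acc is None else acc + Sf
        out = self._fft.irfft2(acc, s=(n, 2 * n))[:, :n]
        return np.ascontiguousarray(out, dtype=np.float32).ravel()

    def dense(self, **kwargs) -> np.ndarray:
        return build_grid_weights(self.n_g, **kwargs)


def lattice_pattern(n_g: int, k_bumps: int = 4) -> np.ndarray:
    """The commensurate bump-lattice template used as the initial state.

    Sum of three plane waves on the reciprocal basis of the stretched
    triangular lattice; rectified so bumps sit on the lattice points.
    """
    ii, jj = np.meshgrid(np.arange(n_g), np.arange(n_g), indexing="ij")
    x = ii.ravel() / n_g
    y = jj.ravel() / n_g
    k = 2.0 * math.pi * k_bumps
    waves = (
        np.cos(k * (x - 0.5 * y))
        + np.cos(k * y)
        + np.cos(k * (-x - 0.5 * y))
    )
    return np.maximum(waves, 0.0)


@dataclass
class GridModule:
    """State and parameters of one grid-cell attractor module."""

    n_g: int
    pop: Population
    dirs: np.ndarray                      # (N, 2) preferred directions
    k_bumps: int = 4
    spacing: float = 5.3                  # spatial grid period (length units)
    gain: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    #: mean rate of the settled, input-free pattern; strong localized
    #: calibration drive is renormalized against it (divisive stabilization,
    #: as in the attractor implementations this module follows)
    mean_target: float = 0.0
    #: excursion factor above mean_target at which divisive rescaling kicks
    #: in (1.0 = always normalize the mean back to its reference level)
    stabilize_gate: float = 1.2

    @property
    def r(self) -> np.ndarray:
        return self.pop.s

    @property
    def n_cells(self) -> int:
        return self.n_g * self.n_g

    def sheet_index(self, neuron: int) -> tuple[int, int]:
        """Bijective map from neuron id to (i, j) sheet coordinates."""
        return divmod(int(neuron), self.n_g)

    def neuron_id(self, i: int, j: int) -> int:
        return int(i) * self.n_g + int(j)

    def sheet_distance(self, a: int, b: int) -> float:
        """Euclidean distance between index tuples, respecting wraparound."""
        ia, ja = self.sheet_index(a)
        ib, jb = self.sheet_index(b)
        d = np.array([(ia - ib) / self.n_g, (ja - jb) / self.n_g])
        return float(np.linalg.norm(_torus_displacement(d))) * self.n_g

    def rates_as_sheet(self) -> np.ndarray:
        return self.pop.s.reshape(self.n_g, self.n_g)

    # -- phase tracking ---------------------------------------------------

    def _reciprocal(self) -> np.ndarray:
        k = 2.0 * math.pi * self.k_bumps
        return np.array([[k, -0.5 * k], [0.0, k]])

    def pattern_phase(self) -> np.ndarray:
        """Phases (radians) of the two primary Fourier modes of the pattern."""
        n = self.n_g
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        xy = np.stack([ii.ravel(), jj.ravel()], axis=-1) / n
        out = np.empty(2)
        for m, kvec in enumerate(self._reciprocal()):
            z = np.sum(self.pop.s * np.exp(-1j * (xy @ kvec)))
            out[m] = np.angle(z)
        return out

    def displacement_from_phases(
        self, ph0: np.ndarray, ph1: np.ndarray
    ) -> np.ndarray:
        """Sheet displacement between two phase snapshots (assumed < 1/2 period)."""
        dph = np.angle(np.exp(1j * (ph1 - ph0)))
        K = self._reciprocal()
        return np.linalg.solve(K, -dph)


def make_grid_module(
    n_g: int = 32,
    k_bumps: int = 4,
    spacing: float = 5.3,
    tau: float = 0.1,
    dt: float = 0.01,
    settle_steps: int = 800,
    calibrate: bool = True,
    **kernel_kwargs,
) -> GridModule:
    """Build, initialize and (optionally) gain-calibrate a grid module.

    The module starts on the commensurate lattice template and settles with
    zero velocity; the path-integration gain is then measured per axis so
    that moving one grid ``spacing`` in space shifts the sheet pattern by
    exactly one lattice period.  ``connectivity="fft"`` (default) applies
    the recurrent weights matrix-free; ``"dense"`` materializes them.
    """
    connectivity = kernel_kwargs.pop("connectivity", "fft")
    if connectivity == "fft":
        w = GridConnectivity(n_g, k_bumps=k_bumps, **kernel_kwargs)
    else:
        w = build_grid_weights(n_g, k_bumps=k_bumps, **kernel_kwargs)
    ii, jj = np.meshgrid(np.arange(n_g), np.arange(n_g), indexing="ij")
    dirs = _DIRS[(ii.ravel() % 2) + 2 * (jj.ravel() % 2)]
    s0 = lattice_pattern(n_g, k_bumps).astype(np.float32)
    pop = Population(s=s0, w=w, tau=tau)
    gm = GridModule(n_g=n_g, pop=pop, dirs=dirs, k_bumps=k_bumps, spacing=spacing)
    for _ in range(settle_steps):
        step_grid(gm, None, None, dt)
    gm.mean_target = float(gm.pop.s.mean())
    if calibrate:
        gm.gain = _calibrate_gain(gm, dt)
    return gm


def velocity_to_input(gm: GridModule, v) -> np.ndarray:
    """Velocity-modulated input: each neuron's drive is scaled by the dot
    product of the (per-axis gain-scaled) velocity with its direction."""
    v = np.asarray(v, dtype=float)
    return gm.dirs @ (gm.gain * v)


def step_grid(gm: GridModule, B_v, B_c, dt: float) -> np.ndarray:
    """One Euler step of the module with velocity + calibration input.

    After the rate update the total activity is divisively renormalized
    whenever it exceeds the input-free level: the purely additive rate
    equation has no mechanism bounding the response to a strong localized
    calibration bump, and without this stabilization dense-place-cell
    configurations drive local rates to many times the pattern amplitude.
    Velocity-only operation is unaffected (the mean then stays at its
    reference level by itself).
    """
    B = 0.0
    if B_v is not None:
        B = B + B_v
    if B_c is not None:
        B = B + B_c
    gm.pop.B = np.broadcast_to(np.asarray(B, dtype=float), gm.pop.s.shape)
    s = step_rates(gm.pop, dt)
    if gm.mean_target > 0.0:
        m = float(s.mean())
        cap = gm.stabilize_gate * gm.mean_target
        if m > cap:
            s *= cap / m
    return s


def _measure_drift(gm: GridModule, v, dt: float, n_steps: int) -> np.ndarray:
    """Sheet displacement per second under constant velocity ``v``."""
    ph = gm.pattern_phase()
    total = np.zeros(2)
    for _ in range(n_steps):
        step_grid(gm, velocity_to_input(gm, v), None, dt)
        ph1 = gm.pattern_phase()
        total += gm.displacement_from_phases(ph, ph1)
        ph = ph1
    return total / (n_steps * dt)


def _calibrate_gain(
    gm: GridModule,
    dt: float,
    probe_speed: float = 2.0,
    probe_gain: float = 0.05,
    n_steps: int = 400,
    n_rounds: int = 2,
) -> np.ndarray:
    """Per-axis path-integration gain.

    Target: sheet drift of ``|v| / (spacing * k_bumps)`` sheet units per
    second, i.e. one bump-lattice period per grid spacing travelled.  The
    attractor's velocity response saturates at strong drive, so the probe
    starts at a small gain inside the linear regime and is refined by a
    second proportional round; each axis gets its own gain.
    """
    target = probe_speed / (gm.spacing * gm.k_bumps)
    gain = np.array([probe_gain, probe_gain])
    state0 = gm.pop.s.copy()
    for axis in range(2):
        g = probe_gain
        v = np.zeros(2)
        v[axis] = probe_speed
        for _ in range(n_rounds):
            gm.pop.s = state0.copy()
            gm.gain = np.array([g, g])
            drift = _measure_drift(gm, v, dt, n_steps)[axis]
            if abs(drift) < 1e-12:
                raise ValueError("no measurable pattern drift; kernel unusable")
            g *= target / drift
        gain[axis] = g
    gm.pop.s = state0
    return gain
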