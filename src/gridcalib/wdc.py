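"""Wall distance cells (WDCs).

A WDC vector is a population of ``n`` neurons, each with a preferred
distance (*peak*) to one reference wall.  Peaks are placed either uniformly
(constant target density) or by a recursive rule that realizes an arbitrary
target density profile ``f`` — by default the exponential profile with
``f(0) = 1`` and ``f(0.5) = 0.1``, mimicking the experimentally observed
higher packing of boundary-tuned cells at short distances.

Two span-scaling regimes exist: option (ii) scales peaks to the fixed
maximal wall-to-wall extent of the cage; option (i) rescales them to the
local cage width through the agent's current position, so peak loci bend
toward the narrow end of a tapering cage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

#: WDC population time constant (seconds).
TAU_WDC = 0.05

EXP_C2 = 2.0 * np.log(0.1)


@dataclass(frozen=True)
class DensitySpec:
    """Target peak-density profile ``f(x) = c1 * exp(c2 * x)`` on [0, 1].

    ``kind="constant"`` fixes ``f = c1``; the exponential default satisfies
    ``f(0) = 1`` and ``f(0.5) = 0.1``.
    """

    kind: str = "constant"
    c1: float = 1.0
    c2: float = EXP_C2

    def __post_init__(self):
        if self.kind not in ("constant", "exponential"):
            raise ValueError(f"unknown density kind {self.kind!r}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "constant":
            return np.broadcast_to(np.float64(self.c1), x.shape).copy()
        return self.c1 * np.exp(self.c2 * x)


def place_peaks_uniform(n: int, l: float) -> np.ndarray:
    """Evenly spaced peaks ``p(i) = l*i/n`` for ``i = 1..n``.

    The index starts at 1 so no peak sits on the wall itself.
    """
    if n < 1 or l <= 0:
        raise ValueError("need n >= 1 and l > 0")
    return l * np.arange(1, n + 1) / n


def normalize_density(
    f: DensitySpec, n: int, l: float, l_max: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Rescale ``f`` so that exactly ``n`` peaks fit into ``[0, l]``.

    Returns ``f'(x) = f(x) * n / integral_0^l f(u / l_max) du`` with the
    integral evaluated by adaptive quadrature.  Under option (ii) callers
    pass ``l = l_max``.
    """
    if l <= 0 or l > l_max * (1 + 1e-9):
        raise ValueError("need 0 < l <= l_max")
    integral, _ = quad(lambda u: float(f(u / l_max)), 0.0, l)
    if integral <= 0:
        raise ValueError("density integrates to a non-positive value")
    scale = n / integral

    def f_prime(x):
        return f(x) * scale

    return f_prime


def place_peaks_density(
    f: DensitySpec, n: int, l: float, l_max: float
) -> np.ndarray:
    """Place ``n`` peaks realizing density ``f`` via the recursion
    ``p(i) = 1 / f'(p(i-1) / l_max) + p(i-1)`` anchored at ``p(0) = 0``.

    The recursion freezes the density over each increment at its left end —
    the approximation whose quality :func:`validate_density_approx`
    quantifies.  For constant ``f`` it reproduces
    :func:`place_peaks_uniform` exactly.
    """
    f_prime = normalize_density(f, n, l, l_max)
    peaks = np.empty(n)
    p = 0.0
    for i in range(n):
        p = p + 1.0 / float(f_prime(p / l_max))
        peaks[i] = p
    if peaks[-1] > l * 1.2:
        raise ValueError("peak recursion left the cage span")
    return peaks


def validate_density_approx(
    peaks: np.ndarray, f_prime: Callable, l_max: float
) -> float:
    """Mean relative deviation between realized and target peak density.

    The realized density over interval ``(p(i-1), p(i)]`` is the reciprocal
    spacing ``1 / (p(i) - p(i-1))``, evaluated at the interval midpoint
    (scaled by ``l_max``); the return value is the mean over intervals of
    ``|realized - target| / target``.
    """
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks")
    ext = np.concatenate([[0.0], peaks])
    gaps = np.diff(ext)
    if np.any(gaps <= 0):
        raise ValueError("peaks must be strictly increasing (no duplicates)")
    mids = (ext[:-1] + ext[1:]) / 2.0 / l_max
    realized = 1.0 / gaps
    target = np.asarray(f_prime(mids), dtype=float)
    return float(np.mean(np.abs(realized - target) / target))


def place_peaks(
    density: DensitySpec, n: int, l: float, l_max: float
) -> np.ndarray:
    """Dispatch: uniform placement for constant density, recursion otherwise."""
    if density.kind == "constant":
        return place_peaks_uniform(n, l)
    return place_peaks_density(density, n, l, l_max)


class PeakTable:
    """Peak positions as a function of the local span ``l``.

    Under option (i) the peaks must be recomputed at every step from the
    local cage width; for the exponential density this is a 130-step
    recursion, so the table precomputes peaks on a grid of spans and
    interpolates linearly in ``l`` (peaks vary smoothly with the span).
    """

    def __init__(self, density: DensitySpec, n: int, l_max: float,
                 l_min: float | None = None, resolution: int = 256):
        self.density = density
        self.n = n
        self.l_max = l_max
        if density.kind == "constant":
            self._grid = None
        else:
            lo = max(l_min if l_min is not None else l_max / 50.0, 1e-6)
            self._ls = np.linspace(lo, l_max, resolution)
            self._grid = np.stack(
                [place_peaks_density(density, n, l, l_max) for l in self._ls]
            )

    def __call__(self, l: float) -> np.ndarray:
        if self._grid is None:
            return place_peaks_uniform(self.n, l)
        l = float(np.clip(l, self._ls[0], self._ls[-1]))
        j = int(np.searchsorted(self._ls, l))
        if j == 0:
            return self._grid[0]
        if j >= len(self._ls):
            return self._grid[-1]
        w = (l - self._ls[j - 1]) / (self._ls[j] - self._ls[j - 1])
        return (1 - w) * self._grid[j - 1] + w * self._grid[j]


@dataclass
class WDCVector:
    """One axis's WDC population and its rate state.

    ``axis`` is "x" (peaks are distances to wall_y) or "y" (distances to
    wall_x).  ``activation`` is "nearest" (the unique neuron whose
    nearest-peak interval contains the current distance relaxes toward 1)
    or "radius" (every neuron within ``r`` of the distance does).
    """

    axis: str
    peaks: np.ndarray
    activation: str = "nearest"
    r: float = 1.0
    tau: float = TAU_WDC
    state: np.ndarray = field(default=None)

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=float)
        if np.any(np.diff(self.peaks) <= 0):
            raise ValueError("peaks must be strictly increasing")
        if self.activation not in ("nearest", "radius"):
            raise ValueError(f"unknown activation mode {self.activation!r}")
        if self.state is None:
            self.state = np.zeros_like(self.peaks)

    @property
    def n(self) -> int:
        return len(self.peaks)

    def target(self, d: float) -> np.ndarray:
        """The 0/1 target vector toward which the state relaxes at distance d."""
        tgt = np.zeros(self.n)
        if self.activation == "nearest":
            mids = (self.peaks[:-1] + self.peaks[1:]) / 2.0
            # lower-open / upper-closed intervals: a distance exactly on a
            # midpoint belongs to the lower neuron
            tgt[int(np.searchsorted(mids, d, side="left"))] = 1.0
        else:
            tgt[np.abs(d - self.peaks) <= self.r] = 1.0
        return tgt


def wdc_step(v: WDCVector, d: float, dt: float) -> np.ndarray:
    """One leaky relaxation step of the WDC state toward its target.

    ``state <- (1 - dt/tau) * state + (dt/tau) * target`` elementwise, which
    keeps every component in [0, 1].
    """
    if not dt < v.tau:
        raise ValueError("explicit update requires dt < tau")
    if d < 0:
        raise ValueError("wall distance must be nonnegative")
    a = dt / v.tau
    v.state *= 1.0 - a
    v.state += a * v.target(d)
    return v.state
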