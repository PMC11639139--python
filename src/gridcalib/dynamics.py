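"""The shared rate-neuron update rule.

Every subnetwork follows the same first-order rate dynamics

    tau * ds/dt + s = max(w @ s + B + 1, 0)

integrated with explicit Euler.  For a constant total input sum x an
isolated neuron converges geometrically to max(x, 0); that fixed-point
property is what the analytic AND-gate shortcut and the Hebbian coactivation
rule rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default time constant for grid and gate populations (seconds).
TAU_DEFAULT = 0.1

try:  # single-thread SIMD matvec; the platform BLAS is unoptimized
    from numba import njit

    @njit(fastmath=True, cache=True)
    def _gemv32(w, s):
        n = w.shape[0]
        out = np.empty(n, dtype=np.float32)
        for i in range(n):
            acc = np.float32(0.0)
            row = w[i]
            for j in range(n):
                acc += row[j] * s[j]
            out[i] = acc
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


@dataclass
class Population:
    """A recurrently connected rate population.

    ``w[i, j]`` is the connection strength from neuron ``j`` onto neuron
    ``i`` (so the recurrent drive to the population is ``w @ s``).  ``B`` is
    the external input; the constant baseline ``+1`` of the update rule is
    added inside :func:`step_rates`, not stored in ``B``.
    """

    s: np.ndarray
    w: np.ndarray
    tau: float = TAU_DEFAULT
    B: np.ndarray = field(default=None)

    def __post_init__(self):
        # floating dtypes are preserved (large modules run in float32)
        self.s = np.asarray(self.s)
        self.s = (
            self.s.astype(float)
            if not np.issubdtype(self.s.dtype, np.floating)
            else self.s.copy()
        )
        if isinstance(self.w, np.ndarray) or not hasattr(self.w, "__matmul__"):
            self.w = np.asarray(self.w)
            if not np.issubdtype(self.w.dtype, np.floating):
                self.w = self.w.astype(float)
        if self.B is None:
            self.B = np.zeros_like(self.s)
        self.B = np.asarray(self.B)
        n = self.s.shape[-1]
        if self.w.shape != (n, n) or self.B.shape[-1] != n:
            raise ValueError("dimensions of s, w and B disagree")


def step_rates(pop: Population, dt: float) -> np.ndarray:
    """Advance the population one explicit-Euler step of length ``dt``.

    Requires ``dt < tau`` for stability of the explicit scheme.  Updates
    ``pop.s`` in place and returns it.
    """
    if not dt < pop.tau:
        raise ValueError("explicit Euler requires dt < tau")
    if (
        _HAVE_NUMBA
        and isinstance(pop.w, np.ndarray)
        and pop.w.dtype == np.float32
        and pop.s.dtype == np.float32
        and pop.s.size >= 256
    ):
        drive = _gemv32(pop.w, pop.s)
    else:
        drive = pop.w @ pop.s
    drive = drive.astype(pop.s.dtype, copy=False)
    drive += pop.B
    drive += 1.0
    np.maximum(drive, 0.0, out=drive)
    drive -= pop.s
    drive *= dt / pop.tau
    pop.s = pop.s + drive
    return pop.s
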