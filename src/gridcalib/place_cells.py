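"""Place cells as AND conjunctions of wall distance cells.

Each place cell is the output of an AND gate over one x-vector and one
y-vector WDC, so its firing peak sits where the two preferred-distance loci
intersect.  The gate exists in two forms: an 8-neuron disinhibition circuit
simulated with the shared rate dynamics, and its analytic steady state
``max(i1 + i2 - 1, 0)`` used in all experiments for speed.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .dynamics import Population, step_rates
from .environment import Environment
from .wdc import WDCVector

log = logging.getLogger(__name__)

# Neuron order in the symmetric disinhibition circuit.
_GATE_NEURONS = ("In1", "In2", "C", "Inh1", "Inh2", "Ex1", "Ex2", "Out")


def _gate_weights() -> np.ndarray:
    """Recurrent weights of the symmetric AND-gate circuit.

    Wiring (post <- pre): Inh1 <- +C, -In1 (so Inh1 converges to 1 - i1);
    Ex1 <- +In1, -Inh2; Ex2 <- +In2, -Inh1; Out <- +0.5*Ex1, +0.5*Ex2.
    With the constant neuron C pinned at 1 the steady-state output is
    max(i1 + i2 - 1, 0), symmetric in the two inputs.
    """
    idx = {name: k for k, name in enumerate(_GATE_NEURONS)}
    w = np.zeros((8, 8))
    w[idx["Inh1"], idx["C"]] = 1.0
    w[idx["Inh1"], idx["In1"]] = -1.0
    w[idx["Inh2"], idx["C"]] = 1.0
    w[idx["Inh2"], idx["In2"]] = -1.0
    w[idx["Ex1"], idx["In1"]] = 1.0
    w[idx["Ex1"], idx["Inh2"]] = -1.0
    w[idx["Ex2"], idx["In2"]] = 1.0
    w[idx["Ex2"], idx["Inh1"]] = -1.0
    w[idx["Out"], idx["Ex1"]] = 0.5
    w[idx["Out"], idx["Ex2"]] = 0.5
    return w


def and_gate_analytic(i1, i2):
    """Steady-state AND-gate output ``max(i1 + i2 - 1, 0)``.

    Inputs outside [0, 1] are clipped (with a warning): the derivation of
    the steady state assumes rates in [0, 1].
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if np.any(i1 < 0) or np.any(i1 > 1) or np.any(i2 < 0) or np.any(i2 > 1):
        log.warning("AND-gate inputs outside [0, 1]; clipping")
        i1 = np.clip(i1, 0.0, 1.0)
        i2 = np.clip(i2, 0.0, 1.0)
    return np.maximum(i1 + i2 - 1.0, 0.0)


def and_gate_neural(
    i1: float, i2: float, dt: float = 0.01, T: float = 2.0, tau: float = 0.1
) -> np.ndarray:
    """Simulate the 8-neuron gate circuit for constant inputs over ``T`` s.

    Returns the time course of the output neuron's rate.  External inputs
    ``B`` are chosen so each neuron's total input sum matches its derived
    steady-state expression: the baseline +1 of the rate equation is
    cancelled with -1 offsets except at C (pinned to 1) and the inputs.
    """
    idx = {name: k for k, name in enumerate(_GATE_NEURONS)}
    B = -np.ones(8)
    B[idx["In1"]] += i1
    B[idx["In2"]] += i2
    B[idx["C"]] = 0.0  # total input 0 + 1 -> C converges to 1
    pop = Population(s=np.zeros(8), w=_gate_weights(), tau=tau, B=B)
    n_steps = int(round(T / dt))
    trace = np.empty(n_steps)
    for t in range(n_steps):
        trace[t] = step_rates(pop, dt)[idx["Out"]]
    return trace


def pc_activity(
    xv: WDCVector, yv: WDCVector, mode: str = "analytic"
) -> np.ndarray:
    """Place-cell activation matrix ``a[i, j] = AND(x_i, y_j)``.

    In "analytic" mode (the default used in all experiments) this is the
    closed-form steady state; "neural" mode runs each gate circuit to
    convergence and is orders of magnitude slower — intended for validation.
    """
    if mode == "analytic":
        return and_gate_analytic(
            xv.state[:, None], yv.state[None, :]
        )
    if mode == "neural":
        out = np.empty((xv.n, yv.n))
        for i in range(xv.n):
            for j in range(yv.n):
                out[i, j] = and_gate_neural(xv.state[i], yv.state[j])[-1]
        return out
    raise ValueError(f"unknown PC mode {mode!r}")


def pc_peak_position(
    i: int, j: int, env: Environment, x_peaks: np.ndarray, y_peaks: np.ndarray
) -> np.ndarray:
    """Cage position where the peaks of x-cell ``i`` and y-cell ``j`` meet.

    Solves the two line-distance constraints: distance ``x_peaks[i]`` from
    wall_y and ``y_peaks[j]`` from wall_x (both walls through the origin).
    Positions outside the cage are still returned — the PC simply never
    fires there — but are logged.
    """
    px = float(x_peaks[i])
    py = float(y_peaks[j])
    # signed-distance equations:  sin(psi)*x - cos(psi)*y = px
    #                            -sin(phi)*x + cos(phi)*y = py
    A = np.array(
        [
            [math.sin(env.psi), -math.cos(env.psi)],
            [-math.sin(env.phi), math.cos(env.phi)],
        ]
    )
    p = np.linalg.solve(A, np.array([px, py]))
    if not env.contains(p, tol=1e-6):
        log.debug("PC peak (%d, %d) at %s lies outside the cage", i, j, p)
    return p
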