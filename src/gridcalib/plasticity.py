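"""Hebbian calibration weights from place cells onto grid cells.

At every step the coactivation between a PC and a grid cell is

    alpha_ij = s_i * r_j / r_max - alpha_th

and where it is positive the weight relaxes toward it with time constant
``tau`` (10 ms — equal to the simulation step, so the update is an
instantaneous jump to alpha).  The calibration drive to grid cell j is the
gain-scaled weighted sum ``b_j = k * sum_i w_ij * s_i``.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

ALPHA_TH_DEFAULT = 0.05
TAU_LEARN_DEFAULT = 0.01
K_DEFAULT = 0.05

try:  # fused Hebbian step + calibration drive: one pass over the rows
    from numba import njit

    @njit(fastmath=True, cache=True)
    def _calib_step32(W, flat, s_act, r_rel, a_th, factor, learn, b_out):
        n = W.shape[1]
        b_out[:] = 0.0
        for p in range(flat.shape[0]):
            row = W[flat[p]]
            sp = s_act[p]
            for j in range(n):
                if learn:
                    a = sp * r_rel[j] - a_th
                    if a > 0.0:
                        row[j] += factor * (a - row[j])
                b_out[j] += sp * row[j]
        return b_out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def fused_calibration_step(
    W: np.ndarray,
    flat: np.ndarray,
    s_act: np.ndarray,
    r_rel: np.ndarray | None,
    a_th: float,
    factor: float,
    learn: bool,
    k: float,
) -> np.ndarray:
    """Hebbian update of the active rows and the calibration drive ``k W^T s``.

    ``flat`` indexes the active place cells, ``s_act`` their rates and
    ``r_rel`` the grid rates normalized by their maximum (``None`` skips
    learning).  Semantics match :func:`update_weights` followed by
    :func:`calibration_input`, fused for speed.
    """
    learn = learn and r_rel is not None
    if _HAVE_NUMBA and W.dtype == np.float32:
        b = np.empty(W.shape[1], dtype=np.float32)
        rr = (
            r_rel.astype(np.float32)
            if learn
            else np.empty(0, dtype=np.float32)
        )
        if not learn:
            rr = np.zeros(W.shape[1], dtype=np.float32)
        _calib_step32(
            W, flat.astype(np.int64), s_act.astype(np.float32), rr,
            np.float32(a_th), np.float32(factor), learn, b,
        )
        return k * b
    rows = W[flat]
    if learn:
        alpha = s_act[:, None] * r_rel[None, :] - a_th
        rows = np.where(alpha > 0, rows + factor * (alpha - rows), rows)
        W[flat] = rows
    return k * (s_act @ rows)


class CalibrationWeights:
    """PC -> GC weight matrix with the Hebbian update rule.

    ``W`` has shape ``(m, N)`` for ``m`` place cells and ``N`` grid cells.
    Weights stay within ``[0, 1 - alpha_th]`` because updates only ever
    relax toward attainable coactivation values.
    """

    def __init__(self, m: int, n_grid: int, alpha_th: float = ALPHA_TH_DEFAULT,
                 tau: float = TAU_LEARN_DEFAULT, k: float = K_DEFAULT):
        self.W = np.zeros((m, n_grid), dtype=np.float32)
        self.alpha_th = alpha_th
        self.tau = tau
        self.k = k

    # thin vector API used by the experiment loop ------------------------

    def learn(self, s: np.ndarray, r: np.ndarray, dt: float) -> None:
        """One Hebbian step given PC rates ``s`` and GC rates ``r``.

        Only rows with ``s_i > alpha_th`` can have positive coactivation
        (``r_j / r_max <= 1``), so the update touches just those rows.
        """
        r_max = float(r.max())
        if r_max <= 0:
            log.warning("r_max = 0; Hebbian step skipped")
            return
        active = np.flatnonzero(s > self.alpha_th)
        if active.size == 0:
            return
        alpha = coactivation(
            s[active, None], r[None, :], r_max, self.alpha_th
        ).astype(np.float32)
        rows = self.W[active]
        self.W[active] = update_weights(rows, alpha, dt, self.tau)

    def drive(self, s: np.ndarray) -> np.ndarray:
        """Calibration input ``b = k * W^T s`` (sparse in active PCs)."""
        return calibration_input(self.W, s, self.k)


def coactivation(s, r, r_max: float, alpha_th: float = ALPHA_TH_DEFAULT):
    """``alpha = s * (r / r_max) - alpha_th`` (broadcasts)."""
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    return np.asarray(s) * (np.asarray(r) / r_max) - alpha_th


def update_weights(W, alpha, dt: float, tau: float = TAU_LEARN_DEFAULT):
    """Relax ``W`` toward ``alpha`` where ``alpha > 0``; leave it otherwise.

    The relaxation factor ``dt / tau`` is clipped at 1 so that ``dt = tau``
    (the default pairing) is an exact jump to the fixed point rather than an
    overshoot.
    """
    W = np.asarray(W)
    alpha = np.asarray(alpha)
    gate = alpha > 0
    factor = min(dt / tau, 1.0)
    return np.where(gate, W + factor * (alpha - W), W)


def calibration_input(W, s, k: float = K_DEFAULT) -> np.ndarray:
    """``b_j = k * sum_i w_ij s_i``, computed over the nonzero rows of s."""
    s = np.asarray(s)
    active = np.flatnonzero(s > 0)
    if active.size == 0:
        return np.zeros(W.shape[1])
    return k * (s[active].astype(W.dtype) @ W[active])
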