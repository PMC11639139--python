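"""Hard-coded linear map between test-cage and training-cage coordinates.

When the agent is moved from the (square) training cage to a linearly
deformed test cage, the place-cell code re-labels space: the PC that fired
at position ``h(p)`` in training fires at ``p`` in the test cage.  The
velocity fed to the grid network must be remapped accordingly or path
integration permanently contradicts the calibration drive.  For the
uniform-extent span regime (option ii) with constant WDC density the map is
the position-independent linear transform

    D = [[ s_x * sin(psi), -s_x * cos(psi)],
         [-s_y * sin(phi),  s_y * cos(phi)]]

and velocity transforms identically: ``g = h`` as linear maps.

The scale-factor subscripts carry a subtlety: each coordinate of ``h`` is a
wall distance whose WDC peaks scale with the extent *perpendicular to the
other wall*.  By default each scale factor is therefore the training/test
ratio of the extent governing that coordinate's peak placement (the first
row uses the wall_y extent ratio), which makes the PC-peak round trip
exact; ``convention="literal"`` swaps them to the published pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .environment import Environment


@dataclass(frozen=True)
class TransformSpec:
    """The 2x2 test->training coordinate map and its ingredients."""

    phi: float
    psi: float
    s_x: float
    s_y: float
    D: np.ndarray

    @classmethod
    def identity(cls) -> "TransformSpec":
        return cls(0.0, math.pi / 2, 1.0, 1.0, np.eye(2))


def build_transform(
    train_env: Environment,
    test_env: Environment,
    convention: str = "auto",
) -> TransformSpec:
    """Construct the linear map from the two cages' wall geometry.

    Valid only under the option (ii) + constant-density assumptions; for
    position-dependent spans no position-independent linear map exists and
    the caller should fall back to the identity transform with a raised
    calibration gain ``k``.
    """
    if convention not in ("auto", "literal"):
        raise ValueError(f"unknown transform convention {convention!r}")
    phi = test_env.phi
    psi = test_env.psi
    if convention == "literal":
        s_x = train_env.lx_max / test_env.lx_max
        s_y = train_env.ly_max / test_env.ly_max
    else:
        # first coordinate = distance to wall_y, whose peaks scale with the
        # wall_y extent; second likewise with the wall_x extent
        s_x = train_env.ly_max / test_env.ly_max
        s_y = train_env.lx_max / test_env.lx_max
    D = np.array(
        [
            [s_x * math.sin(psi), -s_x * math.cos(psi)],
            [-s_y * math.sin(phi), s_y * math.cos(phi)],
        ]
    )
    return TransformSpec(phi=phi, psi=psi, s_x=s_x, s_y=s_y, D=D)


def transform_position(T: TransformSpec, p) -> np.ndarray:
    """Training-cage position of the PC whose test-cage peak is at ``p``."""
    return T.D @ np.asarray(p, dtype=float)


def transform_velocity(T: TransformSpec, v) -> np.ndarray:
    """Agent-frame velocity ``g(v) = D v`` (position independent)."""
    return T.D @ np.asarray(v, dtype=float)
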