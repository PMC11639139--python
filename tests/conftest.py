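"""Shared fixtures.

The simulation regressions (stability, rectangle, trapezoid distortions)
are expensive, so each scenario is run once per session at a compact scale
and shared by every test that inspects it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gridcalib import analysis
from gridcalib.environment import default_trapezoid, make_environment
from gridcalib.experiments import (
    builtin_scenarios,
    run_stability,
    run_test,
    run_training,
    scaled,
)


@pytest.fixture()
def square20():
    return make_environment("square", 20.0)


@pytest.fixture()
def trapezoid():
    return default_trapezoid()


# -- session-scoped simulation runs ---------------------------------------

#: iteration counts for the in-suite regression runs; large enough for
#: usable rate maps at 1-unit bins, small enough for a CI-style budget.
SUITE_TRAIN = 80_000
SUITE_TEST = 110_000


@pytest.fixture(scope="session")
def linear_runs():
    """Square-trained, trapezoid-tested linear-distortion run (compact)."""
    cfg = scaled(
        builtin_scenarios()["trapezoid_linear"],
        n_train=SUITE_TRAIN,
        n_test=SUITE_TEST,
    )
    cfg = dataclasses.replace(cfg, bin_size=1.0)
    trained = run_training(cfg)
    test = run_test(cfg, trained)
    return {
        "config": cfg,
        "train_res": trained.train_result,
        "test_res": test,
        "train_map": trained.train_result.rate_map,
        "test_map": test.rate_map,
    }


@pytest.fixture(scope="session")
def nonlinear_runs():
    """Nonlinear-distortion run: exponential WDC density, option (i), k=3."""
    cfg = scaled(
        builtin_scenarios()["trapezoid_nonlinear"],
        n_train=180_000,
        n_test=200_000,
    )
    # finer bins than the other fixtures: the compressed vertical
    # wavelengths in the trapezoid approach 3 units
    cfg = dataclasses.replace(cfg, bin_size=0.75)
    trained = run_training(cfg)
    test = run_test(cfg, trained)
    return {
        "config": cfg,
        "train_res": trained.train_result,
        "test_res": test,
        "train_map": trained.train_result.rate_map,
        "test_map": test.rate_map,
    }


@pytest.fixture(scope="session")
def rectangle_runs():
    """Square-trained, half-width-rectangle-tested run."""
    cfg = scaled(
        builtin_scenarios()["rectangles"],
        n_train=60_000,
        n_test=80_000,
    )
    cfg = dataclasses.replace(cfg, bin_size=0.6)
    trained = run_training(cfg)
    test = run_test(cfg, trained)
    return {
        "config": cfg,
        "train_res": trained.train_result,
        "test_res": test,
        "train_map": trained.train_result.rate_map,
        "test_map": test.rate_map,
    }


@pytest.fixture(scope="session")
def stability_runs():
    """Calibrated vs uncalibrated traversal of the training square.

    Both arms share the identical trajectory and odometry-error
    realization; the run length and segment grid are chosen so that
    uncorrected drift blurs (without erasing) the field and every VAR
    segment collects several independent encounters.
    """
    cfg = scaled(builtin_scenarios()["stability"], n_train=150_000)
    cfg = dataclasses.replace(cfg, bin_size=1.0, snapshot_every=500)
    return {
        "on": run_stability(cfg, calibration=True, segments=60),
        "off": run_stability(cfg, calibration=False, segments=60),
    }


def hex_field(
    shape=(81, 81),
    spacing_bins: float = 10.0,
    angle_deg: float = 0.0,
    shear: float = 0.0,
    stretch_y: float = 1.0,
):
    """Synthetic hexagonal cosine-sum field (unit bins) for analysis oracles.

    Built from three plane waves 60 degrees apart, then linearly deformed:
    rotation by ``angle_deg``, horizontal shear, vertical stretch.
    """
    th = np.radians(angle_deg)
    A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    A = A @ np.array([[1.0, shear], [0.0, 1.0]])
    A = A @ np.diag([1.0, stretch_y])
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    # wavevectors of a regular hexagonal lattice with the given spacing
    kmag = 4.0 * np.pi / (np.sqrt(3.0) * spacing_bins)
    field = np.zeros(shape)
    Ainv_t = np.linalg.inv(A).T
    for ang in (0.0, np.pi / 3.0, 2.0 * np.pi / 3.0):
        k = kmag * np.array([np.cos(ang + np.pi / 2), np.sin(ang + np.pi / 2)])
        k = Ainv_t @ k
        field += np.cos(k[0] * ii + k[1] * jj)
    return field


def as_rate_map(values: np.ndarray, bin_size: float = 1.0) -> analysis.RateMap:
    """Wrap a dense array as a fully-visited RateMap (for analysis oracles)."""
    nx, ny = values.shape
    return analysis.RateMap(
        x_edges=np.arange(nx + 1) * bin_size,
        y_edges=np.arange(ny + 1) * bin_size,
        occupancy=np.ones_like(values),
        firing_sum=np.asarray(values, dtype=float),
    )
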