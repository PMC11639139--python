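"""Wall distance cells: peak placement, density normalization, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from gridcalib.wdc import (
    EXP_C2,
    DensitySpec,
    PeakTable,
    WDCVector,
    normalize_density,
    place_peaks_density,
    place_peaks_uniform,
    validate_density_approx,
    wdc_step,
)


def test_uniform_peaks_examples():
    np.testing.assert_allclose(place_peaks_uniform(4, 20.0), [5, 10, 15, 20])
    np.testing.assert_allclose(place_peaks_uniform(1, 7.0), [7.0])
    p = place_peaks_uniform(15, 20.0)
    np.testing.assert_allclose(np.diff(p), 4.0 / 3.0)


@given(n=st.integers(1, 200), l=st.floats(0.1, 100.0))
@settings(max_examples=50, deadline=None)
def test_uniform_peaks_scale_equivariance(n, l):
    """Doubling the span doubles every constant-density peak."""
    p1 = place_peaks_uniform(n, l)
    p2 = place_peaks_uniform(n, 2.0 * l)
    np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-12)
    assert np.all(np.diff(p1) > 0) or n == 1
    assert p1[-1] == pytest.approx(l)


def test_exponential_default_matches_printed_anchors():
    f = DensitySpec("exponential")
    assert f(0.0) == pytest.approx(1.0)
    assert f(0.5) == pytest.approx(0.1)
    assert EXP_C2 == pytest.approx(2.0 * np.log(0.1))


def test_normalize_density_constant():
    f = DensitySpec("constant", c1=3.7)
    fp = normalize_density(f, n=10, l=25.0, l_max=25.0)
    np.testing.assert_allclose(fp(np.linspace(0, 1, 7)), 10.0 / 25.0)


def test_normalize_density_preserves_exponential_ratio():
    fp = normalize_density(DensitySpec("exponential"), 130, 30.0, 30.0)
    assert fp(0.0) / fp(1.0) == pytest.approx(100.0)


def test_normalize_density_quadrature_matches_antiderivative():
    """Adaptive quadrature agrees with the closed-form exponential integral."""
    c2 = EXP_C2
    for l, l_max in ((30.0, 30.0), (17.0, 30.0), (9.5, 28.46)):
        fp = normalize_density(DensitySpec("exponential"), 130, l, l_max)
        exact = l_max / c2 * (np.exp(c2 * l / l_max) - 1.0)
        assert fp(0.3) == pytest.approx(
            np.exp(c2 * 0.3) * 130 / exact, rel=1e-8
        )


def test_density_placement_constant_equals_uniform():
    f = DensitySpec("constant")
    np.testing.assert_allclose(
        place_peaks_density(f, 15, 20.0, 20.0),
        place_peaks_uniform(15, 20.0),
        atol=1e-9,
    )


def test_density_placement_spacing_increases_for_decaying_density():
    p = place_peaks_density(DensitySpec("exponential"), 130, 30.0, 30.0)
    gaps = np.diff(p)
    assert np.all(gaps > 0)
    assert np.all(np.diff(gaps) > 0)


def test_density_placement_matches_inverse_cdf_oracle():
    """Realized spacings match the equal-mass inverse-CDF oracle locally.

    The recursion freezes the density at each interval's left end, so its
    *local* spacing tracks the oracle's to a few percent while cumulative
    positions drift for steep densities (that drift is exactly what the
    mean-relative-deviation validation quantifies).
    """
    n, l = 130, 30.0
    f = DensitySpec("exponential")
    fp = normalize_density(f, n, l, l)
    from scipy.integrate import quad

    def cdf(x):
        return quad(lambda u: float(fp(u / l)), 0.0, x)[0]

    total = cdf(l)
    oracle = np.array(
        [brentq(lambda x, i=i: cdf(x) - total * i / n, 0.0, l) for i in range(1, n + 1)]
    )
    peaks = place_peaks_density(f, n, l, l)
    ext = np.concatenate([[0.0], peaks])
    gaps = np.diff(ext)
    mids = (ext[:-1] + ext[1:]) / 2.0
    target = 1.0 / fp(mids / l)  # oracle's local spacing at the same place
    rel = np.abs(gaps - target) / target
    assert rel.mean() < 0.03  # same scale as the Eq.-7 validation statistic
    assert rel.max() < 0.15   # worst interval sits at the sparse end
    # forward placement undershoots a growing-spacing profile everywhere
    assert np.all(peaks <= oracle + 1e-9)
    # both place the same first peak to first order
    assert peaks[0] == pytest.approx(oracle[0], rel=0.02)


def test_validate_density_constant_is_exact():
    f = DensitySpec("constant")
    peaks = place_peaks_density(f, 20, 10.0, 10.0)
    fp = normalize_density(f, 20, 10.0, 10.0)
    assert validate_density_approx(peaks, fp, 10.0) == pytest.approx(0.0, abs=1e-12)


def test_validate_density_error_shrinks_with_n():
    f = DensitySpec("exponential")
    eps = []
    for n in (30, 300):
        peaks = place_peaks_density(f, n, 30.0, 30.0)
        fp = normalize_density(f, n, 30.0, 30.0)
        eps.append(validate_density_approx(peaks, fp, 30.0))
    assert eps[1] < eps[0]


def test_peak_table_interpolates_recursion(trapezoid):
    table = PeakTable(DensitySpec("exponential"), 130, trapezoid.lx_max)
    for l in (12.0, 20.0, 28.0):
        direct = place_peaks_density(DensitySpec("exponential"), 130, l, trapezoid.lx_max)
        np.testing.assert_allclose(table(l), direct, atol=0.02)


def test_wdc_step_single_step_values():
    v = WDCVector(axis="x", peaks=[5.0, 10.0, 15.0, 20.0])
    v.state[:] = [0.0, 1.0, 0.0, 0.0]
    wdc_step(v, d=4.9, dt=0.01)  # nearest peak is 5 -> neuron 0
    assert v.state[0] == pytest.approx(0.2)
    assert v.state[1] == pytest.approx(0.8)
    assert v.state[2] == pytest.approx(0.0)


def test_wdc_nearest_partition_unique_target():
    """Exactly one neuron is driven toward 1 for any distance in the span."""
    v = WDCVector(axis="x", peaks=place_peaks_uniform(15, 20.0))
    for d in np.linspace(0.0, 20.0, 301):
        assert v.target(d).sum() == 1.0
    # midpoint belongs to the lower neuron (upper-closed intervals)
    mid = (v.peaks[3] + v.peaks[4]) / 2.0
    assert v.target(mid)[3] == 1.0
    assert v.target(np.nextafter(mid, 21.0))[4] == 1.0


def test_wdc_radius_mode_multiple_active():
    v = WDCVector(axis="y", peaks=[1.0, 1.5, 2.0, 8.0], activation="radius", r=1.0)
    assert v.target(1.4).tolist() == [1.0, 1.0, 1.0, 0.0]
    assert v.target(7.2).tolist() == [0.0, 0.0, 0.0, 1.0]
    assert v.target(5.0).sum() == 0.0


@given(st.floats(0.0, 25.0))
@settings(max_examples=40, deadline=None)
def test_wdc_state_stays_in_unit_interval(d):
    v = WDCVector(axis="x", peaks=place_peaks_uniform(10, 25.0))
    rng = np.random.default_rng(0)
    v.state[:] = rng.uniform(0, 1, 10)
    for _ in range(30):
        wdc_step(v, d, dt=0.01)
    assert np.all(v.state >= 0.0) and np.all(v.state <= 1.0)


def test_wdc_step_rejects_bad_arguments():
    v = WDCVector(axis="x", peaks=[1.0, 2.0])
    with pytest.raises(ValueError):
        wdc_step(v, d=-0.1, dt=0.01)
    with pytest.raises(ValueError):
        wdc_step(v, d=1.0, dt=1.0)
    with pytest.raises(ValueError):
        WDCVector(axis="x", peaks=[2.0, 1.0])
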