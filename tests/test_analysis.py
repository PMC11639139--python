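"""Analysis stack: rate maps, autocorrelograms, grid metrics, stability."""

import numpy as np
import pytest

from gridcalib import analysis
from gridcalib.analysis import (
    Profile,
    accumulate_rate_map,
    autocorr_peaks,
    autocorrelogram,
    detect_peaks,
    ellipticity,
    firing_variance,
    inner_peaks,
    mean_nearest_peak_distance,
    mean_wavelength,
    orientation,
    profile_mse,
)

from .conftest import as_rate_map, hex_field


# -- rate maps -------------------------------------------------------------

def test_rate_map_constant_firing():
    rng = np.random.default_rng(0)
    pos = rng.uniform(0, 10, (5000, 2))
    rm = accumulate_rate_map(pos, np.ones(5000), (0, 10, 0, 10), bin_size=1.0)
    v = rm.values
    assert np.nanmax(v) == pytest.approx(1.0)
    assert np.nanmin(v) == pytest.approx(1.0)


def test_rate_map_indicator_of_left_half():
    rng = np.random.default_rng(1)
    pos = rng.uniform(0, 10, (20000, 2))
    firing = (pos[:, 0] < 5).astype(float)
    rm = accumulate_rate_map(pos, firing, (0, 10, 0, 10), bin_size=1.0)
    v = rm.values
    assert np.allclose(v[:5], 1.0)
    assert np.allclose(v[5:], 0.0)


def test_rate_map_order_invariance():
    rng = np.random.default_rng(2)
    pos = rng.uniform(0, 5, (1000, 2))
    firing = rng.uniform(0, 1, 1000)
    perm = rng.permutation(1000)
    a = accumulate_rate_map(pos, firing, (0, 5, 0, 5), bin_size=0.5)
    b = accumulate_rate_map(pos[perm], firing[perm], (0, 5, 0, 5), bin_size=0.5)
    np.testing.assert_allclose(a.values, b.values, equal_nan=True)


def test_rate_map_empty_firing_rejected():
    with pytest.raises(ValueError):
        accumulate_rate_map(np.zeros((0, 2)), np.array([]), (0, 1, 0, 1))


# -- autocorrelogram -------------------------------------------------------

def test_autocorr_white_noise_decorrelates():
    rng = np.random.default_rng(3)
    rm = as_rate_map(rng.normal(size=(60, 60)))
    ac = autocorrelogram(rm)
    ci, cj = ac.center
    assert ac.values[ci, cj] == pytest.approx(1.0)
    ring = ac.values[ci - 15 : ci + 16, cj - 15 : cj + 16].copy()
    ring[12:19, 12:19] = np.nan  # mask the center
    assert np.nanmax(np.abs(ring)) < 0.15


def test_autocorr_hexagonal_field_has_six_first_ring_peaks():
    rm = as_rate_map(hex_field(spacing_bins=12.0))
    ac = autocorrelogram(rm)
    ring = inner_peaks(autocorr_peaks(ac), 6)
    assert len(ring) == 6
    radii = np.hypot(ring[:, 0], ring[:, 1])
    np.testing.assert_allclose(radii, 12.0, rtol=0.08)


def test_autocorr_point_symmetry():
    rng = np.random.default_rng(4)
    rm = as_rate_map(rng.uniform(size=(31, 41)))
    ac = autocorrelogram(rm)
    v = ac.values
    np.testing.assert_allclose(v, v[::-1, ::-1], atol=1e-8, equal_nan=True)


def test_autocorr_respects_minimum_overlap_mask():
    rm = as_rate_map(np.ones((10, 10)))
    ac = autocorrelogram(rm, min_overlap=20)
    # extreme displacements overlap in < 20 bins -> masked
    assert np.isnan(ac.values[0, 0])


def test_autocorr_rejects_degenerate_map():
    with pytest.raises(ValueError):
        autocorrelogram(as_rate_map(np.full((5, 5), np.nan)))


# -- peak detection --------------------------------------------------------

def test_detect_single_gaussian_bump():
    ii, jj = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
    field = np.exp(-((ii - 17.3) ** 2 + (jj - 24.6) ** 2) / 20.0)
    pk = detect_peaks(field, smoothing=1.0)
    assert len(pk) == 1
    np.testing.assert_allclose(pk[0], (17.3, 24.6), atol=1.0)


def test_detect_peaks_threshold_above_max_is_empty():
    field = np.random.default_rng(0).uniform(size=(20, 20))
    assert len(detect_peaks(field, threshold=2.0)) == 0


def test_detect_peaks_min_separation_suppresses_duplicates():
    field = np.zeros((40, 40))
    field[10, 10] = 1.0
    field[10, 12] = 0.9
    field[30, 30] = 0.8
    pk = detect_peaks(field, smoothing=0.8, min_separation=5.0)
    assert len(pk) == 2


# -- grid metrics ----------------------------------------------------------

def test_ellipticity_zero_for_regular_hexagon():
    ang = np.radians(np.arange(6) * 60.0 + 13.0)
    ring = 7.0 * np.column_stack([np.cos(ang), np.sin(ang)])
    assert ellipticity(ring) == pytest.approx(0.0, abs=1e-6)


def test_ellipticity_of_doubled_axis_hexagon():
    """Stretching one axis x2 gives eccentricity sqrt(1 - 1/4) = 0.866."""
    ang = np.radians(np.arange(6) * 60.0)
    ring = np.column_stack([2.0 * np.cos(ang), np.sin(ang)])
    assert ellipticity(ring) == pytest.approx(np.sqrt(0.75), abs=1e-9)


def test_ellipticity_requires_five_peaks():
    with pytest.raises(ValueError):
        ellipticity(np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]]))


def test_orientation_recovers_injected_rotation():
    for angle in (0.0, 7.0, -11.0, 23.0):
        rm = as_rate_map(hex_field(spacing_bins=11.0, angle_deg=angle))
        ring = inner_peaks(autocorr_peaks(autocorrelogram(rm)), 6)
        assert orientation(ring) == pytest.approx(angle, abs=0.5)


def test_orientation_region_matches_whole_map():
    """Translation invariance: a wide sub-region reports the same angle."""
    rm = as_rate_map(hex_field(shape=(101, 101), spacing_bins=11.0, angle_deg=7.0))
    whole = orientation(inner_peaks(autocorr_peaks(autocorrelogram(rm)), 6))
    sub = rm.restrict_x(10.0, 70.0)
    part = orientation(inner_peaks(autocorr_peaks(autocorrelogram(sub)), 6))
    assert part == pytest.approx(whole, abs=0.5)


def test_orientation_negates_under_mirror():
    f = hex_field(spacing_bins=11.0, angle_deg=9.0)
    a = orientation(inner_peaks(autocorr_peaks(autocorrelogram(as_rate_map(f))), 6))
    b = orientation(
        inner_peaks(autocorr_peaks(autocorrelogram(as_rate_map(f[:, ::-1]))), 6)
    )
    assert b == pytest.approx(-a, abs=0.5)


def test_mean_wavelength_recovers_cosine_wavelength():
    """E[W] converges to lambda for a pure 2-D cosine (3% tolerance)."""
    lam = 12.0
    ii, jj = np.meshgrid(np.arange(121), np.arange(121), indexing="ij")
    field = np.cos(2 * np.pi * ii / lam) + np.cos(2 * np.pi * jj / lam)
    ac = autocorrelogram(as_rate_map(field))
    assert mean_wavelength(ac) == pytest.approx(lam, rel=0.03)


def test_mean_wavelength_scales_with_bin_size():
    field = hex_field(spacing_bins=10.0)
    ac1 = autocorrelogram(as_rate_map(field, bin_size=1.0))
    ac2 = autocorrelogram(as_rate_map(field, bin_size=2.5))
    assert mean_wavelength(ac2) == pytest.approx(2.5 * mean_wavelength(ac1), rel=1e-6)


def test_mean_wavelength_requires_square_bins():
    ac = autocorrelogram(as_rate_map(hex_field()))
    ac.dx = 2 * ac.dy
    with pytest.raises(ValueError):
        mean_wavelength(ac)


def test_nearest_peak_distance_cases():
    assert mean_nearest_peak_distance(np.array([[0, 0], [3, 0]])) == 3.0
    g = np.array([[i, j] for i in range(5) for j in range(5)], dtype=float) * 2.0
    assert mean_nearest_peak_distance(g) == pytest.approx(2.0)
    # hexagonal lattice with spacing a (allow edge-truncation tolerance)
    a = 4.0
    pts = []
    for i in range(-4, 5):
        for j in range(-4, 5):
            pts.append([a * (i + 0.5 * j), a * np.sqrt(3) / 2 * j])
    assert mean_nearest_peak_distance(np.array(pts)) == pytest.approx(a, rel=1e-6)
    with pytest.raises(ValueError):
        mean_nearest_peak_distance(np.array([[0.0, 0.0]]))


def test_metric_recovery_across_deformation_sweep():
    """Ellipticity/orientation/wavelength recover synthetic deformations."""
    for shear in (0.0, 0.25, 0.5):
        for angle in (0.0, 15.0, 30.0):
            rm = as_rate_map(
                hex_field(shape=(101, 101), spacing_bins=11.0,
                          angle_deg=angle, shear=shear)
            )
            ring = inner_peaks(autocorr_peaks(autocorrelogram(rm)), 6)
            # expected ellipse: unit circle mapped by rotation @ shear
            th = np.radians(angle)
            A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            A = A @ np.array([[1.0, shear], [0.0, 1.0]])
            sv = np.linalg.svd(A, compute_uv=False)
            expected_ecc = np.sqrt(1.0 - (sv[1] / sv[0]) ** 2)
            assert ellipticity(ring) == pytest.approx(expected_ecc, abs=0.05)


# -- profiles, MSE, VAR ----------------------------------------------------

def test_field_profile_of_gaussian_bump_lattice():
    """Profile of identical Gaussian bumps equals the radial bump shape."""
    shape = (90, 90)
    spacing = 15.0
    sigma = 2.5
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    field = np.zeros(shape)
    centers = []
    for a in range(1, 6):
        for b in range(1, 6):
            c = (a * spacing, b * spacing)
            centers.append(c)
            field += np.exp(-((ii - c[0]) ** 2 + (jj - c[1]) ** 2) / (2 * sigma**2))
    prof = analysis.field_profile(as_rate_map(field), smoothing=0.0)
    ok = np.isfinite(prof.values) & (prof.centers < 0.45)
    expected = np.exp(-((prof.centers[ok] * spacing) ** 2) / (2 * sigma**2))
    np.testing.assert_allclose(prof.values[ok], expected, atol=0.06)
    # the zero-distance bin holds the bump-height average
    first = np.flatnonzero(np.isfinite(prof.values))[0]
    assert prof.values[first] == pytest.approx(1.0, abs=0.05)


def test_sheet_profile_consistent_with_field_profile():
    """The sheet pattern analysed as a field gives the same profile shape."""
    field = np.maximum(hex_field(shape=(64, 64), spacing_bins=8.0), 0.0)
    sheet = analysis.sheet_profile([field])
    fieldp = analysis.field_profile(as_rate_map(field), smoothing=0.0)
    both = np.isfinite(sheet.values) & np.isfinite(fieldp.values)
    assert both.sum() >= 15  # torus distances cap near 0.6 relative units
    # small offsets on the steep flank come from peak quantization and the
    # wraparound metric; 0.25 is ~8% of the bump amplitude
    np.testing.assert_allclose(
        sheet.values[both], fieldp.values[both], atol=0.25
    )


def test_profile_mse_cases():
    c = np.linspace(0.0, 1.5, 50)
    a = Profile(centers=c, values=np.sin(c))
    assert profile_mse(a, a) == pytest.approx(0.0)
    b = Profile(centers=c, values=np.sin(c) + 0.3)
    assert profile_mse(a, b) == pytest.approx(0.09, abs=1e-12)
    coarse = Profile(centers=c[::2], values=np.sin(c[::2]) + 0.3)
    assert profile_mse(a, coarse) == pytest.approx(0.09, abs=1e-3)


def test_firing_variance_constant_is_zero():
    rng = np.random.default_rng(5)
    pos = rng.uniform(0, 10, (2000, 2))
    assert firing_variance(pos, np.ones(2000), (0, 10, 0, 10), segments=20) == 0.0


def test_firing_variance_alternating_bernoulli():
    """Fair 0/1 across encounters of every segment has variance 1/4."""
    pos = np.tile(np.array([[1.0, 1.0], [5.0, 5.0]]), (100, 1))
    firing = np.tile([0.0, 0.0, 1.0, 1.0], 50)  # each segment sees 0,1,0,1,...
    assert firing_variance(pos, firing, (0, 10, 0, 10), segments=10) == pytest.approx(0.25)


def test_firing_variance_matches_two_pass_oracle():
    """Encounter accumulation equals an explicit per-segment variance, 1e-12.

    Rates are sampled once per entry into a segment; the oracle replays the
    trajectory, collects entry samples, and applies the population-variance
    formula segment by segment.
    """
    rng = np.random.default_rng(6)
    pos = rng.uniform(0, 4, (5000, 2))
    firing = rng.uniform(0, 2, 5000)
    segs = 8
    got = firing_variance(pos, firing, (0, 4, 0, 4), segments=segs)
    edges = np.linspace(0, 4, segs + 1)
    ix = np.clip(np.digitize(pos[:, 0], edges) - 1, 0, segs - 1)
    iy = np.clip(np.digitize(pos[:, 1], edges) - 1, 0, segs - 1)
    samples: dict[tuple[int, int], list[float]] = {}
    prev = None
    for t in range(len(pos)):
        key = (ix[t], iy[t])
        if key != prev:
            samples.setdefault(key, []).append(firing[t])
        prev = key
    vs = [
        np.mean((np.array(v) - np.mean(v)) ** 2)
        for v in samples.values()
        if len(v) >= 2
    ]
    assert got == pytest.approx(np.mean(vs), abs=1e-12)


def test_metrics_invariant_to_rate_rescaling():
    field = hex_field(spacing_bins=10.0, shear=0.2)
    m1 = analysis.grid_metrics(as_rate_map(field + 2.0))
    m2 = analysis.grid_metrics(as_rate_map(5.0 * (field + 2.0)))
    assert m1.ellipticity == pytest.approx(m2.ellipticity, abs=1e-9)
    assert m1.orientation_deg == pytest.approx(m2.orientation_deg, abs=1e-9)
    assert m1.mean_wavelength == pytest.approx(m2.mean_wavelength, rel=1e-9)
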