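"""Derived statistics: rate maps, autocorrelograms, grid and stability metrics.

The distortion analyses all start from a time-accumulated spatial rate map
of one grid cell.  From its spatial autocorrelogram we measure

* ellipticity — eccentricity of the ellipse fitted to the six inner peaks
  (0 for a regular hexagonal grid),
* orientation — angle of the grid axis closest to horizontal,
* mean wavelength — the amplitude-weighted mean reciprocal frequency
  magnitude of the autocorrelogram's 2-D Fourier spectrum,
* mean nearest-peak distance — from the firing peaks themselves,

and the stability analysis compares the firing-vs-relative-distance profile
of the spatial field against the same profile measured on the neuron sheet,
via their mean squared error, plus the per-location firing variance VAR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# rate maps

@dataclass
class RateMap:
    """Binned mean firing over space (defined only where occupancy > 0)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray    # (nx, ny) visit counts
    firing_sum: np.ndarray   # (nx, ny) summed rates

    @property
    def values(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.firing_sum / self.occupancy
        v[self.occupancy == 0] = np.nan
        return v

    @property
    def dx(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])

    @property
    def dy(self) -> float:
        return float(self.y_edges[1] - self.y_edges[0])

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def restrict_x(self, lo: float, hi: float) -> "RateMap":
        """Sub-map over an x-interval (used for per-half analyses)."""
        keep = (self.x_centers >= lo) & (self.x_centers <= hi)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            raise ValueError("empty x-interval")
        sl = slice(idx[0], idx[-1] + 1)
        return RateMap(
            x_edges=self.x_edges[idx[0] : idx[-1] + 2],
            y_edges=self.y_edges,
            occupancy=self.occupancy[sl],
            firing_sum=self.firing_sum[sl],
        )

    def smoothed(self, sigma: float = 1.0) -> np.ndarray:
        """Occupancy-aware Gaussian-smoothed values (NaN outside coverage)."""
        return _nan_gaussian(self.values, sigma)

    def to_text(self, path) -> None:
        np.savetxt(path, self.values, delimiter="\t",
                   header=f"dx={self.dx} dy={self.dy}", comments="# ")


def accumulate_rate_map(
    positions: np.ndarray,
    firing: np.ndarray,
    extent: tuple[float, float, float, float],
    bin_size: float = 0.5,
) -> RateMap:
    """Per-bin mean of ``firing`` over visits.

    ``positions`` may be longer than ``firing`` by one (a trajectory's final
    position has no associated step); ``extent = (x0, x1, y0, y1)`` is the
    environment bounding box, binned squarely at ``bin_size``.
    """
    firing = np.asarray(firing, dtype=float)
    if firing.size == 0:
        raise ValueError("empty firing series")
    pos = np.asarray(positions, dtype=float)[: len(firing)]
    x0, x1, y0, y1 = extent
    x_edges = np.arange(x0, x1 + bin_size * 0.5, bin_size)
    y_edges = np.arange(y0, y1 + bin_size * 0.5, bin_size)
    occ, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=(x_edges, y_edges))
    tot, _, _ = np.histogram2d(
        pos[:, 0], pos[:, 1], bins=(x_edges, y_edges), weights=firing
    )
    return RateMap(x_edges=x_edges, y_edges=y_edges, occupancy=occ, firing_sum=tot)


def _nan_gaussian(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaN bins (normalized convolution)."""
    if sigma <= 0:
        return values.copy()
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 1e-12] = np.nan
    return out


# ---------------------------------------------------------------------------
# autocorrelogram

@dataclass
class Autocorrelogram:
    values: np.ndarray  # (2nx-1, 2ny-1), NaN where overlap is insufficient
    dx: float
    dy: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


def autocorrelogram(
    rate_map: RateMap | np.ndarray,
    dx: float | None = None,
    dy: float | None = None,
    min_overlap: int = 20,
    smoothing: float = 0.0,
) -> Autocorrelogram:
    """Pearson spatial autocorrelation at every displacement.

    Unvisited bins are excluded from every displacement's sample, and
    displacements with fewer than ``min_overlap`` overlapping bins are
    masked to NaN.  The zero-displacement value is exactly 1 wherever
    defined.
    """
    if isinstance(rate_map, RateMap):
        v = rate_map.smoothed(smoothing) if smoothing > 0 else rate_map.values
        dx, dy = rate_map.dx, rate_map.dy
    else:
        v = np.asarray(rate_map, dtype=float)
        dx = 1.0 if dx is None else dx
        dy = dx if dy is None else dy
    mask = np.isfinite(v).astype(float)
    if mask.sum() < 2:
        raise ValueError("rate map needs at least 2 visited bins")
    x = np.where(np.isfinite(v), v, 0.0)

    def xcorr(a, b):
        return signal.fftconvolve(a, b[::-1, ::-1], mode="full")

    n = xcorr(mask, mask)
    sx = xcorr(x, mask)
    sy = xcorr(mask, x)
    sxy = xcorr(x, x)
    sxx = xcorr(x * x, mask)
    syy = xcorr(mask, x * x)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt(n * sxx - sx**2) * np.sqrt(n * syy - sy**2)
        r = num / den
    r[np.round(n) < min_overlap] = np.nan
    r[~np.isfinite(r)] = np.nan
    return Autocorrelogram(values=r, dx=dx, dy=dy)


# ---------------------------------------------------------------------------
# peak detection

def detect_peaks(
    values: np.ndarray,
    dx: float = 1.0,
    dy: float = 1.0,
    smoothing: float = 1.0,
    min_separation: float = 0.0,
    threshold: float | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Local maxima of a (possibly NaN-masked) array, in physical coordinates.

    Peaks are detected after Gaussian smoothing, refined to sub-bin accuracy
    by a quadratic fit, thresholded (default: 20% of the smoothed maximum)
    and non-maximum-suppressed within ``min_separation`` (physical units).
    Returns an (m, 2) array of (x, y) coordinates; possibly empty.
    """
    v = _nan_gaussian(np.asarray(values, dtype=float), smoothing)
    finite = np.isfinite(v)
    if not finite.any():
        return np.empty((0, 2))
    vf = np.where(finite, v, -np.inf)
    if threshold is None:
        threshold = 0.2 * vf.max()
    footprint = ndimage.maximum_filter(vf, size=3, mode="nearest")
    is_peak = (vf >= footprint) & finite & (vf > threshold)
    coords = np.argwhere(is_peak)
    if coords.size == 0:
        return np.empty((0, 2))
    heights = vf[is_peak]
    order = np.argsort(heights)[::-1]
    coords = coords[order].astype(float)

    # sub-bin quadratic refinement along each axis
    for p in coords:
        i, j = int(p[0]), int(p[1])
        for axis, k in ((0, i), (1, j)):
            if 0 < k < v.shape[axis] - 1:
                if axis == 0:
                    triple = v[k - 1 : k + 2, j]
                else:
                    triple = v[i, k - 1 : k + 2]
                if np.all(np.isfinite(triple)):
                    denom = triple[0] - 2 * triple[1] + triple[2]
                    if denom < 0:
                        p[axis] += 0.5 * (triple[0] - triple[2]) / denom

    xy = np.column_stack(
        [origin[0] + coords[:, 0] * dx, origin[1] + coords[:, 1] * dy]
    )
    if min_separation > 0 and len(xy) > 1:
        kept = []
        for p in xy:  # greedy NMS in height order
            if all(np.hypot(*(p - q)) >= min_separation for q in kept):
                kept.append(p)
        xy = np.array(kept)
    return xy


def autocorr_peaks(
    ac: Autocorrelogram,
    smoothing: float = 1.0,
    min_separation: float | None = None,
    threshold: float = 0.1,
) -> np.ndarray:
    """Peaks of an autocorrelogram as displacements relative to its center."""
    ci, cj = ac.center
    pk = detect_peaks(
        ac.values,
        dx=ac.dx,
        dy=ac.dy,
        smoothing=smoothing,
        min_separation=min_separation if min_separation is not None else 2.0 * ac.dx,
        threshold=threshold,
        origin=(-ci * ac.dx, -cj * ac.dy),
    )
    return pk


def inner_peaks(peaks: np.ndarray, n: int = 6, r_min: float = 1e-6) -> np.ndarray:
    """The ``n`` peaks nearest the origin, excluding the origin itself."""
    r = np.hypot(peaks[:, 0], peaks[:, 1])
    keep = peaks[r > r_min]
    r = r[r > r_min]
    order = np.argsort(r)
    return keep[order[:n]]


# ---------------------------------------------------------------------------
# grid metrics

@dataclass
class GridMetrics:
    ellipticity: float
    orientation_deg: float
    mean_wavelength: float
    mean_nearest_peak_distance: float


def ellipticity(ring_peaks: np.ndarray) -> float:
    """Eccentricity of the least-squares ellipse through the inner peaks.

    Fits the centered conic ``a x^2 + b xy + c y^2 = 1`` (the
    autocorrelogram is point symmetric, so the ellipse is centered); returns
    ``sqrt(1 - (b/a)^2)`` for semi-axes ``a >= b``.  Requires at least 5
    peaks; 0 for a regular hexagon.
    """
    p = np.asarray(ring_peaks, dtype=float)
    if len(p) < 5:
        raise ValueError("ellipse fit needs at least 5 peaks")
    M = np.column_stack([p[:, 0] ** 2, p[:, 0] * p[:, 1], p[:, 1] ** 2])
    coef, *_ = np.linalg.lstsq(M, np.ones(len(p)), rcond=None)
    a, b, c = coef
    conic = np.array([[a, b / 2.0], [b / 2.0, c]])
    ev = np.linalg.eigvalsh(conic)
    if ev[0] <= 0:
        raise ValueError("fitted conic is not an ellipse")
    ratio = ev[0] / ev[1]  # = (b_semi / a_semi)^2
    return float(np.sqrt(1.0 - ratio))


def orientation(ring_peaks: np.ndarray) -> float:
    """Grid-axis angle (degrees) closest to the horizontal.

    Each inner peak defines an axis with angle folded to (-90, 90]; the one
    with the smallest absolute angle is returned.
    """
    p = np.asarray(ring_peaks, dtype=float)
    if len(p) == 0:
        raise ValueError("no peaks")
    ang = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    ang = (ang + 90.0) % 180.0 - 90.0
    return float(ang[np.argmin(np.abs(ang))])


def mean_wavelength(ac: Autocorrelogram) -> float:
    """Amplitude-weighted mean wavelength of the autocorrelogram spectrum.

    Crops the autocorrelogram to a centered square (equal bin sizes are
    required so frequencies form a square grid), applies a Hann window
    (without it, spectral leakage weighted by the diverging 1/f wavelength
    factor biases the estimate by 5-20%), takes the 2-D DFT, and averages
    ``(fx^2 + fy^2)^(-1/2)`` weighted by spectral amplitude.  The DC
    component, whose wavelength diverges, is excluded from both the sum and
    the normalization.
    """
    if not np.isclose(ac.dx, ac.dy, rtol=1e-6):
        raise ValueError("square frequency grid requires equal bin sizes")
    v = ac.values
    m = min(v.shape)
    if m % 2 == 0:
        m -= 1
    ci, cj = ac.center
    h = m // 2
    v = v[ci - h : ci + h + 1, cj - h : cj + h + 1]
    v = np.where(np.isfinite(v), v, 0.0)
    if not v.any():
        raise ValueError("empty autocorrelogram")
    win = np.hanning(m)
    P = np.abs(np.fft.fft2(v * win[:, None] * win[None, :]))
    fx = np.fft.fftfreq(m, d=ac.dx)
    fy = np.fft.fftfreq(m, d=ac.dy)
    f2 = fx[:, None] ** 2 + fy[None, :] ** 2
    P[0, 0] = 0.0  # DC excluded
    with np.errstate(divide="ignore"):
        wav = np.where(f2 > 0, 1.0 / np.sqrt(f2), 0.0)
    sp = P.sum()
    if sp <= 0:
        raise ValueError("all-zero spectrum")
    return float((P * wav).sum() / sp)


def mean_nearest_peak_distance(peaks: np.ndarray) -> float:
    """Mean over peaks of the distance to the nearest other peak."""
    p = np.asarray(peaks, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 peaks")
    d = cdist(p, p)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def grid_metrics(
    rate_map: RateMap,
    smoothing: float = 0.0,
    field_peak_smoothing: float = 1.0,
    field_peak_threshold: float = 0.3,
) -> GridMetrics:
    """All four distortion metrics of one rate map.

    The autocorrelogram is computed on the raw (optionally pre-smoothed)
    map; peak detection applies its own one-bin smoothing, so extra map
    smoothing is usually counterproductive.
    """
    ac = autocorrelogram(rate_map, smoothing=smoothing)
    ring = inner_peaks(autocorr_peaks(ac), 6)
    v = rate_map.smoothed(field_peak_smoothing)
    fp = detect_peaks(
        v,
        dx=rate_map.dx,
        dy=rate_map.dy,
        smoothing=0.0,
        min_separation=2.0,
        threshold=field_peak_threshold * np.nanmax(v),
        origin=(rate_map.x_centers[0], rate_map.y_centers[0]),
    )
    return GridMetrics(
        ellipticity=ellipticity(ring),
        orientation_deg=orientation(ring),
        mean_wavelength=mean_wavelength(ac),
        mean_nearest_peak_distance=mean_nearest_peak_distance(fp),
    )


# ---------------------------------------------------------------------------
# stability: profiles, MSE, VAR

@dataclass
class Profile:
    """Mean firing as a function of relative distance to the nearest peak.

    Relative distance = absolute distance divided by the mean distance
    between neighboring firing peaks.
    """

    centers: np.ndarray
    values: np.ndarray


PROFILE_BINS = 50
PROFILE_MAX = 1.5


def _profile_from_samples(dist_rel, firing, n_bins, r_max):
    edges = np.linspace(0.0, r_max, n_bins + 1)
    idx = np.clip(np.digitize(dist_rel, edges) - 1, 0, n_bins - 1)
    keep = dist_rel <= r_max
    cnt = np.bincount(idx[keep], minlength=n_bins)
    tot = np.bincount(idx[keep], weights=firing[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = tot / cnt
    vals[cnt == 0] = np.nan
    return Profile(centers=0.5 * (edges[:-1] + edges[1:]), values=vals)


def field_profile(
    rate_map: RateMap,
    smoothing: float = 1.0,
    n_bins: int = PROFILE_BINS,
    r_max: float = PROFILE_MAX,
) -> Profile:
    """Profile of a spatial firing field around its detected peaks."""
    v = rate_map.smoothed(smoothing)
    peaks = detect_peaks(
        v,
        dx=rate_map.dx,
        dy=rate_map.dy,
        smoothing=0.0,
        min_separation=2.0,
        threshold=0.3 * np.nanmax(v),
        origin=(rate_map.x_centers[0], rate_map.y_centers[0]),
    )
    if len(peaks) < 2:
        raise ValueError("too few firing peaks for a profile")
    spacing = mean_nearest_peak_distance(peaks)
    xx, yy = np.meshgrid(rate_map.x_centers, rate_map.y_centers, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    vals = rate_map.values.ravel()
    ok = np.isfinite(vals)
    d = cdist(pts[ok], peaks).min(axis=1) / spacing
    return _profile_from_samples(d, vals[ok], n_bins, r_max)


def sheet_profile(
    snapshots,
    n_bins: int = PROFILE_BINS,
    r_max: float = PROFILE_MAX,
) -> Profile:
    """Profile of the neuron-sheet activity pattern, averaged over snapshots.

    Distances are Euclidean between sheet index tuples with wraparound;
    bump centers are detected per snapshot on the periodically padded sheet.
    """
    acc_cnt = np.zeros(n_bins)
    acc_tot = np.zeros(n_bins)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    for s in snapshots:
        s = np.asarray(s, dtype=float)
        n = s.shape[0]
        tiled = np.tile(s, (3, 3))
        pk = detect_peaks(tiled, smoothing=1.0, min_separation=2.0,
                          threshold=0.3 * s.max())
        pk = pk[
            (pk[:, 0] >= n) & (pk[:, 0] < 2 * n)
            & (pk[:, 1] >= n) & (pk[:, 1] < 2 * n)
        ] - n
        if len(pk) < 2:
            continue
        # min-image distances on the (plain) torus
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
        diff = pts[:, None, :] - pk[None, :, :]
        diff = (diff + n / 2) % n - n / 2
        dmin = np.sqrt((diff**2).sum(-1)).min(axis=1)
        dpk = pk[:, None, :] - pk[None, :, :]
        dpk = (dpk + n / 2) % n - n / 2
        dd = np.sqrt((dpk**2).sum(-1))
        np.fill_diagonal(dd, np.inf)
        spacing = dd.min(axis=1).mean()
        rel = dmin / spacing
        idx = np.clip(np.digitize(rel, edges) - 1, 0, n_bins - 1)
        keep = rel <= r_max
        acc_cnt += np.bincount(idx[keep], minlength=n_bins)
        acc_tot += np.bincount(idx[keep], weights=s.ravel()[keep], minlength=n_bins)
    if acc_cnt.sum() == 0:
        raise ValueError("no usable sheet snapshots")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = acc_tot / acc_cnt
    vals[acc_cnt == 0] = np.nan
    return Profile(centers=0.5 * (edges[:-1] + edges[1:]), values=vals)


def profile_mse(a: Profile, b: Profile) -> float:
    """Mean squared difference over shared bins (resampled to the coarser)."""
    if len(a.centers) < len(b.centers):
        a, b = b, a
    ok_b = np.isfinite(b.values)
    ok_a = np.isfinite(a.values)
    if not ok_a.any() or not ok_b.any():
        raise ValueError("profiles have disjoint supports")
    interp = np.interp(b.centers, a.centers[ok_a], a.values[ok_a])
    both = ok_b & (b.centers >= a.centers[ok_a][0]) & (b.centers <= a.centers[ok_a][-1])
    if not both.any():
        raise ValueError("profiles have disjoint supports")
    return float(np.mean((interp[both] - b.values[both]) ** 2))


def firing_variance(
    positions: np.ndarray,
    firing: np.ndarray,
    extent: tuple[float, float, float, float],
    segments: int = 200,
) -> float:
    """VAR: mean over visited segments of the per-segment firing variance.

    The environment bounding box is split into ``segments x segments``
    cells; the cell's rate is sampled once per *encounter* (entry into the
    segment, not every dwelling step, so samples are independent visits),
    and each cell's population variance (divisor = encounter count) is
    averaged over cells with at least 2 encounters.
    """
    firing = np.asarray(firing, dtype=float)
    pos = np.asarray(positions, dtype=float)[: len(firing)]
    x0, x1, y0, y1 = extent
    ix = np.clip(
        ((pos[:, 0] - x0) / (x1 - x0) * segments).astype(int), 0, segments - 1
    )
    iy = np.clip(
        ((pos[:, 1] - y0) / (y1 - y0) * segments).astype(int), 0, segments - 1
    )
    seg = ix * segments + iy
    entry = np.ones(len(seg), dtype=bool)
    entry[1:] = seg[1:] != seg[:-1]
    seg = seg[entry]
    r = firing[entry]
    n_seg = segments * segments
    cnt = np.bincount(seg, minlength=n_seg)
    s1 = np.bincount(seg, weights=r, minlength=n_seg)
    s2 = np.bincount(seg, weights=r * r, minlength=n_seg)
    ok = cnt >= 2
    if not ok.any():
        return 0.0
    var = s2[ok] / cnt[ok] - (s1[ok] / cnt[ok]) ** 2
    return float(np.mean(np.maximum(var, 0.0)))
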