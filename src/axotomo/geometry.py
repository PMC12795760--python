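"""Line-scan spacing and spiral geometry measurements.

``line_profile_spacing`` reproduces the line-scan/plot-profile procedure:
intensity is sampled at sub-voxel resolution along a polyline (trilinear
interpolation), protein peaks (minima under protein-dark contrast) are
detected with a prominence filter, and spacings are consecutive peak
distances along the arc.

``measure_spiral`` fits a plane (total least squares), projects the
points and fits a circle (algebraic Kåsa estimate refined geometrically)
to define the diameter; the width is the FWHM of the averaged radial
cross-profile of the rendered volume through the fitted circle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .io import PROTEIN_DARK, Volume3D

log = logging.getLogger("axotomo.geometry")


class ExtendedConformationError(ValueError):
    """Collinear points: the oligomer is in the extended (string) state,
    so a diameter is undefined."""


@dataclass
class LineProfile:
    arc_nm: np.ndarray
    intensity: np.ndarray
    peak_arc_nm: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def spacings_nm(self) -> np.ndarray:
        return np.diff(self.peak_arc_nm)


@dataclass
class SpiralGeometry:
    spiral_id: int
    diameter_nm: float
    width_nm: float
    spacings_nm: np.ndarray


# ---------------------------------------------------------------------------
# profile sampling and peak spacing
# ---------------------------------------------------------------------------


def sample_profile(volume: Volume3D, polyline_nm: np.ndarray,
                   step_nm: float = 0.1) -> LineProfile:
    """Trilinear intensity profile along a polyline at ``step_nm`` spacing."""
    poly = np.asarray(polyline_nm, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, arc[-1] + step_nm / 2, step_nm)
    pts = np.column_stack([np.interp(s, arc, poly[:, i]) for i in range(3)])
    zyx = volume.nm_to_voxel(pts)  # fractional (z, y, x)
    vals = ndimage.map_coordinates(volume.grid, zyx.T, order=1, mode="nearest")
    return LineProfile(arc_nm=s, intensity=vals)


def _noise_sigma(profile: np.ndarray) -> float:
    """Robust high-frequency noise estimate from successive differences."""
    d = np.diff(profile)
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def line_profile_spacing(volume: Volume3D, polyline_nm: np.ndarray,
                         min_prominence: float | None = None,
                         step_nm: float = 0.1,
                         profile_smooth_nm: float = 0.4) -> np.ndarray:
    """Consecutive peak-to-peak distances along a line scan.

    Protein peaks are intensity minima under protein-dark contrast. The
    sampled profile is low-passed with a small 1D Gaussian
    (``profile_smooth_nm``) to suppress the piecewise-linear kinks of
    trilinear interpolation, which otherwise quantize peak positions to
    voxel crossings on oblique lines. The default prominence is the
    larger of 2x the profile's MAD-based noise sigma and a fifth of its
    5-95 percentile dynamic range. Fewer than two peaks yields an empty
    result with a warning.
    """
    prof = sample_profile(volume, polyline_nm, step_nm)
    y = prof.intensity
    if volume.contrast == PROTEIN_DARK:
        y = -y
    if profile_smooth_nm > 0:
        y = ndimage.gaussian_filter1d(y, sigma=profile_smooth_nm / step_nm, mode="nearest")
    if min_prominence is None:
        span = float(np.percentile(y, 95) - np.percentile(y, 5))
        min_prominence = max(2.0 * _noise_sigma(y), 0.2 * span, 1e-12)
    peaks, _ = signal.find_peaks(y, prominence=min_prominence)
    if len(peaks) < 2:
        log.warning("fewer than two peaks detected along the line scan")
        return np.zeros(0)
    return np.diff(prof.arc_nm[peaks])


# ---------------------------------------------------------------------------
# plane and circle fitting
# ---------------------------------------------------------------------------


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane: returns (centroid, unit normal)."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    if s[1] < 1e-6 * max(s[0], 1e-12):
        raise ExtendedConformationError(
            "points are collinear (extended conformation); diameter undefined")
    return c, vt[2]


def fit_circle_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) circle fit refined by geometric least squares."""
    x, y = xy[:, 0], xy[:, 1]
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(a_mat, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = np.sqrt(sol[2] + cx * cx + cy * cy)

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    out = optimize.least_squares(resid, x0=[cx, cy, r], method="lm")
    cx, cy, r = out.x
    return np.array([cx, cy]), float(abs(r))


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(normal, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


def fit_circle_3d(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Fit a circle to 3D points: (center, normal, radius, rms residual)."""
    c0, n = fit_plane(points)
    u, v = _plane_basis(n)
    rel = points - c0
    xy = np.column_stack([rel @ u, rel @ v])
    c2, r = fit_circle_2d(xy)
    center = c0 + c2[0] * u + c2[1] * v
    inplane = np.hypot(xy[:, 0] - c2[0], xy[:, 1] - c2[1]) - r
    rms = float(np.sqrt(np.mean(inplane**2)))
    return center, n, r, rms


# ---------------------------------------------------------------------------
# spiral measurement
# ---------------------------------------------------------------------------


def measure_width_fwhm(volume: Volume3D, center: np.ndarray, normal: np.ndarray,
                       radius: float, bead_points: np.ndarray,
                       half_extent_nm: float = 6.0, step_nm: float = 0.05) -> float:
    """FWHM of the averaged in-plane radial cross-profile through the
    fitted circle, evaluated at the bead positions."""
    u, v = _plane_basis(normal)
    profiles = []
    r_axis = np.arange(-half_extent_nm, half_extent_nm + step_nm / 2, step_nm)
    for b in bead_points:
        rel = b - center
        rel_in = rel - (rel @ normal) * normal
        rr = np.linalg.norm(rel_in)
        if rr < 1e-9:
            continue
        rad_dir = rel_in / rr
        line = center + np.outer(rr + r_axis, rad_dir)
        zyx = volume.nm_to_voxel(line)
        vals = ndimage.map_coordinates(volume.grid, zyx.T, order=1, mode="nearest")
        profiles.append(vals)
    if not profiles:
        return float("nan")
    prof = np.mean(profiles, axis=0)
    if volume.contrast == PROTEIN_DARK:
        prof = -prof
    edge = max(3, len(prof) // 10)
    baseline = 0.5 * (prof[:edge].mean() + prof[-edge:].mean())
    prof = prof - baseline
    imax = int(np.argmax(prof))
    half = prof[imax] / 2.0
    left = right = None
    for i in range(imax, 0, -1):
        if prof[i - 1] <= half <= prof[i]:
            frac = (half - prof[i - 1]) / (prof[i] - prof[i - 1] + 1e-30)
            left = r_axis[i - 1] + frac * step_nm
            break
    for i in range(imax, len(prof) - 1):
        if prof[i + 1] <= half <= prof[i]:
            frac = (prof[i] - half) / (prof[i] - prof[i + 1] + 1e-30)
            right = r_axis[i] + frac * step_nm
            break
    if left is None or right is None:
        return float("nan")
    return float(right - left)


def measure_spiral(points: np.ndarray, volume: Volume3D | None = None,
                   spiral_id: int = 0, min_prominence: float | None = None) -> SpiralGeometry:
    """Measure diameter (fitted circle), width (cross-profile FWHM) and
    subunit spacings (line scan through the points) of one spiral.

    ``points`` are measured bead/trace positions (>= 6). Width and
    spacings require the rendered volume and are NaN/empty without it.
    Collinear points raise :class:`ExtendedConformationError`.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 6:
        raise ValueError("need at least 6 points to measure a spiral")
    center, normal, radius, _ = fit_circle_3d(pts)
    width = float("nan")
    spacings = np.zeros(0)
    if volume is not None:
        width = measure_width_fwhm(volume, center, normal, radius, pts)
        # order points by angle around the fitted circle for the line scan
        u, v = _plane_basis(normal)
        rel = pts - center
        ang = np.arctan2(rel @ v, rel @ u)
        order = np.argsort(ang)
        path = pts[order]
        gaps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        if len(gaps) and gaps.max() < 4 * np.median(gaps):
            path = np.vstack([path, path[0]])  # close the loop
        spacings = line_profile_spacing(volume, path, min_prominence=min_prominence)
    return SpiralGeometry(spiral_id=spiral_id, diameter_nm=2 * radius,
                          width_nm=width, spacings_nm=spacings)


def detect_bead_centers(volume: Volume3D, approx_points: np.ndarray,
                        search_radius_nm: float = 2.0,
                        smooth_sigma_px: float = 0.5) -> np.ndarray:
    """Refine approximate bead positions to local intensity minima.

    For each approximate point the darkest voxel within the search radius
    is taken and refined to sub-voxel precision by a separable parabolic
    fit — the measurement analog of clicking bead centers on slices.
    """
    from .picking import smooth_volume

    sm = smooth_volume(volume, smooth_sigma_px)
    g = sm.grid
    nz, ny, nx = g.shape
    vs = sm.voxel_size
    rad = max(1, int(round(search_radius_nm / vs)))
    out = []
    for p in np.atleast_2d(approx_points):
        zyx = ((p - sm.origin) / vs)[::-1]
        c = np.round(zyx).astype(int)
        zlo, zhi = max(c[0] - rad, 0), min(c[0] + rad + 1, nz)
        ylo, yhi = max(c[1] - rad, 0), min(c[1] + rad + 1, ny)
        xlo, xhi = max(c[2] - rad, 0), min(c[2] + rad + 1, nx)
        sub = g[zlo:zhi, ylo:yhi, xlo:xhi]
        k = np.unravel_index(np.argmin(sub), sub.shape)
        idx = np.array([zlo + k[0], ylo + k[1], xlo + k[2]])
        frac = np.zeros(3)
        for ax in range(3):
            i = idx[ax]
            if 0 < i < g.shape[ax] - 1:
                sel = list(idx)
                sel[ax] = slice(i - 1, i + 2)
                y0, y1, y2 = g[tuple(sel)]
                denom = y0 - 2 * y1 + y2
                if abs(denom) > 1e-12:
                    frac[ax] = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
        zyx_ref = idx + frac
        out.append(zyx_ref[::-1] * vs + sm.origin)
    return np.array(out)
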