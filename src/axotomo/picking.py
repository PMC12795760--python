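"""Luminal particle (MIP) picking.

The workflow follows the three-step scheme: Gaussian pre-filter
(sigma = 0.5 px), greyscale-minima detection inside the lumen and shell
masks, 0-dimensional sublevel-set topological persistence to rank minima,
an adaptive persistence threshold calibrated so the *shell* retains a
fixed minima density (0.006 vertices per nm^3 — the shell is a regular
tubulin polymer, so its structural minima density is a per-tomogram
contrast invariant), and finally flat-kernel mean-shift clustering of the
retained lumen minima with a 5 nm bandwidth to avoid over-picking
multi-domain complexes.

Persistence here is the classic union-find sweep over voxels sorted by
ascending intensity: a minimum's persistence is the intensity at which
its basin merges into an older (deeper, or equal-depth but earlier in
lexicographic order) basin minus its own intensity; the region's global
minimum gets (region max - region min).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import Config, Volume3D
from .tracing import FilamentTrace, RegionMasks, make_region_masks

log = logging.getLogger("axotomo.picking")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MinimaSet:
    """Local minima of a masked region: voxel coords, values, persistence."""

    coords: np.ndarray  # (n, 3) int voxel (z, y, x)
    values: np.ndarray  # (n,)
    persistence: np.ndarray | None = None
    region: str = "lumen"

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class PersistenceThreshold:
    threshold: float
    achieved_density: float
    target_density: float
    n_retained: int
    underpopulated: bool = False


@dataclass
class ParticleSet:
    """Clustered particle centroids (nm) with provenance."""

    centroids: np.ndarray  # (n, 3) nm (x, y, z)
    n_members: np.ndarray  # minima per cluster
    summed_persistence: np.ndarray
    bandwidth_nm: float = 5.0
    threshold: PersistenceThreshold | None = None

    def __len__(self) -> int:
        return len(self.centroids)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_volume(volume: Volume3D, sigma_px: float = 0.5) -> Volume3D:
    """Gaussian low-pass with reflective boundaries; sigma = 0 is identity."""
    if sigma_px < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_px == 0:
        grid = volume.grid.copy()
    else:
        grid = ndimage.gaussian_filter(volume.grid, sigma=sigma_px, mode="reflect")
    return Volume3D(grid=grid, voxel_size=volume.voxel_size,
                    origin=volume.origin.copy(), contrast=volume.contrast)


# ---------------------------------------------------------------------------
# minima detection
# ---------------------------------------------------------------------------

_FOOTPRINT = np.ones((3, 3, 3), dtype=bool)
_FOOTPRINT[1, 1, 1] = False


def detect_minima(volume: Volume3D, mask: np.ndarray, region: str = "lumen") -> MinimaSet:
    """Strict 26-connected local minima restricted to ``mask``.

    Equal-valued plateaus that are minima count once, represented by the
    lexicographically smallest voxel; a plateau with no higher neighbour
    inside the mask (e.g. a constant region) is not a minimum.
    """
    if not mask.any():
        raise ValueError("empty mask")
    g = np.where(mask, volume.grid, np.inf).astype(np.float64)
    nbr_min = ndimage.minimum_filter(g, footprint=_FOOTPRINT, mode="constant", cval=np.inf)
    strict = mask & (g < nbr_min)
    coords = [np.argwhere(strict)]
    values = [g[strict]]
    ties = np.argwhere(mask & (g == nbr_min) & np.isfinite(g))
    if len(ties):
        coords_t, values_t = _plateau_minima(g, mask, ties)
        coords.append(coords_t)
        values.append(values_t)
    c = np.vstack(coords) if coords else np.zeros((0, 3), dtype=int)
    v = np.concatenate(values)
    order = np.lexsort((c[:, 2], c[:, 1], c[:, 0]))
    return MinimaSet(coords=c[order].astype(np.int64), values=v[order], region=region)


def _plateau_minima(g: np.ndarray, mask: np.ndarray,
                    candidates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flood equal-value plateaus; keep lex-min representative of plateaus
    whose entire outside boundary (within mask) is strictly higher."""
    visited = set()
    out_c, out_v = [], []
    offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
            for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    shape = g.shape
    for cand in map(tuple, candidates):
        if cand in visited:
            continue
        val = g[cand]
        plateau = {cand}
        stack = [cand]
        is_min = True
        has_outside = False
        while stack:
            cur = stack.pop()
            for off in offs:
                nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if not all(0 <= nb[i] < shape[i] for i in range(3)):
                    continue
                if not mask[nb]:
                    continue
                nv = g[nb]
                if nv == val:
                    if nb not in plateau:
                        plateau.add(nb)
                        stack.append(nb)
                elif nv < val:
                    is_min = False
                else:
                    has_outside = True
        visited |= plateau
        if is_min and has_outside:
            rep = min(plateau)
            out_c.append(rep)
            out_v.append(val)
    if not out_c:
        return np.zeros((0, 3), dtype=int), np.zeros(0)
    return np.array(out_c, dtype=int), np.array(out_v)


# ---------------------------------------------------------------------------
# topological persistence (union-find sweep)
# ---------------------------------------------------------------------------


def compute_persistence(volume: Volume3D, minima: MinimaSet, mask: np.ndarray) -> MinimaSet:
    """Assign 0-dim sublevel-set persistence to each minimum of a region."""
    g = volume.grid.astype(np.float64)
    shape = g.shape
    lin_ids = np.flatnonzero(mask.ravel())
    vals = g.ravel()[lin_ids]
    order = np.lexsort((lin_ids, vals))  # ascending value, lex index tie-break
    pers_by_lin = _run_sweep(np.ascontiguousarray(order.astype(np.int64)),
                             np.ascontiguousarray(vals),
                             np.ascontiguousarray(lin_ids.astype(np.int64)),
                             shape, float(vals.max()), float(vals.min()))
    out = np.empty(len(minima))
    for i, c in enumerate(minima.coords):
        lin = int((c[0] * shape[1] + c[1]) * shape[2] + c[2])
        p = pers_by_lin.get(lin)
        if p is None:
            # minimum not a union-find birth: only possible for plateau
            # representatives displaced from the sweep's first-voxel rule
            p = 0.0
        out[i] = p
    return MinimaSet(coords=minima.coords, values=minima.values,
                     persistence=out, region=minima.region)


@njit(cache=True)
def _sweep_numba(order, vals, lin_ids, lookup, shape_z, shape_y, shape_x, vmax):  # pragma: no cover
    n = order.shape[0]
    parent = np.arange(n)
    birth_val = np.zeros(n)
    birth_lin = np.zeros(n, dtype=np.int64)
    processed = np.zeros(n, dtype=np.uint8)
    death = np.full(n, np.nan)
    is_birth = np.zeros(n, dtype=np.uint8)
    for rank in range(n):
        lid = order[rank]
        lin = lin_ids[lid]
        z = lin // (shape_y * shape_x)
        rem = lin - z * shape_y * shape_x
        y = rem // shape_x
        x = rem - y * shape_x
        v = vals[lid]
        root_self = -1
        for dz in range(-1, 2):
            zz = z + dz
            if zz < 0 or zz >= shape_z:
                continue
            for dy in range(-1, 2):
                yy = y + dy
                if yy < 0 or yy >= shape_y:
                    continue
                for dx in range(-1, 2):
                    if dz == 0 and dy == 0 and dx == 0:
                        continue
                    xx = x + dx
                    if xx < 0 or xx >= shape_x:
                        continue
                    nid = lookup[(zz * shape_y + yy) * shape_x + xx]
                    if nid < 0 or processed[nid] == 0:
                        continue
                    # find root with path compression
                    rt = nid
                    while parent[rt] != rt:
                        rt = parent[rt]
                    j = nid
                    while parent[j] != rt:
                        k = parent[j]
                        parent[j] = rt
                        j = k
                    if root_self == -1:
                        root_self = rt
                    elif rt != root_self:
                        a = root_self
                        b = rt
                        if (birth_val[b] < birth_val[a]) or (
                            birth_val[b] == birth_val[a] and birth_lin[b] < birth_lin[a]
                        ):
                            a, b = b, a
                        death[b] = v
                        parent[b] = a
                        root_self = a
        if root_self == -1:
            birth_val[lid] = v
            birth_lin[lid] = lin
            is_birth[lid] = 1
        else:
            parent[lid] = root_self
        processed[lid] = 1
    # survivor: persistence = vmax - birth
    for i in range(n):
        if is_birth[i] == 1 and np.isnan(death[i]):
            death[i] = vmax
    return death, birth_val, birth_lin, is_birth


def _run_sweep(order: np.ndarray, vals: np.ndarray, lin_ids: np.ndarray,
               shape: tuple[int, int, int], vmax: float, vmin: float) -> dict[int, float]:
    lookup = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    lookup[lin_ids] = np.arange(len(lin_ids))
    death, birth_val, birth_lin, is_birth = _sweep_numba(
        order, vals, lin_ids, lookup, shape[0], shape[1], shape[2], vmax
    )
    out: dict[int, float] = {}
    for i in np.flatnonzero(is_birth):
        out[int(birth_lin[i])] = float(death[i] - birth_val[i])
    return out


# ---------------------------------------------------------------------------
# adaptive calibration and clustering
# ---------------------------------------------------------------------------


def calibrate_persistence_threshold(shell_minima: MinimaSet, shell_volume_nm3: float,
                                    target_density: float = 0.006) -> PersistenceThreshold:
    """Threshold = persistence of the k-th most persistent shell minimum,
    k = round(target * shell volume), half-up; ties at the threshold are
    retained in full. Underpopulated shells get threshold 0 and a warning.
    """
    if target_density <= 0:
        raise ValueError("target density must be positive")
    if shell_volume_nm3 <= 0:
        raise ValueError("shell volume must be positive")
    pers = np.asarray(shell_minima.persistence)
    k = int(np.floor(target_density * shell_volume_nm3 + 0.5))
    if len(pers) < k:
        log.warning("shell underpopulated: %d minima < target %d; threshold 0", len(pers), k)
        return PersistenceThreshold(threshold=0.0,
                                    achieved_density=len(pers) / shell_volume_nm3,
                                    target_density=target_density,
                                    n_retained=len(pers), underpopulated=True)
    thr = float(np.sort(pers)[::-1][k - 1]) if k > 0 else float(np.inf)
    n_ret = int((pers >= thr).sum())
    return PersistenceThreshold(threshold=thr, achieved_density=n_ret / shell_volume_nm3,
                                target_density=target_density, n_retained=n_ret)


def apply_threshold(minima: MinimaSet, threshold: float) -> MinimaSet:
    keep = np.asarray(minima.persistence) >= threshold
    return MinimaSet(coords=minima.coords[keep], values=minima.values[keep],
                     persistence=np.asarray(minima.persistence)[keep],
                     region=minima.region)


def cluster_minima(positions_nm: np.ndarray, bandwidth_nm: float = 5.0,
                   persistence: np.ndarray | None = None,
                   max_iter: int = 500, tol_nm: float = 0.01) -> ParticleSet:
    """Flat-kernel mean shift; modes closer than bandwidth/2 are merged.

    Every input point seeds a mode; a mode moves to the centroid of all
    input points within the bandwidth until the shift drops below
    ``tol_nm``. Cluster centroids are the means of their converged seeds.
    """
    if bandwidth_nm <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    if pts.size == 0 or len(pts) == 0:
        return ParticleSet(centroids=np.zeros((0, 3)), n_members=np.zeros(0, dtype=int),
                           summed_persistence=np.zeros(0), bandwidth_nm=bandwidth_nm)
    if persistence is None:
        persistence = np.zeros(len(pts))
    tree = cKDTree(pts)
    modes = pts.copy()
    active = np.ones(len(pts), dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx_lists = tree.query_ball_point(modes[active], r=bandwidth_nm)
        new = np.array([pts[idx].mean(axis=0) for idx in idx_lists])
        shift = np.linalg.norm(new - modes[active], axis=1)
        modes[active] = new
        still = shift >= tol_nm
        act_idx = np.flatnonzero(active)
        active[act_idx[~still]] = False
    # merge modes within bandwidth/2 (greedy, in input order)
    centers: list[np.ndarray] = []
    assign = np.empty(len(pts), dtype=int)
    for i, m in enumerate(modes):
        for ci, c in enumerate(centers):
            if np.linalg.norm(m - c) < bandwidth_nm / 2.0:
                assign[i] = ci
                break
        else:
            centers.append(m.copy())
            assign[i] = len(centers) - 1
    n_clusters = len(centers)
    centroids = np.zeros((n_clusters, 3))
    n_members = np.zeros(n_clusters, dtype=int)
    spers = np.zeros(n_clusters)
    for ci in range(n_clusters):
        sel = assign == ci
        centroids[ci] = modes[sel].mean(axis=0)
        n_members[ci] = sel.sum()
        spers[ci] = np.asarray(persistence)[sel].sum()
    order = np.argsort(centroids[:, 2], kind="stable")
    return ParticleSet(centroids=centroids[order], n_members=n_members[order],
                       summed_persistence=spers[order], bandwidth_nm=bandwidth_nm)


# ---------------------------------------------------------------------------
# composed picking
# ---------------------------------------------------------------------------


def pick_luminal_particles(volume: Volume3D, trace: FilamentTrace,
                           config: Config | None = None,
                           masks: RegionMasks | None = None) -> ParticleSet:
    """Full per-filament picking: smooth -> masks -> minima -> persistence
    -> shell-calibrated threshold -> lumen threshold -> mean shift."""
    cfg = config or Config()
    sm = smooth_volume(volume, cfg.smooth_sigma_px)
    if masks is None:
        masks = make_region_masks(trace, sm, cfg.lumen_radius_nm, cfg.outer_radius_nm)
    shell_min = detect_minima(sm, masks.shell, region="shell")
    shell_min = compute_persistence(sm, shell_min, masks.shell)
    thr = calibrate_persistence_threshold(shell_min, masks.shell_volume_nm3,
                                          cfg.target_shell_density)
    lumen_min = detect_minima(sm, masks.lumen, region="lumen")
    lumen_min = compute_persistence(sm, lumen_min, masks.lumen)
    retained = apply_threshold(lumen_min, thr.threshold)
    coords = _subvoxel_refine(sm.grid, retained.coords)
    pos_nm = coords[:, ::-1] * sm.voxel_size + sm.origin  # (x, y, z)
    particles = cluster_minima(pos_nm, cfg.mean_shift_bandwidth_nm,
                               persistence=retained.persistence)
    particles.threshold = thr
    return particles


def _subvoxel_refine(grid: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Separable parabolic refinement of minima positions (voxel units)."""
    out = coords.astype(float).copy()
    for i, c in enumerate(coords):
        for ax in range(3):
            j = c[ax]
            if 0 < j < grid.shape[ax] - 1:
                sel = list(c)
                sel[ax] = slice(j - 1, j + 2)
                y0, y1, y2 = grid[tuple(sel)]
                denom = y0 - 2 * y1 + y2
                if abs(denom) > 1e-12:
                    out[i, ax] += float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return out
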