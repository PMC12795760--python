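"""Tubulin lattice spacing by rigid monomer fitting.

Each tubulin monomer (a chain of the four-chain A-D model, A/C alpha and
B/D beta) is independently refined against the density map by maximizing
the mean interpolated density at its C-alpha positions (sign-adjusted for
the contrast convention, normalized by the map sigma) over rigid motions.
Distances are medians of corresponding-C-alpha separations over the
structurally conserved residue ranges 1-37 and 48-170.

Nomenclature: the intra-dimer distance pairs chains A-B, the B-C median
pairs adjacent dimers across the interface, and the A-C median is the
dimer repeat — the quantity whose printed magnitude (~83 Å) is commonly
labelled the "inter-dimer distance". All three are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .io import PROTEIN_DARK, AtomModel, Volume3D

CONSERVED_RANGES = ((1, 37), (48, 170))


def conserved_residues(ranges=CONSERVED_RANGES) -> set[int]:
    out: set[int] = set()
    for lo, hi in ranges:
        out |= set(range(lo, hi + 1))
    return out


@dataclass
class RigidFit:
    chain_id: str
    rotation: np.ndarray  # 3x3, det +1
    translation_nm: np.ndarray
    score: float
    pivot_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, coords_nm: np.ndarray) -> np.ndarray:
        return (coords_nm - self.pivot_nm) @ self.rotation.T + self.pivot_nm + self.translation_nm


@dataclass
class LatticeDistances:
    intra_dimer_A: float  # chains A-B
    inter_dimer_interface_A: float  # chains B-C
    dimer_repeat_A: float  # chains A-C; "inter-dimer distance" (printed convention)
    n_residues: dict[str, int]
    residue_ranges: tuple = CONSERVED_RANGES


# ---------------------------------------------------------------------------
# scoring and refinement
# ---------------------------------------------------------------------------


def _spline_coefficients(volume: Volume3D) -> np.ndarray:
    """Cubic-spline prefilter of the grid, cached on the volume object so
    repeated scoring during refinement interpolates smoothly at no extra
    per-call cost."""
    cached = getattr(volume, "_spline3", None)
    if cached is None:
        cached = ndimage.spline_filter(volume.grid.astype(np.float64), order=3)
        object.__setattr__(volume, "_spline3", cached)
    return cached


def score_fit(coords_nm: np.ndarray, volume: Volume3D) -> float:
    """Mean interpolated density at the coordinates (cubic B-spline),
    sign-adjusted so higher is better, in units of the map sigma. Errors
    if > 10% of the atoms fall outside the volume bounds."""
    zyx = volume.nm_to_voxel(coords_nm)
    nz, ny, nx = volume.grid.shape
    inside = (
        (zyx[:, 0] >= 0) & (zyx[:, 0] <= nz - 1)
        & (zyx[:, 1] >= 0) & (zyx[:, 1] <= ny - 1)
        & (zyx[:, 2] >= 0) & (zyx[:, 2] <= nx - 1)
    )
    if inside.mean() < 0.9:
        raise ValueError(f"{(~inside).sum()} of {len(inside)} atoms outside the map")
    coeffs = _spline_coefficients(volume)
    vals = ndimage.map_coordinates(coeffs, zyx[inside].T, order=3,
                                   prefilter=False, mode="nearest")
    sigma = float(volume.grid.std()) or 1.0
    mean = float(vals.mean()) / sigma
    return -mean if volume.contrast == PROTEIN_DARK else mean


def refine_monomer(model: AtomModel, chain_id: str, volume: Volume3D,
                   start: RigidFit | None = None,
                   grid_extent_nm: float = 1.0, grid_step_nm: float = 0.25,
                   max_evals: int = 10_000) -> RigidFit:
    """Local rigid-body refinement: coarse translation grid then simplex
    over the 6 rigid parameters (rotation as a rotation vector about the
    chain centroid). Deterministic given the start."""
    _, coords0 = model.chain_coords(chain_id)
    pivot = coords0.mean(axis=0)
    if start is not None:
        coords0 = start.apply(coords0)
        pivot = coords0.mean(axis=0)

    def transform(p: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(p[3:6]).as_matrix()
        return (coords0 - pivot) @ rot.T + pivot + p[:3]

    evals = 0

    def neg_score(p: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        try:
            return -score_fit(transform(p), volume)
        except ValueError:
            return 1e6

    # coarse translation-only grid
    g = np.arange(-grid_extent_nm, grid_extent_nm + grid_step_nm / 2, grid_step_nm)
    best_p = np.zeros(6)
    best_v = neg_score(best_p)
    for tx in g:
        for ty in g:
            for tz in g:
                p = np.array([tx, ty, tz, 0.0, 0.0, 0.0])
                v = neg_score(p)
                if v < best_v:
                    best_v, best_p = v, p
    res = optimize.minimize(neg_score, best_p, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-9,
                                     "maxfev": max_evals - evals, "maxiter": max_evals})
    p = res.x
    rot = Rotation.from_rotvec(p[3:6]).as_matrix()
    fitted = transform(p)
    # compose with the start transform so RigidFit maps original -> fitted
    _, orig = model.chain_coords(chain_id)
    pivot0 = orig.mean(axis=0)
    # solve for the rigid map orig -> fitted (Kabsch)
    a = orig - pivot0
    b = fitted - fitted.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r_full = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t_full = fitted.mean(axis=0) - pivot0
    return RigidFit(chain_id=chain_id, rotation=r_full, translation_nm=t_full,
                    score=-res.fun, pivot_nm=pivot0)


def fitted_model(model: AtomModel, fits: dict[str, RigidFit]) -> AtomModel:
    chains = {}
    for cid, residues in model.chains.items():
        fit = fits.get(cid)
        out = {}
        for rnum, xyz in residues.items():
            out[rnum] = fit.apply(xyz[None, :])[0] if fit is not None else xyz.copy()
        chains[cid] = out
    return AtomModel(chains=chains)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _median_pair_distance_A(model: AtomModel, c1: str, c2: str,
                            residues: set[int], min_overlap: int = 50) -> tuple[float, int]:
    r1, r2 = model.chains[c1], model.chains[c2]
    shared = sorted(residues & set(r1) & set(r2))
    if len(shared) < min_overlap:
        raise ValueError(
            f"chains {c1}-{c2} share only {len(shared)} conserved residues (< {min_overlap})")
    d = [np.linalg.norm(r1[r] - r2[r]) * 10.0 for r in shared]  # nm -> Å
    return float(np.median(d)), len(shared)


def lattice_distances(model: AtomModel, ranges=CONSERVED_RANGES) -> LatticeDistances:
    """Median corresponding-C-alpha distances over the conserved set for
    chain pairs A-B (intra-dimer), B-C (dimer interface) and A-C (dimer
    repeat / printed inter-dimer convention), in Å."""
    res = conserved_residues(ranges)
    ab, n_ab = _median_pair_distance_A(model, "A", "B", res)
    bc, n_bc = _median_pair_distance_A(model, "B", "C", res)
    ac, n_ac = _median_pair_distance_A(model, "A", "C", res)
    return LatticeDistances(intra_dimer_A=ab, inter_dimer_interface_A=bc,
                            dimer_repeat_A=ac,
                            n_residues={"A-B": n_ab, "B-C": n_bc, "A-C": n_ac},
                            residue_ranges=ranges)


def refine_all_and_measure(model: AtomModel, volume: Volume3D,
                           starts: dict[str, RigidFit] | None = None) -> tuple[LatticeDistances, dict[str, RigidFit]]:
    """Independently refine chains A-D and report lattice distances."""
    fits = {}
    for cid in model.chains:
        start = None if starts is None else starts.get(cid)
        fits[cid] = refine_monomer(model, cid, volume, start=start)
    return lattice_distances(fitted_model(model, fits)), fits


def random_start(rng: np.random.Generator, max_shift_nm: float = 0.3,
                 max_angle_deg: float = 5.0, chain_id: str = "",
                 pivot_nm: np.ndarray | None = None) -> RigidFit:
    """Random rigid perturbation within the stated capture range."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(0, max_angle_deg))
    rot = Rotation.from_rotvec(axis * ang).as_matrix()
    shift = rng.uniform(-max_shift_nm, max_shift_nm, size=3)
    return RigidFit(chain_id=chain_id, rotation=rot, translation_nm=shift, score=float("nan"),
                    pivot_nm=np.zeros(3) if pivot_nm is None else np.asarray(pivot_nm, float))
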