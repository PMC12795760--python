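"""Seeded synthetic tomographic scenes with known ground truth.

The generator emulates the structures quantified by the analysis modules:

* microtubules: a 13-protofilament wall rendered as rows of tubulin-
  monomer blobs (4.165 nm axial repeat, i.e. half the 83.3 Å dimer
  repeat) between the 7 nm lumen and 15 nm outer radii, plus the weaker
  inter-protofilament lateral-contact texture of a real wall; luminal
  particles (MIPs) of 6 nm diameter spaced 18.5 nm along the axis,
* spiral tubulin oligomers: bead curves of 37.8 nm diameter, 4.2 nm bead
  FWHM and 4.6 nm subunit spacing, at arbitrary 3D orientation,
* actin control filaments with 5.5 nm subunit periodicity,
* additive Gaussian noise parameterized by SNR (feature contrast of 1
  over noise sigma) and an optional hard Fourier missing wedge,
* rotation tables (polarity analysis) and track tables (transport
  analysis) with per-row ground-truth labels.

Contrast follows the tomogram convention: protein is dark (background 0,
features negative). Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import PROTEIN_DARK, AtomModel, Volume3D
from .tracing import resample_centerline

MONOMER_REPEAT_NM = 0.41665 * 10  # 83.3 Å dimer repeat / 2 monomers
N_PROTOFILAMENTS = 13
WALL_BLOB_SIGMA_NM = 0.85
WALL_DEPTH_INNER = 2.2  # wall is a continuous protein lattice: darker than
WALL_DEPTH_OUTER = 2.0  # an isolated 6 nm particle of unit depth
FEATURE_SUPPORT_EPS = 0.05


# ---------------------------------------------------------------------------
# scene specification / ground truth
# ---------------------------------------------------------------------------


@dataclass
class MicrotubuleSpec:
    """One microtubule: control points (n, 3) nm and radii."""

    control_points: np.ndarray
    lumen_radius_nm: float = 7.0
    outer_radius_nm: float = 15.0
    mip_spacing_nm: float | None = None  # None -> scene default

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if not self.lumen_radius_nm < self.outer_radius_nm:
            raise ValueError("lumen radius must be below outer radius")


@dataclass
class SpiralSpec:
    """One spiral oligomer: a (possibly partial) circle of beads in 3D."""

    center: np.ndarray
    normal: np.ndarray
    diameter_nm: float = 37.8
    width_nm: float = 4.2  # bead FWHM
    subunit_spacing_nm: float = 4.6
    arc_fraction: float = 1.0  # 1.0 = closed circle
    extended: bool = False  # fully extended string conformation

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if not self.extended and self.diameter_nm < 2 * self.width_nm:
            raise ValueError("diameter smaller than twice the bead width is unresolvable")


@dataclass
class ActinSpec:
    """Straight control filament with periodic subunits."""

    start: np.ndarray
    end: np.ndarray
    subunit_spacing_nm: float = 5.5
    width_nm: float = 4.2

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)


@dataclass
class SceneSpec:
    box_shape: tuple[int, int, int]  # (nz, ny, nx) voxels
    voxel_size_nm: float = 1.0
    microtubules: list[MicrotubuleSpec] = field(default_factory=list)
    spirals: list[SpiralSpec] = field(default_factory=list)
    actins: list[ActinSpec] = field(default_factory=list)
    mip_spacing_nm: float = 18.5
    mip_jitter_nm: float = 1.0
    mip_diameter_nm: float = 6.0
    noise_snr: float | None = None  # None -> noiseless
    missing_wedge_halfangle_deg: float | None = None
    shell_texture: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mip_spacing_nm <= 0:
            raise ValueError("mip spacing must be positive")


@dataclass
class SceneTruth:
    """Ground-truth record for every rendered feature."""

    centerlines: dict[int, np.ndarray] = field(default_factory=dict)
    mip_arc_nm: dict[int, np.ndarray] = field(default_factory=dict)
    mip_xyz_nm: dict[int, np.ndarray] = field(default_factory=dict)
    mip_clipped: dict[int, np.ndarray] = field(default_factory=dict)
    spirals: list[dict] = field(default_factory=list)
    actin_beads: list[np.ndarray] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def all_feature_points(self) -> np.ndarray:
        pts = [xyz for xyz in self.mip_xyz_nm.values()]
        pts += [s["beads"] for s in self.spirals]
        pts += list(self.actin_beads)
        return np.vstack(pts) if pts else np.zeros((0, 3))


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def _splat(shape: tuple[int, int, int], voxel: float, origin: np.ndarray,
           points_nm: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Trilinear deposition of weighted impulses onto a (nz, ny, nx) grid."""
    grid = np.zeros(shape, dtype=np.float64)
    if len(points_nm) == 0:
        return grid
    p = (np.atleast_2d(points_nm) - origin) / voxel  # fractional (x, y, z)
    nz, ny, nx = shape
    base = np.floor(p).astype(int)
    frac = p - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                ) * weights
                ix, iy, iz = base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz
                ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
                np.add.at(grid, (iz[ok], iy[ok], ix[ok]), w[ok])
    return grid


def render_blobs(shape: tuple[int, int, int], voxel: float, origin: np.ndarray,
                 points_nm: np.ndarray, sigma_nm: float, depth: float = 1.0,
                 weights: np.ndarray | None = None) -> np.ndarray:
    """Render Gaussian blobs of peak amplitude ``-depth`` (protein dark).

    The splat kernel's variance (1/6 voxel^2 per axis for trilinear
    deposition) is deconvolved from the requested sigma so that the
    rendered blob profile has the stated width.
    """
    pts = np.atleast_2d(points_nm)
    if weights is None:
        weights = np.ones(len(pts))
    sig2 = max(sigma_nm**2 - voxel**2 / 6.0, (0.3 * voxel) ** 2)
    sig_vox = np.sqrt(sig2) / voxel
    mass = depth * (2 * np.pi * sig_vox**2) ** 1.5
    grid = _splat(shape, voxel, origin, pts, np.asarray(weights) * mass)
    return -ndimage.gaussian_filter(grid, sigma=sig_vox, mode="constant")


def apply_missing_wedge(grid: np.ndarray, halfangle_deg: float,
                        tilt_axis: str = "y") -> np.ndarray:
    """Zero a Fourier wedge about the tilt axis (hard mask).

    The wedge is the unsampled region of a +-(90 - halfangle) tilt series:
    spatial frequencies whose (kx, kz) direction lies within ``halfangle``
    of the beam (z) axis, i.e. |kx| < |kz| tan(halfangle).
    """
    f = np.fft.fftn(grid)
    nz, ny, nx = grid.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    t = np.tan(np.deg2rad(halfangle_deg))
    wedge = np.abs(kx) < np.abs(kz) * t
    f = np.where(wedge, 0.0, f)
    out = np.fft.ifftn(f).real
    return out.astype(grid.dtype)


def _frame_along(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal normal/binormal fields for unit tangents (n, 3)."""
    ref = np.array([1.0, 0.0, 0.0])
    n1 = np.cross(tangents, ref)
    bad = np.linalg.norm(n1, axis=1) < 1e-6
    if bad.any():
        n1[bad] = np.cross(tangents[bad], [0.0, 1.0, 0.0])
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    return n1, n2


# ---------------------------------------------------------------------------
# microtubule scenes
# ---------------------------------------------------------------------------


def straight_mt(start: Sequence[float], end: Sequence[float], **kw) -> MicrotubuleSpec:
    return MicrotubuleSpec(control_points=np.array([start, end], dtype=float), **kw)


def _shell_points(centerline: np.ndarray, rng: np.random.Generator,
                  lumen_radius_nm: float,
                  outer_radius_nm: float) -> tuple[np.ndarray, np.ndarray]:
    """Tubulin-wall lattice positions around a densely resampled centerline.

    Two 13-row families at inner/outer wall radii, staggered axially and
    angularly (3-start helical rise between protofilaments), monomer
    repeat 4.1665 nm. The two-family layout reproduces the minima-rich
    texture of a real wall so the shell's structural minima density
    exceeds the 0.006 nm^-3 calibration target.
    """
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(centerline, axis=0), axis=1))])
    total = arc[-1]
    tang = np.gradient(centerline, arc, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    phase = rng.uniform(0, 2 * np.pi)
    r_in = lumen_radius_nm + 2.5
    r_out = outer_radius_nm - 2.5
    families: list[list[np.ndarray]] = [[], []]
    for fam, (radius, dang, dax) in enumerate(
        ((r_in, 0.0, 0.0), (r_out, np.pi / N_PROTOFILAMENTS, MONOMER_REPEAT_NM / 2))
    ):
        for k in range(N_PROTOFILAMENTS):
            a = phase + 2 * np.pi * k / N_PROTOFILAMENTS + dang
            stagger = (k * 3.0 * MONOMER_REPEAT_NM / N_PROTOFILAMENTS + dax) % MONOMER_REPEAT_NM
            s_vals = np.arange(stagger, total, MONOMER_REPEAT_NM)
            pts = np.column_stack([np.interp(s_vals, arc, centerline[:, i]) for i in range(3)])
            tg = np.column_stack([np.interp(s_vals, arc, tang[:, i]) for i in range(3)])
            tg /= np.linalg.norm(tg, axis=1, keepdims=True)
            n1, n2 = _frame_along(tg)
            families[fam].append(pts + radius * (np.cos(a) * n1 + np.sin(a) * n2))
    return np.vstack(families[0]), np.vstack(families[1])


def make_microtubule_scene(spec: SceneSpec) -> tuple[Volume3D, SceneTruth]:
    """Render microtubules with luminal particles; return volume + truth.

    MIP ground truth: arc positions ``k * spacing`` for k = 0 ... floor(L /
    spacing), jittered axially by ``mip_jitter_nm``; features that extend
    outside the box are clipped and flagged in the truth, never an error.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.box_shape)
    vs = spec.voxel_size_nm
    origin = np.zeros(3)
    truth = SceneTruth(metadata={
        "voxel_size_nm": vs, "seed": spec.seed, "contrast": PROTEIN_DARK,
        "noise_snr": spec.noise_snr,
        "missing_wedge_halfangle_deg": spec.missing_wedge_halfangle_deg,
    })
    grid = np.zeros(shape, dtype=np.float64)
    box_hi = np.array([shape[2], shape[1], shape[0]]) * vs  # (x, y, z) nm
    for fid, mt in enumerate(spec.microtubules):
        trace = resample_centerline(mt.control_points, step_nm=1.0, filament_id=fid)
        cl = trace.points
        truth.centerlines[fid] = cl
        prim, sec = _shell_points(cl, rng, mt.lumen_radius_nm, mt.outer_radius_nm)
        if spec.shell_texture:
            grid += render_blobs(shape, vs, origin, prim, WALL_BLOB_SIGMA_NM,
                                 depth=WALL_DEPTH_INNER)
            grid += render_blobs(shape, vs, origin, sec, WALL_BLOB_SIGMA_NM,
                                 depth=WALL_DEPTH_OUTER)
        else:
            # smooth texture-free annulus (wide overlapping blobs)
            grid += render_blobs(shape, vs, origin, prim, 2.5, depth=1.0)
        spacing = mt.mip_spacing_nm or spec.mip_spacing_nm
        n_mips = int(np.floor(trace.length_nm / spacing)) + 1
        arc_true = np.arange(n_mips) * spacing
        arc_jit = arc_true + rng.normal(0.0, spec.mip_jitter_nm, size=n_mips)
        arc_jit = np.clip(arc_jit, 0.0, trace.length_nm)
        xyz = np.column_stack([
            np.interp(arc_jit, trace.arclength, cl[:, i]) for i in range(3)
        ])
        clipped = np.any((xyz < 0) | (xyz > box_hi), axis=1)
        truth.mip_arc_nm[fid] = arc_jit
        truth.mip_xyz_nm[fid] = xyz
        truth.mip_clipped[fid] = clipped
        sigma_mip = spec.mip_diameter_nm / (2 * np.sqrt(2 * np.log(2)))
        grid += render_blobs(shape, vs, origin, xyz, sigma_mip, depth=1.0)
    grid = _finalize(grid, spec, rng)
    return Volume3D(grid=grid, voxel_size=vs, origin=origin), truth


def noise_sigma_for_snr(signal: np.ndarray, snr: float,
                        support_eps: float = FEATURE_SUPPORT_EPS) -> float:
    """Noise sigma realizing a variance SNR (the cryo-EM convention):
    SNR = var(signal) / var(noise), with the signal variance taken over
    the rendered feature support."""
    support = np.abs(signal) > support_eps
    sig_std = float(signal[support].std()) if support.any() else 1.0
    return sig_std / np.sqrt(snr)


def _finalize(grid: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_snr:
        sigma = noise_sigma_for_snr(grid, spec.noise_snr)
        grid = grid + rng.normal(0.0, sigma, size=grid.shape)
    if spec.missing_wedge_halfangle_deg:
        grid = apply_missing_wedge(grid, spec.missing_wedge_halfangle_deg)
    return grid.astype(np.float32)


# ---------------------------------------------------------------------------
# spiral / actin scenes
# ---------------------------------------------------------------------------


def spiral_curve(sp: SpiralSpec, n_samples: int = 400) -> np.ndarray:
    """Analytic curve (dense polyline) of a spiral specification."""
    if sp.extended:
        # string conformation: straight segment of the same contour length
        length = np.pi * sp.diameter_nm * sp.arc_fraction
        d = sp.normal / np.linalg.norm(sp.normal)
        t = np.linspace(-length / 2, length / 2, n_samples)
        return sp.center + np.outer(t, d)
    n = sp.normal / np.linalg.norm(sp.normal)
    u = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    r = sp.diameter_nm / 2.0
    theta = np.linspace(0, 2 * np.pi * sp.arc_fraction, n_samples)
    return sp.center + r * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))


def spiral_beads(sp: SpiralSpec) -> np.ndarray:
    """Bead centers along the spiral curve at the subunit spacing.

    Closed circles place ``round(circumference / spacing)`` beads evenly;
    open arcs place ``floor(arc / spacing) + 1`` beads from the start.
    """
    if sp.extended:
        curve = spiral_curve(sp, 2)
        length = np.linalg.norm(curve[-1] - curve[0])
        n = int(np.floor(length / sp.subunit_spacing_nm)) + 1
        d = (curve[-1] - curve[0]) / length
        return curve[0] + np.outer(np.arange(n) * sp.subunit_spacing_nm, d)
    curve = spiral_curve(sp, 2000)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if sp.arc_fraction >= 1.0 - 1e-9:
        n = int(round(arc[-1] / sp.subunit_spacing_nm))
        s = np.arange(n) * arc[-1] / n
    else:
        n = int(np.floor(arc[-1] / sp.subunit_spacing_nm)) + 1
        s = np.arange(n) * sp.subunit_spacing_nm
    return np.column_stack([np.interp(s, arc, curve[:, i]) for i in range(3)])


def actin_beads(sp: ActinSpec) -> np.ndarray:
    length = np.linalg.norm(sp.end - sp.start)
    n = int(np.floor(length / sp.subunit_spacing_nm)) + 1
    d = (sp.end - sp.start) / length
    return sp.start + np.outer(np.arange(n) * sp.subunit_spacing_nm, d)


def make_spiral_scene(spec: SceneSpec) -> tuple[Volume3D, SceneTruth]:
    """Render spiral oligomers and/or actin control filaments."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.box_shape)
    vs = spec.voxel_size_nm
    origin = np.zeros(3)
    truth = SceneTruth(metadata={"voxel_size_nm": vs, "seed": spec.seed,
                                 "contrast": PROTEIN_DARK, "noise_snr": spec.noise_snr})
    grid = np.zeros(shape, dtype=np.float64)
    for sp in spec.spirals:
        beads = spiral_beads(sp)
        sigma = sp.width_nm / (2 * np.sqrt(2 * np.log(2)))
        grid += render_blobs(shape, vs, origin, beads, sigma, depth=1.0)
        truth.spirals.append({
            "beads": beads, "curve": spiral_curve(sp), "diameter_nm": sp.diameter_nm,
            "width_nm": sp.width_nm, "spacing_nm": sp.subunit_spacing_nm,
            "extended": sp.extended, "center": sp.center, "normal": sp.normal,
        })
    for ac in spec.actins:
        beads = actin_beads(ac)
        sigma = ac.width_nm / (2 * np.sqrt(2 * np.log(2)))
        grid += render_blobs(shape, vs, origin, beads, sigma, depth=1.0)
        truth.actin_beads.append(beads)
    grid = _finalize(grid, spec, rng)
    return Volume3D(grid=grid, voxel_size=vs, origin=origin), truth


# ---------------------------------------------------------------------------
# lattice density (pseudo-atomic two-dimer protofilament)
# ---------------------------------------------------------------------------


def _monomer_shape(n_residues: int = 170, seed: int = 7) -> np.ndarray:
    """A fixed compact pseudo-monomer: n_residues C-alpha positions (nm)
    on a smoothed random walk confined to a ~2 nm sphere."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_residues, 3))
    walk = np.cumsum(steps, axis=0)
    walk = ndimage.gaussian_filter1d(walk, sigma=3.0, axis=0)
    walk -= walk.mean(axis=0)
    r = np.linalg.norm(walk, axis=1)
    walk *= 1.6 / (r.max() + 1e-9)
    return walk


def make_lattice_density(dimer_repeat_A: float, intra_fraction: float = 0.5,
                         noise_sigma: float = 0.0, seed: int = 0,
                         voxel_size_nm: float = 0.1,
                         smear_sigma_nm: float = 0.25) -> tuple[Volume3D, AtomModel]:
    """Two-dimer single-protofilament pseudo-model (chains A-D) + density.

    Chain A (alpha) sits at the origin; A->B translation is
    ``intra_fraction * repeat`` along z and A->C is the full dimer repeat.
    The density is a Gaussian smear of the C-alpha positions (protein
    dark); the unperturbed model is returned as ground truth.
    """
    if not 75.0 <= dimer_repeat_A <= 90.0:
        raise ValueError("dimer repeat must be within 75-90 Å")
    repeat_nm = dimer_repeat_A / 10.0
    mono = _monomer_shape()
    offsets = {
        "A": 0.0,
        "B": intra_fraction * repeat_nm,
        "C": repeat_nm,
        "D": repeat_nm + intra_fraction * repeat_nm,
    }
    chains = {}
    for cid, dz in offsets.items():
        coords = mono + np.array([0.0, 0.0, dz])
        chains[cid] = {i + 1: coords[i] for i in range(len(coords))}
    model = AtomModel(chains=chains)
    all_xyz = np.vstack([np.stack(list(c.values())) for c in chains.values()])
    pad = 1.0  # nm
    lo = all_xyz.min(axis=0) - pad
    hi = all_xyz.max(axis=0) + pad
    shape_xyz = np.ceil((hi - lo) / voxel_size_nm).astype(int) + 1
    shape = (int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0]))
    grid = render_blobs(shape, voxel_size_nm, lo, all_xyz, smear_sigma_nm, depth=1.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sigma, size=grid.shape)
    vol = Volume3D(grid=grid.astype(np.float32), voxel_size=voxel_size_nm, origin=lo)
    return vol, model


# ---------------------------------------------------------------------------
# rotation / track tables
# ---------------------------------------------------------------------------


def make_rotation_table(n_segments: int, parallel_fraction: float,
                        angular_noise_deg: float, seed: int = 0,
                        segments_per_filament: int = 3,
                        n_images: int = 1) -> pd.DataFrame:
    """Per-segment rotations with ground-truth polarity.

    Each filament draws a polarity (parallel with probability
    ``parallel_fraction``); its segments rotate at the per-image reference
    plus 0 or 180 degrees plus wrapped Gaussian noise.
    """
    if not 0.0 <= parallel_fraction <= 1.0:
        raise ValueError("parallel_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    refs = rng.uniform(0, 360, size=n_images)
    rows = []
    fid = 0
    seg_total = 0
    while seg_total < n_segments:
        image = fid % n_images
        parallel = rng.random() < parallel_fraction
        nseg = min(segments_per_filament, n_segments - seg_total)
        for s in range(nseg):
            rot = refs[image] + (0.0 if parallel else 180.0)
            if angular_noise_deg > 0:
                rot += rng.normal(0.0, angular_noise_deg)
            rows.append({
                "image_id": image, "filament_id": fid, "segment_index": s,
                "rotation_deg": rot % 360.0,
                "true_polarity": "parallel" if parallel else "antiparallel",
            })
        seg_total += nseg
        fid += 1
    return pd.DataFrame(rows)


TRACK_CLASSES = ("anterograde_gt5", "intermediate", "within_1um", "retrograde")


def make_track_table(n_tracks: int, class_mixture: dict[str, float], seed: int = 0,
                     duration_s: float = 1800.0, n_points: int = 31,
                     exact_counts: bool = False) -> pd.DataFrame:
    """Tracks of positions along the axon axis (µm, injury site at 0,
    anterograde positive), realizing drawn displacement classes.

    Net displacements per class: anterograde_gt5 U(5.5, 12); intermediate
    U(1.2, 4.8); within_1um U(-0.15, 1.0); retrograde U(-8, -0.5).
    With ``exact_counts`` the population realizes the mixture exactly
    (largest-remainder apportionment, shuffled) instead of drawing each
    track's class independently — the right mode when the mixture itself
    is the condition under study.
    """
    classes = list(class_mixture)
    probs = np.array([class_mixture[c] for c in classes], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("class mixture fractions must sum to 1")
    unknown = set(classes) - set(TRACK_CLASSES)
    if unknown:
        raise ValueError(f"unknown track class(es): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    draw = {
        "anterograde_gt5": lambda: rng.uniform(5.5, 12.0),
        "intermediate": lambda: rng.uniform(1.2, 4.8),
        "within_1um": lambda: rng.uniform(-0.15, 1.0),
        "retrograde": lambda: rng.uniform(-8.0, -0.5),
    }
    if exact_counts:
        base = np.floor(probs * n_tracks).astype(int)
        rem = probs * n_tracks - base
        for i in np.argsort(rem)[::-1][: n_tracks - base.sum()]:
            base[i] += 1
        assignment = np.repeat(np.arange(len(classes)), base)
        rng.shuffle(assignment)
    t = np.linspace(0.0, duration_s, n_points)
    rows = []
    for tid in range(n_tracks):
        cls = classes[assignment[tid]] if exact_counts else classes[rng.choice(len(classes), p=probs)]
        net = draw[cls]()
        x0 = rng.uniform(-20.0, -5.0)
        pos = x0 + (t / duration_s) * net
        jitter = rng.normal(0.0, 0.05, size=n_points)
        jitter[0] = jitter[-1] = 0.0  # endpoints define the net displacement
        pos = pos + jitter
        for ti, xi in zip(t, pos):
            rows.append({"track_id": tid, "time_s": ti, "position_um": xi,
                         "true_class": cls})
    return pd.DataFrame(rows)
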