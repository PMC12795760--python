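"""Volumes, atomic models, tables and configuration.

Conventions used throughout the package:

* the internal length unit is nanometres everywhere; Å values from file
  headers or atomic models are converted at the boundary,
* volume grids are indexed ``(z, y, x)``, 0-based, with voxel centers at
  integer grid coordinates, so the physical position of voxel
  ``(k, j, i)`` is ``origin + voxel_size * (i, j, k)`` (x, y, z order),
* tomographic contrast defaults to ``protein_dark``: protein renders as
  greyscale minima, matching unstained cryo-ET tomograms.
"""

from __future__ import annotations

import dataclasses
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("axotomo")

PROTEIN_DARK = "protein_dark"
PROTEIN_BRIGHT = "protein_bright"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class SchemaError(ValueError):
    """A table is missing or mistypes a required column."""


# ---------------------------------------------------------------------------
# Volume3D and MRC2014 i/o
# ---------------------------------------------------------------------------


@dataclass
class Volume3D:
    """A 3D scalar grid with physical voxel size.

    Parameters
    ----------
    grid : ndarray, shape (nz, ny, nx)
        Scalar intensities, float32.
    voxel_size : float
        Isotropic voxel edge, nm.
    origin : ndarray, shape (3,)
        Physical position of voxel (0, 0, 0) in (x, y, z) order, nm.
    contrast : str
        ``protein_dark`` (default) or ``protein_bright``.
    """

    grid: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    contrast: str = PROTEIN_DARK

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be 3D with at least one voxel per axis")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.contrast not in (PROTEIN_DARK, PROTEIN_BRIGHT):
            raise ValueError(f"unknown contrast convention {self.contrast!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # (nz, ny, nx)

    def voxel_centers_nm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coordinate axes (x, y, z) of voxel centers in nm."""
        nz, ny, nx = self.grid.shape
        x = self.origin[0] + self.voxel_size * np.arange(nx)
        y = self.origin[1] + self.voxel_size * np.arange(ny)
        z = self.origin[2] + self.voxel_size * np.arange(nz)
        return x, y, z

    def nm_to_voxel(self, points_nm: np.ndarray) -> np.ndarray:
        """Map (x, y, z) nm coordinates to fractional (z, y, x) grid indices."""
        p = (np.atleast_2d(points_nm) - self.origin) / self.voxel_size
        return p[:, ::-1]


_MRC_HEADER_BYTES = 1024
_MRC_MODE_FLOAT32 = 2


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write an MRC2014 (mode 2) volume; voxel size stored in Å in cella."""
    nz, ny, nx = volume.grid.shape
    apix = volume.voxel_size * 10.0  # nm -> Å
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, _MRC_MODE_FLOAT32)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart..nzstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, apix * nx, apix * ny, apix * nz)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    g = volume.grid
    struct.pack_into("<3f", header, 76, float(g.min()), float(g.max()), float(g.mean()))
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    ox, oy, oz = (np.asarray(volume.origin, dtype=float) * 10.0).tolist()
    struct.pack_into("<3f", header, 196, ox, oy, oz)  # origin, Å
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(g.std()))
    struct.pack_into("<i", header, 220, 1)
    header[224 : 224 + 80] = b"axotomo volume".ljust(80)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(g, dtype="<f4").tobytes())


def read_volume(path: str | Path, contrast: str = PROTEIN_DARK) -> Volume3D:
    """Read an MRC2014 mode-2 volume.

    Raises :class:`FormatError` naming the offending header field when the
    file is not in the supported dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError("truncated MRC header (< 1024 bytes)")
    if raw[208:212] != b"MAP ":
        raise FormatError("bad MRC header field MAP: expected b'MAP ' tag at byte 208")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode != _MRC_MODE_FLOAT32:
        raise FormatError(f"unsupported MRC header field MODE={mode} (only mode 2 / float32)")
    if min(nx, ny, nz) < 1:
        raise FormatError(f"bad MRC header field NX/NY/NZ: ({nx}, {ny}, {nz})")
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    if mx < 1 or cella[0] <= 0:
        raise FormatError("bad MRC header field CELLA/MX: cannot derive voxel size")
    voxel_nm = cella[0] / mx / 10.0
    origin = np.array(struct.unpack_from("<3f", raw, 196)) / 10.0
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    data_offset = _MRC_HEADER_BYTES + nsymbt
    n = nx * ny * nz
    expect = data_offset + 4 * n
    if len(raw) < expect:
        raise FormatError("MRC data block shorter than NX*NY*NZ voxels")
    grid = np.frombuffer(raw, dtype="<f4", count=n, offset=data_offset)
    grid = grid.reshape(nz, ny, nx).copy()
    return Volume3D(grid=grid, voxel_size=float(voxel_nm), origin=origin, contrast=contrast)


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------


@dataclass
class AtomModel:
    """Chain- and residue-indexed Cα coordinates, stored in nm.

    ``chains`` maps chain id to an ordered ``{residue_number: xyz_nm}``
    mapping. Distances are reported in Å at the interface of the
    lattice-spacing module (×10 at the boundary).
    """

    chains: dict[str, dict[int, np.ndarray]]

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            if len(set(residues)) != len(residues):
                raise ValueError(f"duplicate residue numbers in chain {cid}")
            for rnum, xyz in residues.items():
                xyz = np.asarray(xyz, dtype=float)
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"non-finite coordinate at {cid}:{rnum}")
                residues[rnum] = xyz

    def chain_coords(self, chain_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Residue numbers (sorted) and their Cα coordinates (nm)."""
        residues = self.chains[chain_id]
        nums = np.array(sorted(residues), dtype=int)
        coords = np.stack([residues[int(r)] for r in nums])
        return nums, coords


def read_atom_model(path: str | Path, chain_filter: set[str] | None = None) -> AtomModel:
    """Read Cα coordinates from a PDB or mmCIF file (via gemmi).

    Only chains in ``chain_filter`` are retained (all when None); non-Cα
    atoms are dropped. Coordinates are converted from Å to nm.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    available = [ch.name for ch in model]
    if chain_filter is not None:
        missing = set(chain_filter) - set(available)
        if missing:
            raise ValueError(
                f"requested chain(s) {sorted(missing)} absent; available chains: {sorted(available)}"
            )
    chains: dict[str, dict[int, np.ndarray]] = {}
    for ch in model:
        if chain_filter is not None and ch.name not in chain_filter:
            continue
        residues: dict[int, np.ndarray] = {}
        for res in ch:
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue
            residues[res.seqid.num] = np.array([ca.pos.x, ca.pos.y, ca.pos.z]) / 10.0
        chains[ch.name] = residues
    return AtomModel(chains=chains)


def write_atom_model(model: AtomModel, path: str | Path) -> None:
    """Write Cα-only chains to a minimal PDB file (coordinates nm -> Å)."""
    st = gemmi.Structure()
    st.name = "axotomo"
    md = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for rnum in sorted(residues):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(rnum, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            xyz = residues[rnum] * 10.0
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

#: canonical schemas (column name -> numpy dtype kind: 'i' int, 'f' float, 'O' str)
SEGMENT_SCHEMA = {"image_id": "i", "filament_id": "i", "segment_index": "i", "rotation_deg": "f"}
TRACK_SCHEMA = {"track_id": "i", "time_s": "f", "position_um": "f"}
TRACE_SCHEMA = {"filament_id": "i", "index": "i", "x": "f", "y": "f", "z": "f", "arclength": "f"}
PARTICLE_SCHEMA = {"filament_id": "i", "x": "f", "y": "f", "z": "f", "persistence": "f", "n_members": "i"}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    """Read a CSV/TSV with a declared header into typed columns.

    Strict dialect: '.' decimal point, one header row. A missing required
    column raises :class:`SchemaError`; unparsable values (e.g. a
    locale-style decimal comma) raise :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, skipinitialspace=True)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        if kind == "O":
            out[col] = df[col].astype(str)
            continue
        try:
            values = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"column {col!r}: cannot parse value ({exc})") from exc
        out[col] = values.astype(int if kind == "i" else float)
    # keep any extra columns as strings (provenance etc.)
    for col in df.columns:
        if col not in out.columns:
            out[col] = df[col]
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """All downstream tunables; defaults are the study values where stated."""

    # geometry (nm)
    voxel_size_nm: float = 1.0
    lumen_radius_nm: float = 7.0
    outer_radius_nm: float = 15.0
    template_length_nm: float = 100.0
    resample_step_nm: float = 1.0
    # picking
    smooth_sigma_px: float = 0.5
    target_shell_density: float = 0.006  # vertices / nm^3
    mean_shift_bandwidth_nm: float = 5.0
    # synthetic features
    mip_spacing_nm: float = 18.5
    mip_diameter_nm: float = 6.0
    mip_jitter_nm: float = 1.0
    spiral_diameter_nm: float = 37.8
    spiral_width_nm: float = 4.2
    spiral_spacing_nm: float = 4.6
    actin_spacing_nm: float = 5.5
    # statistics
    occupancy_threshold_nm: float = 50.0
    anterograde_threshold_um: float = 5.0
    stationary_threshold_um: float = 1.0
    retrograde_deadband_um: float = 0.2
    # tracing
    ncc_threshold: float = 0.1
    n_orientations: int = 100
    min_trace_length_nm: float = 50.0
    # misc
    contrast: str = PROTEIN_DARK
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
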