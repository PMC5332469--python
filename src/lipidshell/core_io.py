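"""Trajectory, topology-annotation, and volume I/O.

All lengths are nanometres internally.  Coordinate/trajectory files are read
through MDAnalysis (which reports Angstrom) and converted on load.  Volumes
are written as CCP4/MRC mode-2 (float32) maps through gemmi.

The topology annotation is a tabular sidecar (CSV), not a force-field
topology: per-atom name, residue, element, role, chain/carbon indexing for
acyl chains, partial charge and Lennard-Jones parameters.  This keeps the
package force-field agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TopologyTable",
    "LeafletAssignment",
    "DensityGrid3D",
    "ROLES",
    "read_trajectory",
    "assign_leaflets",
    "write_volume",
    "read_volume",
]

A_PER_NM = 10.0

#: recognised atom roles; the partition must be exhaustive and disjoint.
ROLES = (
    "phosphate",
    "chain_carbon",
    "headgroup_other",
    "protein",
    "solvent",
    "ion",
)

TOPOLOGY_COLUMNS = [
    "atom_index",
    "atom_name",
    "residue_id",
    "residue_name",
    "element",
    "role",
    "chain",
    "carbon_index",
    "charge",
    "lj_sigma",
    "lj_epsilon",
]


class FormatError(ValueError):
    """Unreadable or unsupported input file."""


class ConsistencyError(ValueError):
    """Mutually inconsistent inputs (e.g. atom-count mismatch)."""


class DegenerateBilayerError(ValueError):
    """Leaflet assignment impossible (all phosphates on one side)."""


@dataclass
class Trajectory:
    """Ordered frames of coordinates with per-frame orthorhombic box.

    Attributes
    ----------
    coords : (n_frames, n_atoms, 3) float array, nm
    box : (n_frames, 3) float array, nm — orthorhombic box lengths
    times : optional (n_frames,) array, ps
    """

    coords: np.ndarray
    box: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


class TopologyTable:
    """Per-atom annotations backed by a pandas DataFrame.

    Columns: atom_index, atom_name, residue_id, residue_name, element, role,
    chain (sn1/sn2 or empty), carbon_index (int, -1 if n/a), charge (e),
    lj_sigma (nm), lj_epsilon (kJ/mol).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"topology table missing columns: {missing}")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    # -- role selections -------------------------------------------------
    def mask(self, role: str | list[str]) -> np.ndarray:
        roles = [role] if isinstance(role, str) else list(role)
        return self.df["role"].isin(roles).to_numpy()

    @property
    def phosphate_mask(self) -> np.ndarray:
        return self.mask("phosphate")

    @property
    def protein_mask(self) -> np.ndarray:
        return self.mask("protein")

    def lipid_residue_ids(self) -> np.ndarray:
        return np.unique(self.df.loc[self.phosphate_mask, "residue_id"].to_numpy())

    def chain_carbon_indices(self, residue_id: int, chain: str) -> dict[int, int]:
        """Map carbon_index -> atom row index for one chain of one lipid."""
        sel = self.df[
            (self.df["residue_id"] == residue_id)
            & (self.df["role"] == "chain_carbon")
            & (self.df["chain"] == chain)
        ]
        return dict(zip(sel["carbon_index"].astype(int), sel.index))

    def validate_lipids(self) -> None:
        """Check the per-lipid invariants: one phosphate, >=2 carbons/chain."""
        for rid in self.lipid_residue_ids():
            res = self.df[self.df["residue_id"] == rid]
            if (res["role"] == "phosphate").sum() != 1:
                raise ConsistencyError(f"residue {rid}: expected exactly one phosphate atom")
            for ch in sorted(set(res.loc[res["role"] == "chain_carbon", "chain"])):
                n = ((res["role"] == "chain_carbon") & (res["chain"] == ch)).sum()
                if n < 2:
                    raise ConsistencyError(f"residue {rid} chain {ch}: fewer than 2 carbons")

    # -- persistence -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.df[TOPOLOGY_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TopologyTable":
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
        df["chain"] = df["chain"].astype(str)
        return cls(df)


@dataclass
class LeafletAssignment:
    """Leaflet label (+1 upper/extracellular, -1 lower/intracellular) per lipid."""

    residue_ids: np.ndarray
    leaflet: np.ndarray  # +1 / -1 per residue, same order as residue_ids
    midplane_z: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.midplane_z):
            raise ValueError("midplane_z must be finite")
        if set(np.unique(self.leaflet)) - {-1, 1}:
            raise ValueError("leaflet labels must be +1 or -1")

    def label_of(self, residue_id: int) -> int:
        idx = np.searchsorted(self.residue_ids, residue_id)
        return int(self.leaflet[idx])

    def residues(self, side: str) -> np.ndarray:
        want = 1 if side in ("upper", "extracellular") else -1
        return self.residue_ids[self.leaflet == want]


@dataclass
class DensityGrid3D:
    """Regular 3D scalar field.

    ``origin`` is the coordinate of the *center* of voxel (0, 0, 0);
    voxel values are field values at voxel centers.
    """

    origin: np.ndarray  # (3,) nm
    spacing: np.ndarray  # (3,) nm
    values: np.ndarray  # (nx, ny, nz)
    normalized: bool = False
    n_frames_accumulated: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be > 0 on all axes")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def copy(self) -> "DensityGrid3D":
        return DensityGrid3D(
            self.origin.copy(),
            self.spacing.copy(),
            self.values.copy(),
            self.normalized,
            self.n_frames_accumulated,
        )


# ---------------------------------------------------------------------------
# trajectory reading


def _check_orthorhombic(dimensions: np.ndarray) -> None:
    angles = dimensions[3:6]
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise FormatError(
            f"only orthorhombic boxes are supported (angles {angles}); "
            "triclinic input is not handled"
        )


def read_trajectory(
    coord_file: str | Path, traj_file: str | Path | None = None
) -> Trajectory:
    """Read a coordinate file (PDB/GRO) and optional trajectory (XTC/TRR/DCD).

    Returns coordinates in nm regardless of the source format's native unit.
    """
    import MDAnalysis as mda

    coord_file = Path(coord_file)
    if not coord_file.exists():
        raise FormatError(f"coordinate file not found: {coord_file}")
    try:
        if traj_file is None:
            u = mda.Universe(str(coord_file))
        else:
            traj_file = Path(traj_file)
            if not traj_file.exists():
                raise FormatError(f"trajectory file not found: {traj_file}")
            u = mda.Universe(str(coord_file), str(traj_file))
    except FormatError:
        raise
    except Exception as exc:  # MDAnalysis raises many flavours
        if traj_file is not None and "number of atoms" in str(exc).lower():
            raise ConsistencyError(str(exc)) from exc
        raise FormatError(f"could not read input: {exc}") from exc

    n_atoms = len(u.atoms)
    coords, boxes, times = [], [], []
    for ts in u.trajectory:
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise FormatError("frame without box dimensions")
        _check_orthorhombic(np.asarray(ts.dimensions, dtype=float))
        coords.append(ts.positions.astype(np.float64) / A_PER_NM)
        boxes.append(np.asarray(ts.dimensions[:3], dtype=np.float64) / A_PER_NM)
        times.append(float(getattr(ts, "time", 0.0)))
    traj = Trajectory(
        np.array(coords).reshape(-1, n_atoms, 3),
        np.array(boxes),
        np.array(times),
    )
    return traj


def check_consistency(traj: Trajectory, topo: TopologyTable) -> None:
    if traj.n_atoms != len(topo):
        raise ConsistencyError(
            f"trajectory has {traj.n_atoms} atoms but topology annotates {len(topo)}"
        )


# ---------------------------------------------------------------------------
# leaflet assignment


def assign_leaflets(
    traj: Trajectory, topo: TopologyTable, frame: int = 0
) -> LeafletAssignment:
    """Assign each lipid to a leaflet by its phosphate z versus the midplane.

    midplane_z is the mean z of all phosphate atoms in ``frame``; a lipid is
    upper (+1) if its phosphate lies above the midplane.  Deterministic.
    """
    check_consistency(traj, topo)
    pmask = topo.phosphate_mask
    if pmask.sum() < 2:
        raise DegenerateBilayerError("need >= 2 phosphate-role atoms")
    pz = traj.coords[frame, pmask, 2]
    rids = topo.df.loc[pmask, "residue_id"].to_numpy()
    order = np.argsort(rids)
    rids, pz = rids[order], pz[order]
    midplane = float(np.mean(pz))
    side = np.where(pz > midplane, 1, -1).astype(int)
    if np.all(side == side[0]):
        raise DegenerateBilayerError("all phosphates on one side of the midplane")
    return LeafletAssignment(rids, side, midplane)


# ---------------------------------------------------------------------------
# volume I/O (CCP4/MRC mode 2)


def write_volume(grid: DensityGrid3D, path: str | Path) -> None:
    """Write a CCP4/MRC mode-2 (float32) volume.

    The unit cell is spacing x shape (in Angstrom, per MRC convention) and the
    nm origin is stored in the MRC2014 ORIGIN header words.  NaN sentinel
    values (from masking) are not representable in a density volume: refuse.
    """
    import gemmi

    if not np.all(np.isfinite(grid.values)):
        raise ValueError("volume contains non-finite values; refusing to write")
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.shape
    g.unit_cell = gemmi.UnitCell(
        nx * grid.spacing[0] * A_PER_NM,
        ny * grid.spacing[1] * A_PER_NM,
        nz * grid.spacing[2] * A_PER_NM,
        90.0,
        90.0,
        90.0,
    )
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    # MRC2014 ORIGIN (words 50-52), stored in Angstrom
    for w, val in zip((50, 51, 52), grid.origin * A_PER_NM):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


def read_volume(path: str | Path) -> DensityGrid3D:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, copy=True).astype(np.float64)
    cell = m.grid.unit_cell
    shape = values.shape
    spacing = np.array(
        [cell.a / shape[0], cell.b / shape[1], cell.c / shape[2]]
    ) / A_PER_NM
    origin = np.array([m.header_float(w) for w in (50, 51, 52)]) / A_PER_NM
    return DensityGrid3D(origin, spacing, values)


# ---------------------------------------------------------------------------
# 2D grid text I/O helpers (matrix + JSON metadata sidecar)


def write_matrix(
    values: np.ndarray, path: str | Path, metadata: dict | None = None
) -> None:
    """Plain-text matrix; NaN encodes masked cells; metadata in a .json sidecar."""
    path = Path(path)
    np.savetxt(path, values, fmt="%.10g")
    if metadata is not None:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(metadata, fh, indent=1, sort_keys=True)


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict | None]:
    path = Path(path)
    values = np.loadtxt(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    metadata = None
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = json.load(fh)
    return values, metadata
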