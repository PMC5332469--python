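"""Leaflet-resolved 2D property maps on a lateral grid.

Implements the local-membrane-property machinery: inter-phosphate and
hydrophobic (carbon-2) thickness surfaces, Voronoi local area-per-lipid, and
carbon-deuterium order parameters S_CD, each binned on an nx x ny lateral
grid (100 x 100 by default) with optional radial masking around a reference
center, plus a radial profile reducer and the hexatic (psi-6) bond-orientational
order parameter used to detect gel-like hexagonal chain packing.

Conventions
-----------
* Grid cells are half-open intervals over the (time-averaged) box; samples
  are wrapped into the primary box before binning.
* A lipid is binned by the reference atom of the property in question
  (phosphate for thickness/APL, the carbon-k position for S_CD).
* S_CD at carbon k reconstructs the two C-H directions as an orthonormal
  pair perpendicular to the C(k-1)->C(k+1) axis; for any such pair the mean
  of (3 cos^2(theta) - 1)/2 over the two H's equals -1/2 times the second
  Legendre polynomial of the axis' angle to the normal, so the estimator is
  exactly the classic -S_axis/2 relation per sample.  Values are stored
  signed; display/report convention is |S_CD|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from scipy import ndimage

from .core_io import (
    LeafletAssignment,
    TopologyTable,
    Trajectory,
    check_consistency,
    read_matrix,
    write_matrix,
)

__all__ = [
    "PropertyGrid2D",
    "ScdSpec",
    "thickness_map",
    "apl_map",
    "scd_map",
    "radial_profile",
    "hexatic_order",
    "psi6",
    "voronoi_areas_periodic",
]


@dataclass
class PropertyGrid2D:
    """2D scalar field over the membrane plane with occupancy and mask."""

    values: np.ndarray  # (nx, ny); NaN where masked
    counts: np.ndarray  # (nx, ny) accumulated sample counts
    extent: tuple[float, float]  # box_x, box_y (nm)
    property: str
    units: str
    leaflet: str = "both"

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is valid (unmasked)."""
        return np.isfinite(self.values)

    @property
    def nx(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        dx = self.extent[0] / self.nx
        dy = self.extent[1] / self.ny
        return (
            dx * (np.arange(self.nx) + 0.5),
            dy * (np.arange(self.ny) + 0.5),
        )

    def save(self, path) -> None:
        write_matrix(
            self.values,
            path,
            metadata={
                "extent": list(self.extent),
                "property": self.property,
                "units": self.units,
                "leaflet": self.leaflet,
                "counts_total": int(self.counts.sum()),
            },
        )

    @classmethod
    def load(cls, path) -> "PropertyGrid2D":
        values, meta = read_matrix(path)
        meta = meta or {}
        return cls(
            values=values,
            counts=np.zeros_like(values),
            extent=tuple(meta.get("extent", (1.0, 1.0))),
            property=meta.get("property", "unknown"),
            units=meta.get("units", ""),
            leaflet=meta.get("leaflet", "both"),
        )


@dataclass
class ScdSpec:
    carbon_index: int
    chain: str = "both"  # "sn1" | "sn2" | "both"
    leaflet: str = "upper"  # "upper" | "lower"


# ---------------------------------------------------------------------------
# binning helpers


def _bin_indices(xy: np.ndarray, extent, nx: int, ny: int) -> tuple[np.ndarray, np.ndarray]:
    bx, by = extent
    x = np.mod(xy[:, 0], bx)
    y = np.mod(xy[:, 1], by)
    ix = np.minimum((x / (bx / nx)).astype(int), nx - 1)
    iy = np.minimum((y / (by / ny)).astype(int), ny - 1)
    return ix, iy


def _radial_mask(extent, nx, ny, center, cutoff) -> np.ndarray:
    dx, dy = extent[0] / nx, extent[1] / ny
    xc = dx * (np.arange(nx) + 0.5)
    yc = dy * (np.arange(ny) + 0.5)
    r = np.hypot(xc[:, None] - center[0], yc[None, :] - center[1])
    return r <= cutoff


def _nearest_fill(values: np.ndarray) -> np.ndarray:
    """Fill NaN cells with the nearest valid cell's value (Euclidean index
    distance)."""
    invalid = ~np.isfinite(values)
    if not invalid.any():
        return values
    if invalid.all():
        raise ValueError("no valid cells to fill from")
    ind = ndimage.distance_transform_edt(
        invalid, return_distances=False, return_indices=True
    )
    return values[tuple(ind)]


def _phosphate_rows(topo: TopologyTable, residue_ids: np.ndarray) -> np.ndarray:
    """Row index of the phosphate atom of each residue, aligned to residue_ids."""
    df = topo.df
    rows = df.index[topo.phosphate_mask].to_numpy()
    rid = df.loc[rows, "residue_id"].to_numpy()
    sel = {r: i for r, i in zip(rid, rows)}
    return np.array([sel[r] for r in residue_ids])


def _carbon_rows(
    topo: TopologyTable, residue_ids: np.ndarray, carbon_index: int, chain: str
) -> np.ndarray:
    """Row index of carbon ``carbon_index`` of ``chain``, aligned to residue_ids."""
    df = topo.df
    sel = df[
        (df["role"] == "chain_carbon")
        & (df["carbon_index"] == carbon_index)
        & (df["chain"] == chain)
    ]
    lut = dict(zip(sel["residue_id"].to_numpy(), sel.index.to_numpy()))
    try:
        return np.array([lut[r] for r in residue_ids])
    except KeyError as exc:
        raise ValueError(
            f"carbon {carbon_index} ({chain}) missing for residue {exc.args[0]}"
        ) from exc


def _reference_positions(
    traj: Trajectory, frame: int, rows: np.ndarray | tuple
) -> np.ndarray:
    """Reference positions per lipid: single row array, or a tuple of two row
    arrays whose positions are averaged under the minimum image (hydrophobic
    carbon-2 reference; the pair may straddle the periodic boundary)."""
    if isinstance(rows, tuple):
        a = traj.coords[frame, rows[0], :]
        d = traj.coords[frame, rows[1], :] - a
        box = traj.box[frame]
        d = d - box * np.round(d / box)
        return a + 0.5 * d
    return traj.coords[frame, rows, :]


# ---------------------------------------------------------------------------
# thickness


def thickness_map(
    traj: Trajectory,
    topo: TopologyTable,
    leaflets: LeafletAssignment,
    kind: str = "pp",
    nx: int = 100,
    ny: int = 100,
    radial_cutoff: float | None = 6.5,
    center: tuple[float, float] | None = None,
) -> PropertyGrid2D:
    """Local bilayer thickness: upper minus lower leaflet reference surface.

    ``kind='pp'`` uses phosphate z (inter-phosphate thickness);
    ``kind='hydrophobic'`` uses the mean position of the two carbon-2 atoms
    of each lipid.  Per-cell surfaces are time-averaged; cells left empty are
    filled from the nearest valid cell before the leaflet subtraction.
    """
    if kind not in ("pp", "hydrophobic"):
        raise ValueError("kind must be 'pp' or 'hydrophobic'")
    check_consistency(traj, topo)
    extent = tuple(traj.box.mean(axis=0)[:2])
    zsum = {s: np.zeros((nx, ny)) for s in (1, -1)}
    cnt = {s: np.zeros((nx, ny)) for s in (1, -1)}
    for side in (1, -1):
        rids = leaflets.residue_ids[leaflets.leaflet == side]
        if len(rids) == 0:
            raise ValueError("a leaflet has zero reference lipids")
        if kind == "pp":
            rows = _phosphate_rows(topo, rids)
        else:
            rows = (
                _carbon_rows(topo, rids, 2, "sn1"),
                _carbon_rows(topo, rids, 2, "sn2"),
            )
        for f in range(traj.n_frames):
            pos = _reference_positions(traj, f, rows)
            ix, iy = _bin_indices(pos[:, :2], extent, nx, ny)
            np.add.at(zsum[side], (ix, iy), pos[:, 2])
            np.add.at(cnt[side], (ix, iy), 1.0)
    surfaces = {}
    for side in (1, -1):
        with np.errstate(invalid="ignore"):
            surf = zsum[side] / cnt[side]
        surfaces[side] = _nearest_fill(surf)
    values = surfaces[1] - surfaces[-1]
    counts = cnt[1] + cnt[-1]
    if radial_cutoff is not None:
        c = center if center is not None else (extent[0] / 2, extent[1] / 2)
        values = np.where(_radial_mask(extent, nx, ny, c, radial_cutoff), values, np.nan)
    return PropertyGrid2D(
        values, counts, extent,
        property=f"thickness_{kind}", units="nm", leaflet="both",
    )


# ---------------------------------------------------------------------------
# area per lipid (Voronoi)


def voronoi_areas_periodic(xy: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Voronoi cell area of each site under periodic boundary conditions.

    The sites are wrapped into the box and surrounded by their 8 periodic
    images; the central cells then exactly tile the box, so the areas sum to
    the box area to floating-point precision.
    """
    n = len(xy)
    if n < 3:
        raise ValueError("need >= 3 sites for a Voronoi tessellation")
    bx, by = box
    pts = np.column_stack([np.mod(xy[:, 0], bx), np.mod(xy[:, 1], by)])
    images = []
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            images.append(pts + np.array([sx * bx, sy * by]))
    allpts = np.vstack(images)
    # central copy occupies block index 4
    off = 4 * n
    try:
        vor = Voronoi(allpts)
    except Exception as exc:
        raise ValueError(f"degenerate site configuration: {exc}") from exc
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[off + i]]
        if -1 in region or len(region) == 0:
            raise ValueError(f"unbounded Voronoi cell for site {i}")
        verts = vor.vertices[region]
        x, y = verts[:, 0], verts[:, 1]
        areas[i] = 0.5 * np.abs(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )
    return areas


def apl_map(
    traj: Trajectory,
    topo: TopologyTable,
    leaflets: LeafletAssignment,
    leaflet: str = "upper",
    nx: int = 100,
    ny: int = 100,
    radial_cutoff: float | None = 6.5,
    center: tuple[float, float] | None = None,
    protein_seeds: bool = True,
) -> PropertyGrid2D:
    """Local area per lipid from a periodic Voronoi tessellation of the
    phosphate positions.

    Each grid cell takes the Voronoi area of the lipid owning the cell
    center in that frame, then time-averages.  ``leaflet`` may be 'upper',
    'lower', or 'both' (the two leaflet maps averaged).  With
    ``protein_seeds`` (default) the lateral positions of protein atoms are
    included as extra tessellation seeds so lipid cells do not extend into
    the protein footprint; grid cells owned by protein seeds are masked and
    the per-lipid area conservation then holds over the lipid-owned region.
    """
    if leaflet == "both":
        up = apl_map(traj, topo, leaflets, "upper", nx, ny, radial_cutoff,
                     center, protein_seeds)
        lo = apl_map(traj, topo, leaflets, "lower", nx, ny, radial_cutoff,
                     center, protein_seeds)
        vals = 0.5 * (up.values + lo.values)
        return PropertyGrid2D(
            vals, up.counts + lo.counts, up.extent, "apl", "nm^2", "both"
        )
    check_consistency(traj, topo)
    side = 1 if leaflet in ("upper", "extracellular") else -1
    rids = leaflets.residue_ids[leaflets.leaflet == side]
    if len(rids) < 3:
        raise ValueError("need >= 3 lipids in the leaflet")
    extent = tuple(traj.box.mean(axis=0)[:2])
    bx, by = extent
    xc = (bx / nx) * (np.arange(nx) + 0.5)
    yc = (by / ny) * (np.arange(ny) + 0.5)
    centers = np.stack(np.meshgrid(xc, yc, indexing="ij"), axis=-1).reshape(-1, 2)
    vsum = np.zeros(nx * ny)
    cnt = np.zeros(nx * ny)
    prow = _phosphate_rows(topo, rids)
    prot_rows = np.flatnonzero(topo.protein_mask) if protein_seeds else np.array([], int)
    n_lip = len(prow)
    for f in range(traj.n_frames):
        pos = traj.coords[f, prow, :]
        xy = np.column_stack([np.mod(pos[:, 0], bx), np.mod(pos[:, 1], by)])
        if len(prot_rows):
            pxy = traj.coords[f, prot_rows, :2]
            pxy = np.column_stack([np.mod(pxy[:, 0], bx), np.mod(pxy[:, 1], by)])
            # protein atoms stacked along z share lateral positions; qhull
            # needs distinct seeds
            pxy = np.unique(np.round(pxy, 6), axis=0)
            seeds = np.vstack([xy, pxy])
        else:
            seeds = xy
        areas = voronoi_areas_periodic(seeds, extent)
        # ownership: nearest seed under periodic images
        images, owner_ids = [], []
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                images.append(seeds + np.array([sx * bx, sy * by]))
                owner_ids.append(np.arange(len(seeds)))
        tree = cKDTree(np.vstack(images))
        _, j = tree.query(centers, k=1)
        owner = np.concatenate(owner_ids)[j]
        lipid_owned = owner < n_lip
        vsum[lipid_owned] += areas[owner[lipid_owned]]
        cnt[lipid_owned] += 1.0
    with np.errstate(invalid="ignore"):
        values = (vsum / cnt).reshape(nx, ny)
    values[cnt.reshape(nx, ny) == 0] = np.nan
    counts = cnt.reshape(nx, ny)
    if radial_cutoff is not None:
        c = center if center is not None else (bx / 2, by / 2)
        values = np.where(_radial_mask(extent, nx, ny, c, radial_cutoff), values, np.nan)
    return PropertyGrid2D(values, counts, extent, "apl", "nm^2", leaflet)


# ---------------------------------------------------------------------------
# S_CD order parameters


def scd_samples(
    coords_km1: np.ndarray, coords_kp1: np.ndarray, box: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Signed per-sample S_CD from the C(k-1) and C(k+1) positions.

    The two reconstructed C-H unit vectors form an orthonormal pair
    perpendicular to the C(k-1)->C(k+1) axis; their mean of
    (3 cos^2 theta - 1)/2 against the z normal equals -1/2 P2(cos_axis)
    identically, independent of the azimuth of the pair (validated
    numerically against explicit tetrahedral-geometry sampling in tests).
    The axis is taken under the minimum image if ``box`` is given (chains
    wrapped across the periodic boundary).  Returns (signed S_CD, validity
    mask); zero-length axes are invalid.
    """
    axis = coords_kp1 - coords_km1
    if box is not None:
        axis = axis - box * np.round(axis / box)
    norm = np.sqrt(axis[:, 0] ** 2 + axis[:, 1] ** 2 + axis[:, 2] ** 2)
    valid = norm > 0.0
    if not valid.all():
        warnings.warn("zero-length chain axis; sample(s) skipped")
    cos_axis = np.where(valid, axis[:, 2] / np.where(valid, norm, 1.0), 0.0)
    s = -0.5 * (0.5 * (3.0 * cos_axis * cos_axis - 1.0))
    return s, valid


def scd_map(
    traj: Trajectory,
    topo: TopologyTable,
    leaflets: LeafletAssignment,
    spec: ScdSpec,
    nx: int = 100,
    ny: int = 100,
    radial_cutoff: float | None = 6.5,
    center: tuple[float, float] | None = None,
    signed: bool = False,
) -> PropertyGrid2D:
    """Map of the carbon-deuterium order parameter at carbon ``spec.carbon_index``.

    Samples are binned by the lateral position of carbon k; the reported cell
    value is |S_CD| unless ``signed=True``.  ``spec.chain='both'`` averages
    the sn1 and sn2 chains.
    """
    check_consistency(traj, topo)
    side = 1 if spec.leaflet in ("upper", "extracellular") else -1
    rids = leaflets.residue_ids[leaflets.leaflet == side]
    extent = tuple(traj.box.mean(axis=0)[:2])
    chains = ("sn1", "sn2") if spec.chain == "both" else (spec.chain,)
    k = spec.carbon_index
    rowsets = {
        ch: (
            _carbon_rows(topo, rids, k - 1, ch),
            _carbon_rows(topo, rids, k, ch),
            _carbon_rows(topo, rids, k + 1, ch),
        )
        for ch in chains
    }
    ssum = np.zeros((nx, ny))
    cnt = np.zeros((nx, ny))
    for f in range(traj.n_frames):
        for ch in chains:
            rm1, r0, rp1 = rowsets[ch]
            s, valid = scd_samples(
                traj.coords[f, rm1], traj.coords[f, rp1], traj.box[f]
            )
            xy = traj.coords[f, r0, :2][valid]
            ix, iy = _bin_indices(xy, extent, nx, ny)
            np.add.at(ssum, (ix, iy), s[valid])
            np.add.at(cnt, (ix, iy), 1.0)
    with np.errstate(invalid="ignore"):
        values = ssum / cnt
    if not signed:
        values = np.abs(values)
    values[cnt == 0] = np.nan
    if radial_cutoff is not None:
        c = center if center is not None else (extent[0] / 2, extent[1] / 2)
        values = np.where(_radial_mask(extent, nx, ny, c, radial_cutoff), values, np.nan)
    return PropertyGrid2D(
        values, cnt, extent,
        property=f"scd_C{spec.carbon_index}_{spec.chain}", units="",
        leaflet=spec.leaflet,
    )


# ---------------------------------------------------------------------------
# radial profile


def radial_profile(
    grid: PropertyGrid2D,
    center: tuple[float, float] | None = None,
    dr: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Count-weighted mean of cell values in annular bins of width ``dr``.

    Returns (bin centers, values); bins with zero weight are NaN.
    """
    if dr <= 0:
        raise ValueError("dr must be > 0")
    if center is None:
        center = (grid.extent[0] / 2, grid.extent[1] / 2)
    xc, yc = grid.cell_centers()
    r = np.hypot(xc[:, None] - center[0], yc[None, :] - center[1])
    valid = grid.mask
    if not valid.any():
        raise ValueError("grid has no unmasked cells")
    rmax = r[valid].max()
    nbins = int(np.ceil(rmax / dr))
    ib = np.minimum((r / dr).astype(int), nbins - 1)
    w = np.where(valid, np.maximum(grid.counts, 1.0), 0.0)
    num = np.bincount(ib.ravel(), (np.nan_to_num(grid.values) * w).ravel(), nbins)
    den = np.bincount(ib.ravel(), w.ravel(), nbins)
    with np.errstate(invalid="ignore"):
        prof = num / den
    prof[den == 0] = np.nan
    return dr * (np.arange(nbins) + 0.5), prof


# ---------------------------------------------------------------------------
# hexatic order


def psi6(
    xy: np.ndarray, box: tuple[float, float], neighbor_cutoff: float
) -> np.ndarray:
    """Per-site |psi6| of a 2D point pattern under periodic minimum image.

    psi6(j) = |(1/n_j) sum_k exp(6 i theta_jk)| over neighbors within the
    cutoff; sites with no neighbors get NaN.
    """
    n = len(xy)
    if n < 7:
        raise ValueError("need >= 7 sites")
    bx, by = box
    pts = np.column_stack([np.mod(xy[:, 0], bx), np.mod(xy[:, 1], by)])
    out = np.full(n, np.nan)
    # neighbor search with periodic images
    images, ids = [], []
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            images.append(pts + np.array([sx * bx, sy * by]))
            ids.append(np.arange(n))
    allpts = np.vstack(images)
    tree = cKDTree(allpts)
    pairs = tree.query_ball_point(pts, neighbor_cutoff)
    for j in range(n):
        acc = 0.0 + 0.0j
        cnt = 0
        for m in pairs[j]:
            k = m % n
            if k == j and np.allclose(allpts[m], pts[j]):
                continue
            d = allpts[m] - pts[j]
            if d[0] == 0.0 and d[1] == 0.0:
                continue
            acc += np.exp(6j * np.arctan2(d[1], d[0]))
            cnt += 1
        if cnt:
            out[j] = np.abs(acc / cnt)
    return out


def hexatic_order(
    traj: Trajectory,
    topo: TopologyTable,
    leaflets: LeafletAssignment,
    leaflet: str = "upper",
    carbon_index: int = 2,
    neighbor_cutoff: float = 0.8,
    frames: slice | None = None,
) -> tuple[np.ndarray, float]:
    """Mean hexatic order of the chain-carbon lateral pattern in one leaflet.

    Uses the carbon ``carbon_index`` bead of both chains of every lipid in
    the leaflet as the 2D point pattern, per frame; returns the per-site
    values of the last evaluated frame and the overall mean |psi6|.
    """
    check_consistency(traj, topo)
    side = 1 if leaflet in ("upper", "extracellular") else -1
    rids = set(leaflets.residue_ids[leaflets.leaflet == side])
    df = topo.df
    rows = df.index[
        (df["role"] == "chain_carbon")
        & (df["carbon_index"] == carbon_index)
        & (df["residue_id"].isin(rids))
    ].to_numpy()
    if len(rows) < 7:
        raise ValueError("need >= 7 chain sites")
    box = tuple(traj.box.mean(axis=0)[:2])
    fr = range(traj.n_frames)[frames] if frames is not None else range(traj.n_frames)
    means = []
    vals = None
    for f in fr:
        vals = psi6(traj.coords[f, rows, :2], box, neighbor_cutoff)
        means.append(np.nanmean(vals))
    return vals, float(np.mean(means))
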