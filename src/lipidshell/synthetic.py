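"""Synthetic bilayer trajectory generator with known ground truth.

Generates planar two-leaflet bilayers of coarse multi-bead lipids (one
phosphate bead + two acyl chains of indexed carbon beads), optionally with an
embedded rigid C4-symmetric cylindrical inclusion ("protein"), annular
density enhancement, and harmonically restrained inclusion beads.

Frames are independent redraws of configurational noise around fixed lattice
sites, not integrated dynamics: every analysis this package performs is a
time average of configurational quantities, so i.i.d. sampling gives exact,
analytically known statistics for parameter-recovery tests.

Phase presets:

* fluid (liquid-crystalline, L_alpha): square lipid lattice with large
  lateral site jitter, area-per-lipid 0.60 nm^2, P-P thickness 3.5 nm,
  hydrophobic (carbon-2) thickness 2.9 nm, segmental chain order 0.4.
* gel (L_beta): hexagonal chain lattice with small jitter, area-per-lipid
  0.48 nm^2, thicker leaflets, segmental order 0.9.

Chain order is imposed by drawing each chain director uniformly from a
spherical cap whose half-angle is calibrated so the mean second Legendre
polynomial P2(cos beta) of the director against the bilayer normal equals
the requested segmental order; a fixed collective tilt multiplies in as
P2(cos tilt) (addition theorem with uniform azimuth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .core_io import TOPOLOGY_COLUMNS, TopologyTable, Trajectory

__all__ = [
    "InclusionSpec",
    "SyntheticBilayerSpec",
    "GroundTruth",
    "generate_bilayer",
    "generate_inclusion_system",
    "write_system",
]

#: kT at 310 K in kJ/mol
KT_310 = 2.577


class PackingError(ValueError):
    """Requested lipids do not fit in the box at the target area per lipid."""


class GeometryError(ValueError):
    """Inconsistent inclusion geometry."""


@dataclass
class InclusionSpec:
    """Rigid C4-symmetric cylindrical inclusion embedded in the bilayer."""

    radius: float = 1.2  # nm, lipid exclusion radius
    c4_asymmetry: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    bead_radius: float = 1.0  # nm, radial position of the bead rings
    n_levels: int = 5  # bead rings along z
    beads_per_quadrant: int = 3  # per ring; total per ring = 4x this
    static: bool = False  # if True, beads are frozen (restrained limit)
    # two-domain options: lipids within [radius, radius+annulus_domain_width]
    # get their own lattice/ordering parameters (lattice mode only)
    annulus_domain_width: float | None = None
    annulus_apl: float | None = None
    annulus_half_thickness_pp: float | None = None
    annulus_half_thickness_c2: float | None = None
    annulus_chain_order_s: float | None = None


@dataclass
class SyntheticBilayerSpec:
    """Full parameterization of a generated bilayer system.

    Lengths in nm, areas in nm^2, energies in kJ/mol.  ``positional_noise_sigma``
    is an isotropic rigid-body translation applied per lipid per frame (the
    lipid's internal geometry is preserved, so chain order is unaffected);
    ``site_jitter_sigma`` is additional lateral disorder of the lattice sites.
    """

    n_lipids_per_leaflet: int = 196
    apl_target: float = 0.60
    box_xy: float | None = None  # derived from apl_target if None
    box_z: float = 7.0
    half_thickness_pp: float = 1.75
    half_thickness_c2: float = 1.45
    chain_length: int = 14
    chain_tilt_deg: float = 0.0
    chain_order_s: float = 0.40
    positional_noise_sigma: float = 0.05
    site_jitter_sigma: float | None = None  # default by lattice type
    lattice: str = "square"  # "square" | "hex"
    chain_spread: float = 0.25  # sn1-sn2 lateral separation, nm
    inclusion: InclusionSpec | None = None
    annular_enhancement: float = 1.0
    annulus_width: float = 0.5  # nm, for occupancy enhancement
    restraint_k: float = 1000.0  # kJ/(nm^2 mol), inclusion bead restraints
    temperature_kT: float = KT_310
    n_frames: int = 100
    seed: int = 0

    @classmethod
    def fluid(cls, **kw) -> "SyntheticBilayerSpec":
        return cls(**kw)

    @classmethod
    def gel(cls, **kw) -> "SyntheticBilayerSpec":
        defaults = dict(
            apl_target=0.48,
            half_thickness_pp=1.95,
            half_thickness_c2=1.65,
            chain_order_s=0.90,
            lattice="hex",
            site_jitter_sigma=0.02,
            positional_noise_sigma=0.02,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """True values of the quantities the analysis modules estimate."""

    residue_ids: list[int]
    leaflet_labels: list[int]  # +1 upper / -1 lower, parallel to residue_ids
    box_xy: tuple[float, float]
    n_lipids_per_leaflet: int
    thickness_pp: float
    thickness_hydrophobic: float
    apl: float
    scd: float  # |S_CD| for every interior carbon (uniform along the chain)
    chain_order: float  # achieved segmental order of the C(k-1)->C(k+1) axis
    annulus: dict = field(default_factory=dict)  # two-domain true values
    annular_occupancy_ratio: list[float] = field(
        default_factory=lambda: [1.0, 1.0, 1.0, 1.0]
    )
    annulus_radii: tuple[float, float] | None = None
    inclusion_center: tuple[float, float] | None = None
    restrained_bead_sd: float | None = None  # per-coordinate SD, nm

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("box_xy", "annulus_radii", "inclusion_center"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# order-parameter calibration


def _p2(c: float | np.ndarray):
    return 0.5 * (3.0 * np.asarray(c) ** 2 - 1.0)


def _cap_cos_min(target_order: float) -> float:
    """Cap lower cosine bound c0 such that a director uniform in the cap
    [c0, 1] has mean P2 equal to ``target_order``.

    For cos(beta) uniform on [c0, 1], <P2> = c0 (1 + c0) / 2.
    """
    if not -0.124 < target_order <= 1.0:
        raise ValueError(f"unreachable cap order {target_order}")
    if target_order >= 1.0:
        return 1.0
    return brentq(lambda c0: 0.5 * c0 * (1.0 + c0) - target_order, -0.49, 1.0)


# ---------------------------------------------------------------------------
# lattices


def _square_lattice(n_target: int, apl: float) -> tuple[np.ndarray, float, float, int]:
    nx = int(round(np.sqrt(n_target)))
    nx = max(nx, 1)
    ny = int(round(n_target / nx))
    n = nx * ny
    a = np.sqrt(apl)
    bx, by = nx * a, ny * a
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.column_stack([(ix.ravel() + 0.5) * a, (iy.ravel() + 0.5) * a])
    return pts, bx, by, n

def _hex_lattice(n_target: int, area_per_site: float) -> tuple[np.ndarray, float, float, int]:
    """Periodic-perfect hexagonal lattice; returns sites and box size."""
    a = np.sqrt(2.0 * area_per_site / np.sqrt(3.0))
    dy = a * np.sqrt(3.0) / 2.0
    nx = int(round(np.sqrt(n_target)))
    if nx % 2:
        nx += 1
    ny = int(round(n_target / nx))
    if ny % 2:
        ny += 1
    n = nx * ny
    bx, by = nx * a, ny * dy
    rows = []
    for j in range(ny):
        xoff = 0.25 * a if j % 2 == 0 else 0.75 * a
        xs = xoff + a * np.arange(nx)
        rows.append(np.column_stack([xs, np.full(nx, (j + 0.5) * dy)]))
    return np.vstack(rows), bx, by, n


def _hex_patch(bx: float, by: float, area_per_site: float) -> np.ndarray:
    """Hex lattice covering [0,bx)x[0,by) without periodic closure (for
    two-domain constructions where only a sub-region is kept)."""
    a = np.sqrt(2.0 * area_per_site / np.sqrt(3.0))
    dy = a * np.sqrt(3.0) / 2.0
    ny = int(np.ceil(by / dy))
    rows = []
    for j in range(ny):
        xoff = (0.25 if j % 2 == 0 else 0.75) * a
        xs = xoff + a * np.arange(int(np.ceil(bx / a)) + 1)
        rows.append(np.column_stack([xs, np.full_like(xs, (j + 0.5) * dy)]))
    pts = np.vstack(rows)
    return pts[(pts[:, 0] < bx) & (pts[:, 1] < by)]


# ---------------------------------------------------------------------------
# system assembly helpers


def _chain_step(half_c2: float, chain_length: int) -> float:
    # terminal carbon ends ~0.15 nm short of the midplane
    return (half_c2 - 0.15) / max(chain_length - 2, 1)


def _build_lipid_coords(
    sites: np.ndarray,
    leaflet: np.ndarray,
    directors_sn1: np.ndarray,
    directors_sn2: np.ndarray,
    chain_offsets: np.ndarray,
    half_pp: np.ndarray,
    half_c2: np.ndarray,
    chain_length: int,
) -> np.ndarray:
    """Coordinates for one frame, atoms ordered per lipid as
    [P, sn1 C1..CL, sn2 C1..CL].  ``half_pp``/``half_c2`` are per-lipid."""
    n = len(sites)
    L = chain_length
    step = _chain_step(float(np.mean(half_c2)), L)
    coords = np.empty((n, 1 + 2 * L, 3))
    coords[:, 0, 0] = sites[:, 0]
    coords[:, 0, 1] = sites[:, 1]
    coords[:, 0, 2] = leaflet * half_pp
    ks = np.arange(1, L + 1)
    for ci, (dirs, sign) in enumerate(
        ((directors_sn1, 1.0), (directors_sn2, -1.0))
    ):
        # director points from headgroup toward midplane
        d = dirs.copy()
        d[:, 2] = -leaflet * np.abs(d[:, 2])
        anchor = np.column_stack(
            [
                sites[:, 0] + sign * chain_offsets[:, 0] / 2.0,
                sites[:, 1] + sign * chain_offsets[:, 1] / 2.0,
                leaflet * half_c2,
            ]
        )
        # carbon k at anchor + (k-2)*step*d  (carbon-2 exactly at the anchor)
        disp = (ks - 2)[None, :, None] * step * d[:, None, :]
        coords[:, 1 + ci * L : 1 + (ci + 1) * L, :] = anchor[:, None, :] + disp
    return coords


def _protein_beads(inc: InclusionSpec, center: np.ndarray, half_pp: float) -> np.ndarray:
    """Exactly C4-symmetric bead cylinder: beads placed in one quadrant and
    replicated by 90-degree rotations."""
    if inc.bead_radius >= inc.radius + 0.5:
        raise GeometryError("bead_radius should not exceed the exclusion radius")
    zs = np.linspace(-0.85, 0.85, inc.n_levels) * half_pp
    ang0 = (np.arange(inc.beads_per_quadrant) + 0.5) * (np.pi / 2) / inc.beads_per_quadrant
    beads = []
    for z in zs:
        for k in range(4):
            ang = ang0 + k * np.pi / 2
            beads.append(
                np.column_stack(
                    [
                        center[0] + inc.bead_radius * np.cos(ang),
                        center[1] + inc.bead_radius * np.sin(ang),
                        np.full_like(ang, z),
                    ]
                )
            )
    return np.vstack(beads)


def _quadrant(xy: np.ndarray, center: np.ndarray) -> np.ndarray:
    ang = np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0]) % (2 * np.pi)
    return np.minimum((ang / (np.pi / 2)).astype(int), 3)


def _resample_sites(
    rng: np.random.Generator,
    n: int,
    box: np.ndarray,
    center: np.ndarray,
    r_excl: float,
    r_out: float,
    weights: np.ndarray,
) -> np.ndarray:
    """Rejection-sample lipid sites from a piecewise-constant lateral density:
    0 inside r_excl, ``weights[quadrant]`` in the annulus [r_excl, r_out),
    1 outside."""
    wmax = max(float(np.max(weights)), 1.0)
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = 4 * (n - got) + 16
        pts = rng.uniform(0.0, 1.0, (m, 2)) * box[None, :]
        r = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        w = np.where(r < r_excl, 0.0, 1.0)
        in_ann = (r >= r_excl) & (r < r_out)
        if np.any(in_ann):
            w[in_ann] = weights[_quadrant(pts[in_ann], center)]
        keep = pts[rng.uniform(0.0, wmax, m) < w]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


# ---------------------------------------------------------------------------
# topology construction


def _lipid_topology_rows(residue_id: int, first_atom: int, chain_length: int) -> list:
    rows = [
        [first_atom, "P", residue_id, "LIP", "P", "phosphate", "", -1, -0.8, 0.45, 0.8]
    ]
    i = first_atom + 1
    for chain in ("sn1", "sn2"):
        for k in range(1, chain_length + 1):
            rows.append(
                [i, f"C{k}{chain[-1]}", residue_id, "LIP", "C", "chain_carbon",
                 chain, k, 0.0, 0.39, 0.30]
            )
            i += 1
    return rows


def _protein_topology_rows(n_beads: int) -> list:
    rows = []
    for i in range(n_beads):
        q = 0.4 if i % 2 == 0 else -0.4
        rows.append([i, "BB", i + 1, "PRB", "C", "protein", "", -1, q, 0.40, 0.50])
    return rows


# ---------------------------------------------------------------------------
# generators


def generate_bilayer(
    spec: SyntheticBilayerSpec,
) -> tuple[Trajectory, TopologyTable, GroundTruth]:
    """Planar bilayer without inclusion; see module docstring."""
    return _generate(spec, inclusion=False)


def generate_inclusion_system(
    spec: SyntheticBilayerSpec,
) -> tuple[Trajectory, TopologyTable, GroundTruth]:
    """Bilayer with embedded C4 inclusion, annular enhancement and/or
    two-domain lattice, and (optionally restrained) protein beads."""
    if spec.inclusion is None:
        raise ValueError("spec.inclusion must be set")
    return _generate(spec, inclusion=True)


def _generate(spec, inclusion: bool):
    rng = np.random.default_rng(spec.seed)
    L = spec.chain_length
    tilt = np.deg2rad(spec.chain_tilt_deg)
    if not 0.0 <= spec.chain_tilt_deg < 90.0:
        raise ValueError("chain_tilt_deg must be in [0, 90)")
    p2_tilt = float(_p2(np.cos(tilt)))
    cap_order = spec.chain_order_s / p2_tilt
    cos_min = _cap_cos_min(cap_order)
    achieved_order = 0.5 * cos_min * (1.0 + cos_min) * p2_tilt

    inc = spec.inclusion if inclusion else None
    resample = inclusion and (
        spec.annular_enhancement != 1.0
        or (inc is not None and any(f != 1.0 for f in inc.c4_asymmetry))
    )

    # --- lattice sites and box -----------------------------------------
    two_domain = inc is not None and inc.annulus_apl is not None
    ann_truth: dict = {}
    if spec.lattice == "hex":
        # chain-resolved hexagonal packing: two adjacent sites per lipid
        sites_c, bx, by, n_sites = _hex_lattice(
            2 * spec.n_lipids_per_leaflet, spec.apl_target / 2.0
        )
        # pair columns (2j, 2j+1) within each row into lipids
        order = np.lexsort((sites_c[:, 0], np.round(sites_c[:, 1], 6)))
        sites_c = sites_c[order]
        s1 = sites_c[0::2]
        s2 = sites_c[1::2]
        sites0 = 0.5 * (s1 + s2)
        chain_off0 = s2 - s1
        n_lip = len(sites0)
    else:
        sites0, bx, by, n_lip = _square_lattice(
            spec.n_lipids_per_leaflet, spec.apl_target
        )
        chain_off0 = None  # random azimuth per lipid, fixed over time
    if spec.box_xy is not None:
        if spec.apl_target * spec.n_lipids_per_leaflet > spec.box_xy**2 * 1.0000001:
            raise PackingError("lipids do not fit the requested box at apl_target")
        # keep the derived (lattice-consistent) box; requested box only validated
    box = np.array([bx, by, spec.box_z])
    center = np.array([bx / 2.0, by / 2.0])

    jitter = spec.site_jitter_sigma
    if jitter is None:
        jitter = 0.4 if spec.lattice == "square" else 0.02

    # --- inclusion-driven site filtering / two-domain lattices ----------
    is_annulus = None
    if inc is not None:
        if inc.radius >= min(bx, by) / 2.0:
            raise GeometryError("inclusion radius must be < half the box")
        if two_domain:
            r_in, r_dom = inc.radius, inc.radius + (inc.annulus_domain_width or 1.6)
            ann_sites = _hex_patch(bx, by, inc.annulus_apl)
            ra = np.hypot(ann_sites[:, 0] - center[0], ann_sites[:, 1] - center[1])
            ann_sites = ann_sites[(ra >= r_in + 0.2) & (ra < r_dom)]
            rb = np.hypot(sites0[:, 0] - center[0], sites0[:, 1] - center[1])
            a_bulk = np.sqrt(spec.apl_target)
            bulk_sites = sites0[rb >= r_dom + 0.6 * a_bulk]
            sites0 = np.vstack([ann_sites, bulk_sites])
            is_annulus = np.zeros(len(sites0), bool)
            is_annulus[: len(ann_sites)] = True
            chain_off0 = None
            n_lip = len(sites0)
            ann_truth = {
                "apl": inc.annulus_apl,
                "thickness_pp": 2.0 * (inc.annulus_half_thickness_pp or spec.half_thickness_pp),
                "thickness_hydrophobic": 2.0 * (inc.annulus_half_thickness_c2 or spec.half_thickness_c2),
            }
            if inc.annulus_chain_order_s is not None:
                cmin_a = _cap_cos_min(inc.annulus_chain_order_s / p2_tilt)
                ann_truth["chain_order"] = 0.5 * cmin_a * (1 + cmin_a) * p2_tilt
                ann_truth["scd"] = 0.5 * ann_truth["chain_order"]
        elif not resample:
            r = np.hypot(sites0[:, 0] - center[0], sites0[:, 1] - center[1])
            keep = r >= inc.radius + 0.25
            sites0 = sites0[keep]
            if chain_off0 is not None:
                chain_off0 = chain_off0[keep]
            n_lip = len(sites0)
        protein_ref = _protein_beads(inc, center, spec.half_thickness_pp)
        n_prot = len(protein_ref)
        bead_sd = (
            0.0 if inc.static else float(np.sqrt(spec.temperature_kT / spec.restraint_k))
        )
    else:
        protein_ref = None
        n_prot = 0
        bead_sd = None

    if is_annulus is None:
        is_annulus = np.zeros(n_lip, bool)

    # --- per-lipid fixed attributes -------------------------------------
    if chain_off0 is None:
        az = rng.uniform(0.0, 2.0 * np.pi, n_lip)
        chain_off0 = spec.chain_spread * np.column_stack([np.cos(az), np.sin(az)])
    h_pp = np.full(n_lip, spec.half_thickness_pp)
    h_c2 = np.full(n_lip, spec.half_thickness_c2)
    cmin_lip = np.full(n_lip, cos_min)
    if two_domain:
        if inc.annulus_half_thickness_pp is not None:
            h_pp[is_annulus] = inc.annulus_half_thickness_pp
        if inc.annulus_half_thickness_c2 is not None:
            h_c2[is_annulus] = inc.annulus_half_thickness_c2
        if inc.annulus_chain_order_s is not None:
            cmin_lip[is_annulus] = _cap_cos_min(inc.annulus_chain_order_s / p2_tilt)

    # --- topology --------------------------------------------------------
    rows = _protein_topology_rows(n_prot)
    atoms_per_lipid = 1 + 2 * L
    rid0 = n_prot + 1
    residue_ids, leaflet_labels = [], []
    for li in range(2 * n_lip):
        rid = rid0 + li
        rows.extend(_lipid_topology_rows(rid, n_prot + li * atoms_per_lipid, L))
        residue_ids.append(rid)
        leaflet_labels.append(1 if li < n_lip else -1)
    import pandas as pd

    topo = TopologyTable(pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS))

    # --- frames ----------------------------------------------------------
    n_atoms = n_prot + 2 * n_lip * atoms_per_lipid
    coords = np.empty((spec.n_frames, n_atoms, 3))
    weights = (
        spec.annular_enhancement * np.asarray(inc.c4_asymmetry, float)
        if resample
        else None
    )
    for f in range(spec.n_frames):
        if protein_ref is not None:
            beads = protein_ref.copy()
            if bead_sd:
                beads = beads + rng.normal(0.0, bead_sd, beads.shape)
            beads[:, 2] += spec.box_z / 2.0
            coords[f, :n_prot] = beads
        at = n_prot
        for leaf in (1, -1):
            if resample:
                sites = _resample_sites(
                    rng, n_lip, box[:2], center, inc.radius,
                    inc.radius + spec.annulus_width, weights,
                )
                offs = chain_off0
            else:
                sites = sites0 + rng.normal(0.0, jitter, (n_lip, 2)) if jitter else sites0.copy()
                offs = chain_off0
            # per-lipid cap bounds (two-domain may differ inside annulus)
            c = rng.uniform(cmin_lip, 1.0)
            s = np.sqrt(1.0 - c * c)
            phi = rng.uniform(0.0, 2.0 * np.pi, n_lip)
            d1 = np.column_stack([s * np.cos(phi), s * np.sin(phi), c])
            c2_ = rng.uniform(cmin_lip, 1.0)
            s2_ = np.sqrt(1.0 - c2_ * c2_)
            phi2 = rng.uniform(0.0, 2.0 * np.pi, n_lip)
            d2 = np.column_stack([s2_ * np.cos(phi2), s2_ * np.sin(phi2), c2_])
            if tilt != 0.0:
                d1 = _apply_tilt(rng, d1, tilt)
                d2 = _apply_tilt(rng, d2, tilt)
            leafv = np.full(n_lip, float(leaf))
            lip = _build_lipid_coords(sites, leafv, d1, d2, offs, h_pp, h_c2, L)
            if spec.positional_noise_sigma:
                lip += rng.normal(0.0, spec.positional_noise_sigma, (n_lip, 1, 3))
            lip[:, :, 2] += spec.box_z / 2.0
            # wrap laterally into the primary box
            lip[:, :, 0] %= box[0]
            lip[:, :, 1] %= box[1]
            coords[f, at : at + n_lip * atoms_per_lipid] = lip.reshape(-1, 3)
            at += n_lip * atoms_per_lipid

    traj = Trajectory(coords, np.tile(box, (spec.n_frames, 1)))

    gt = GroundTruth(
        residue_ids=residue_ids,
        leaflet_labels=leaflet_labels,
        box_xy=(bx, by),
        n_lipids_per_leaflet=n_lip,
        thickness_pp=2.0 * spec.half_thickness_pp,
        thickness_hydrophobic=2.0 * spec.half_thickness_c2,
        apl=bx * by / n_lip if inc is None else spec.apl_target,
        scd=0.5 * achieved_order,
        chain_order=achieved_order,
        annulus=ann_truth,
        annular_occupancy_ratio=(
            list(np.asarray(weights)) if resample else [1.0, 1.0, 1.0, 1.0]
        ),
        annulus_radii=(
            (inc.radius, inc.radius + spec.annulus_width) if inc is not None else None
        ),
        inclusion_center=(center[0], center[1]) if inc is not None else None,
        restrained_bead_sd=bead_sd,
    )
    return traj, topo, gt


def _apply_tilt(rng: np.random.Generator, v: np.ndarray, tilt: float) -> np.ndarray:
    ct, st = np.cos(tilt), np.sin(tilt)
    v = v @ np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]]).T
    psi = rng.uniform(0.0, 2.0 * np.pi, len(v))
    cp, sp = np.cos(psi), np.sin(psi)
    return np.stack(
        [cp * v[:, 0] - sp * v[:, 1], sp * v[:, 0] + cp * v[:, 1], v[:, 2]], axis=1
    )


# ---------------------------------------------------------------------------
# persistence (GRO + XTC + topology CSV + ground-truth JSON)


def write_system(
    traj: Trajectory,
    topo: TopologyTable,
    gt: GroundTruth,
    outdir: str | Path,
    prefix: str = "system",
) -> dict[str, Path]:
    import MDAnalysis as mda
    from MDAnalysis.coordinates.XTC import XTCWriter

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = traj.n_atoms
    rids = topo.df["residue_id"].to_numpy()
    uniq, resindex = np.unique(rids, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", topo.df["atom_name"].tolist())
    u.add_TopologyAttr(
        "resnames",
        topo.df.drop_duplicates("residue_id")["residue_name"].tolist(),
    )
    u.add_TopologyAttr("resids", uniq)
    dims = np.concatenate([traj.box[0] * 10.0, [90.0, 90.0, 90.0]])
    u.dimensions = dims
    u.atoms.positions = traj.coords[0] * 10.0

    paths = {
        "gro": outdir / f"{prefix}.gro",
        "xtc": outdir / f"{prefix}.xtc",
        "topology": outdir / f"{prefix}_topology.csv",
        "ground_truth": outdir / f"{prefix}_ground_truth.json",
    }
    u.atoms.write(str(paths["gro"]))
    with XTCWriter(str(paths["xtc"]), n) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f] * 10.0
            u.dimensions = np.concatenate([traj.box[f] * 10.0, [90.0, 90.0, 90.0]])
            w.write(u.atoms)
    topo.to_csv(paths["topology"])
    gt.to_json(paths["ground_truth"])
    return paths
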