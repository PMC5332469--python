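"""Per-atom/per-residue RMSF and lipid-residue nonbonded energy decomposition.

RMSF removes rigid-body motion by least-squares superposition of every frame
onto a reference (the trajectory mean after one fit-to-frame-0 pass, by
default) before measuring fluctuations about the mean position.

The energy decomposition is a rerun-style truncated-Coulomb plus
Lennard-Jones pair sum between two atom groups, intended for ranking
residue-lipid contacts — it deliberately omits mesh electrostatics and
switching functions, which belong to the simulation Hamiltonian, not to a
contact-ranking analysis.  Lorentz-Berthelot combination rules are used:
sigma arithmetic-mean, epsilon geometric-mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core_io import TopologyTable, Trajectory, check_consistency

__all__ = [
    "F_ELEC",
    "RmsfResult",
    "EnergyDecomposition",
    "rmsf",
    "write_bfactor_structure",
    "nonbonded_decomposition",
]

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
F_ELEC = 138.935458


class SuperpositionError(ValueError):
    """Degenerate (collinear) fit selection."""


@dataclass
class RmsfResult:
    atom_indices: np.ndarray
    atom_rmsf: np.ndarray  # nm, per atom of measure selection
    residue_ids: np.ndarray
    residue_rmsf: np.ndarray  # nm, mean over each residue's measured atoms
    fitted: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue_id": self.residue_ids, "rmsf_nm": self.residue_rmsf}
        )


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Optimal rotation + translation of ``mobile`` onto ``ref`` (Kabsch)."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    spread = np.linalg.svd(mobile - mc, compute_uv=False)
    if spread[1] < 1e-12:
        raise SuperpositionError("fit selection is collinear or degenerate")
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot, mc, rc


def _resolve_mask(topo: TopologyTable, selection) -> np.ndarray:
    if selection is None:
        return np.ones(len(topo), bool)
    if isinstance(selection, (str, list)):
        return topo.mask(selection)
    return np.asarray(selection, bool)


def rmsf(
    traj: Trajectory,
    topo: TopologyTable,
    fit_selection=None,
    measure_selection="protein",
    fit: bool = True,
) -> RmsfResult:
    """Root-mean-square fluctuation per atom and per residue.

    rmsf_i = sqrt(< |r_i - <r_i>|^2 >) over frames, after superposing each
    frame onto the reference via ``fit_selection`` (defaults to the measure
    selection).  ``fit=False`` skips superposition (e.g. for externally
    restrained systems analysed in the lab frame).
    """
    check_consistency(traj, topo)
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames for fluctuations")
    measure = _resolve_mask(topo, measure_selection)
    if measure.sum() == 0:
        raise ValueError("empty measure selection")
    coords = traj.coords.copy()
    if fit:
        fmask = _resolve_mask(topo, fit_selection if fit_selection is not None else measure_selection)
        if fmask.sum() < 3:
            raise SuperpositionError("fit selection needs >= 3 atoms")
        # pass 1: fit all frames to frame 0, build the mean structure
        for f in range(traj.n_frames):
            rot, mc, rc = _superpose(coords[f, fmask], coords[0, fmask])
            coords[f] = rot.apply(coords[f] - mc) + rc
        mean1 = coords.mean(axis=0)
        # pass 2: fit to the mean
        for f in range(traj.n_frames):
            rot, mc, rc = _superpose(coords[f, fmask], mean1[fmask])
            coords[f] = rot.apply(coords[f] - mc) + rc
    mean = coords[:, measure].mean(axis=0)
    dev2 = ((coords[:, measure] - mean) ** 2).sum(axis=2)
    atom_rmsf = np.sqrt(dev2.mean(axis=0))
    idx = np.flatnonzero(measure)
    rids = topo.df.loc[idx, "residue_id"].to_numpy()
    uniq = np.unique(rids)
    res_rmsf = np.array([atom_rmsf[rids == r].mean() for r in uniq])
    return RmsfResult(idx, atom_rmsf, uniq, res_rmsf, fitted=fit)


def write_bfactor_structure(
    result: RmsfResult,
    coords: np.ndarray,
    topo: TopologyTable,
    path,
) -> None:
    """Write a PDB whose B-factor column carries the per-residue RMSF in
    Angstrom (a display convention for surface coloring, not a crystallographic
    B).  Values are clamped to the PDB field limit 999.99 with a warning.
    """
    import warnings

    import MDAnalysis as mda

    if coords.shape[0] != len(topo):
        raise ValueError("coordinate/topology atom-count mismatch")
    rmsf_by_res = dict(zip(result.residue_ids, result.residue_rmsf))
    rids = topo.df["residue_id"].to_numpy()
    b = np.array([10.0 * rmsf_by_res.get(r, 0.0) for r in rids])  # nm -> A
    if np.any(b > 999.99):
        warnings.warn("RMSF B-factor values clamped to 999.99")
        b = np.minimum(b, 999.99)
    uniq, resindex = np.unique(rids, return_inverse=True)
    u = mda.Universe.empty(
        len(topo), n_residues=len(uniq), atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", topo.df["atom_name"].tolist())
    u.add_TopologyAttr(
        "resnames", topo.df.drop_duplicates("residue_id")["residue_name"].tolist()
    )
    u.add_TopologyAttr("resids", uniq)
    u.add_TopologyAttr("elements", topo.df["element"].tolist())
    u.add_TopologyAttr("tempfactors", b)
    u.atoms.positions = np.asarray(coords) * 10.0
    u.atoms.write(str(path))


@dataclass
class EnergyDecomposition:
    """Time-averaged pairwise interaction energies between two groups,
    resolved per residue of group A."""

    per_residue: pd.DataFrame  # columns: residue_id, vdw, electrostatic, total
    vdw_total: float
    electrostatic_total: float
    cutoff: float

    @property
    def total(self) -> float:
        return self.vdw_total + self.electrostatic_total


def _group_rows(topo: TopologyTable, group) -> np.ndarray:
    """Roles (str or list of str) select by role; otherwise atom row indices."""
    if isinstance(group, str) or (
        isinstance(group, list) and group and isinstance(group[0], str)
    ):
        return np.flatnonzero(topo.mask(group))
    return np.asarray(group, int)


def nonbonded_decomposition(
    traj: Trajectory,
    topo: TopologyTable,
    group_a,
    group_b,
    cutoff: float = 1.0,
) -> EnergyDecomposition:
    """Truncated Coulomb + LJ interaction energy between groups A and B.

    For every frame and every pair (a in A, b in B) with minimum-image
    distance r <= cutoff:

        elec += F_ELEC q_a q_b / r
        vdw  += 4 eps_ab [ (sig_ab/r)^12 - (sig_ab/r)^6 ]

    with Lorentz-Berthelot combination, time-averaged over frames, and
    accumulated per residue of group A.
    """
    check_consistency(traj, topo)
    rows_a = _group_rows(topo, group_a)
    rows_b = _group_rows(topo, group_b)
    if len(rows_a) == 0 or len(rows_b) == 0:
        raise ValueError("empty interaction group")
    df = topo.df
    for rows, name in ((rows_a, "A"), (rows_b, "B")):
        sub = df.loc[rows, ["charge", "lj_sigma", "lj_epsilon"]]
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        if bad:
            raise ValueError(f"missing nonbonded parameters in group {name}: atoms {bad}")
    qa = df.loc[rows_a, "charge"].to_numpy(float)
    qb = df.loc[rows_b, "charge"].to_numpy(float)
    sa = df.loc[rows_a, "lj_sigma"].to_numpy(float)
    sb = df.loc[rows_b, "lj_sigma"].to_numpy(float)
    ea = df.loc[rows_a, "lj_epsilon"].to_numpy(float)
    eb = df.loc[rows_b, "lj_epsilon"].to_numpy(float)
    rid_a = df.loc[rows_a, "residue_id"].to_numpy()
    uniq_a = np.unique(rid_a)
    amap = np.searchsorted(uniq_a, rid_a)

    sig = 0.5 * (sa[:, None] + sb[None, :])
    eps = np.sqrt(ea[:, None] * eb[None, :])
    qq = qa[:, None] * qb[None, :]

    vdw_res = np.zeros(len(uniq_a))
    elec_res = np.zeros(len(uniq_a))
    for f in range(traj.n_frames):
        box = traj.box[f]
        d = traj.coords[f, rows_a][:, None, :] - traj.coords[f, rows_b][None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(axis=2))
        within = (r <= cutoff) & (r > 0.0)
        sr6 = (sig / np.where(within, r, 1.0)) ** 6
        vdw = np.where(within, 4.0 * eps * (sr6 * sr6 - sr6), 0.0)
        elec = np.where(within, F_ELEC * qq / np.where(within, r, 1.0), 0.0)
        np.add.at(vdw_res, amap, vdw.sum(axis=1))
        np.add.at(elec_res, amap, elec.sum(axis=1))
    vdw_res /= traj.n_frames
    elec_res /= traj.n_frames
    per_res = pd.DataFrame(
        {
            "residue_id": uniq_a,
            "vdw": vdw_res,
            "electrostatic": elec_res,
            "total": vdw_res + elec_res,
        }
    )
    return EnergyDecomposition(
        per_res,
        vdw_total=float(np.sum(vdw_res)),
        electrostatic_total=float(np.sum(elec_res)),
        cutoff=cutoff,
    )
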