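"""Orchestrate the full analysis from a single config.

Stages: simulate (synthetic system generation) -> density (3D map, C4
averaging, sigma normalization, annular contrast) -> thickness / apl / scd /
hexatic 2D maps -> rmsf -> energy.  Every run writes the resolved config and
a manifest of completed stages next to the outputs; identical config + seed
gives bit-identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core_io, density, dynamics, grids, synthetic

__all__ = ["AnalysisConfig", "run_pipeline"]

log = logging.getLogger("lipidshell")

ALL_STAGES = ("simulate", "density", "thickness", "apl", "scd", "hexatic", "rmsf", "energy")


@dataclass
class AnalysisConfig:
    """Single-file configuration for the end-to-end pipeline."""

    outdir: str = "lipidshell_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # inputs: either files, or a synthetic system spec
    coord_file: str | None = None
    traj_file: str | None = None
    topology_csv: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticBilayerSpec fields
    inclusion: dict | None = None  # InclusionSpec fields; None = plain bilayer
    # analysis parameters
    density_spacing: float = 0.1  # nm
    density_selection: str = "phosphate"
    symmetry_fold: int = 4
    normalize: bool = True
    annulus_margin: float = 0.15  # nm, shrink of the measured annular shell
    grid_nx: int = 100
    grid_ny: int = 100
    radial_cutoff: float | None = 6.5  # nm
    scd_carbon: int = 7
    scd_chain: str = "both"
    hexatic_cutoff: float = 0.8
    energy_cutoff: float = 1.0
    # lipid roles for the energy stage; headgroup contacts by default (the
    # synthetic generator does not enforce chain excluded-volume, so chain
    # overlaps would dominate the LJ term unphysically)
    energy_group_b: str = "phosphate"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the requested stages in dependency order; returns the summary.

    Writes into ``config.outdir``: resolved_config.yaml, manifest.json,
    summary.json, plus per-stage volumes/matrices/CSVs.  On stage failure the
    manifest of completed stages is retained and the error re-raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "pipeline.log")
    log.addHandler(fh)
    config.to_yaml(outdir / "resolved_config.yaml")

    summary: dict = {"seed": config.seed}
    manifest: list[str] = []
    stages = [s for s in ALL_STAGES if s in config.stages]

    traj = topo = gt = leaflets = None
    center = None
    try:
        if config.coord_file is not None:
            traj = core_io.read_trajectory(config.coord_file, config.traj_file)
            topo = core_io.TopologyTable.from_csv(config.topology_csv)
        for stage in stages:
            t0 = time.time()
            log.info("stage %s ...", stage)
            if stage == "simulate":
                spec_kw = dict(config.synthetic)
                spec_kw.setdefault("seed", config.seed)
                inc = (
                    synthetic.InclusionSpec(**config.inclusion)
                    if config.inclusion is not None
                    else None
                )
                spec = synthetic.SyntheticBilayerSpec(**spec_kw, inclusion=inc)
                if inc is not None:
                    traj, topo, gt = synthetic.generate_inclusion_system(spec)
                else:
                    traj, topo, gt = synthetic.generate_bilayer(spec)
                synthetic.write_system(traj, topo, gt, outdir, prefix="synthetic")
                summary["n_frames"] = traj.n_frames
                summary["n_atoms"] = traj.n_atoms
            else:
                if traj is None or topo is None:
                    raise StageError(stage, "no input system (run simulate or give files)")
            if stage != "simulate":
                if leaflets is None:
                    leaflets = core_io.assign_leaflets(traj, topo, frame=0)
                if center is None:
                    if topo.protein_mask.any():
                        com = traj.coords[:, topo.protein_mask, :2].mean(axis=(0, 1))
                        center = (float(com[0]), float(com[1]))
                    else:
                        b = traj.box.mean(axis=0)
                        center = (float(b[0]) / 2, float(b[1]) / 2)

            if stage == "density":
                gspec = density.GridSpec.covering_box(
                    traj.box.mean(axis=0), config.density_spacing
                )
                grid = density.accumulate_density(
                    traj, topo, config.density_selection, gspec
                )
                grid = density.symmetrize(
                    grid, density.SymmetryOp(center, config.symmetry_fold)
                )
                if gt is not None and gt.annulus_radii is not None:
                    m = config.annulus_margin
                    r_in, r_out = gt.annulus_radii
                    zmid = float(traj.box.mean(axis=0)[2]) / 2
                    h = gt.thickness_pp / 2
                    occ = density.accumulate_density(
                        traj, topo, "phosphate", gspec,
                        scattering=density.occupancy_kernel(),
                    )
                    occ = density.symmetrize(
                        occ, density.SymmetryOp(center, config.symmetry_fold)
                    )
                    contrast = density.annular_contrast(
                        occ, center, r_in + m, r_out - m,
                        (zmid + 0.7 * h, zmid + 1.3 * h),
                        r_bulk_max=min(grid.shape[0] * grid.spacing[0],
                                       grid.shape[1] * grid.spacing[1]) / 2 - 0.2,
                    )
                    summary["annular_contrast"] = contrast
                core_io.write_volume(grid, outdir / "density_raw.mrc")
                if config.normalize:
                    norm = density.normalize_sigma(grid)
                    core_io.write_volume(norm, outdir / "density_sigma.mrc")
                summary["density_voxel_sum"] = float(grid.values.sum())
            elif stage == "thickness":
                for kind in ("pp", "hydrophobic"):
                    g = grids.thickness_map(
                        traj, topo, leaflets, kind,
                        config.grid_nx, config.grid_ny,
                        config.radial_cutoff, center,
                    )
                    g.save(outdir / f"thickness_{kind}.dat")
                    summary[f"mean_thickness_{kind}"] = float(
                        np.nanmean(g.values)
                    )
            elif stage == "apl":
                g = grids.apl_map(
                    traj, topo, leaflets, "both",
                    config.grid_nx, config.grid_ny, config.radial_cutoff, center,
                )
                g.save(outdir / "apl.dat")
                summary["mean_apl"] = float(np.nanmean(g.values))
            elif stage == "scd":
                for leaf in ("upper", "lower"):
                    g = grids.scd_map(
                        traj, topo, leaflets,
                        grids.ScdSpec(config.scd_carbon, config.scd_chain, leaf),
                        config.grid_nx, config.grid_ny, config.radial_cutoff, center,
                    )
                    g.save(outdir / f"scd_C{config.scd_carbon}_{leaf}.dat")
                    summary[f"mean_abs_scd_{leaf}"] = float(np.nanmean(g.values))
            elif stage == "hexatic":
                _, mean6 = grids.hexatic_order(
                    traj, topo, leaflets, "upper",
                    carbon_index=2,
                    neighbor_cutoff=config.hexatic_cutoff,
                )
                summary["mean_psi6"] = mean6
            elif stage == "rmsf":
                if topo.protein_mask.any():
                    res = dynamics.rmsf(traj, topo, measure_selection="protein")
                    res.as_frame().to_csv(outdir / "rmsf.csv", index=False)
                    summary["mean_rmsf"] = float(res.atom_rmsf.mean())
                    summary["max_rmsf"] = float(res.atom_rmsf.max())
                else:
                    log.info("no protein atoms; rmsf skipped")
            elif stage == "energy":
                if topo.protein_mask.any():
                    dec = dynamics.nonbonded_decomposition(
                        traj, topo, "protein",
                        config.energy_group_b.split(","),
                        cutoff=config.energy_cutoff,
                    )
                    dec.per_residue.to_csv(outdir / "energy_per_residue.csv", index=False)
                    summary["energy_vdw"] = dec.vdw_total
                    summary["energy_electrostatic"] = dec.electrostatic_total
                else:
                    log.info("no protein atoms; energy skipped")
            manifest.append(stage)
            log.info("stage %s done in %.1f s", stage, time.time() - t0)
    finally:
        with open(outdir / "manifest.json", "w") as fhm:
            json.dump({"completed_stages": manifest}, fhm, indent=1)
        log.removeHandler(fh)
        fh.close()

    summary = _round_floats(summary)
    with open(outdir / "summary.json", "w") as fhs:
        json.dump(summary, fhs, indent=1, sort_keys=True)
    return summary
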