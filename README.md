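# lipidshell

Analysis of the lipid shell around membrane proteins in molecular-dynamics
trajectories: where annular lipids localize, and how ordered they are.

Membrane proteins reshape the lipids in direct contact with them (the
*annular* shell): they can recruit density, stretch or compress the bilayer
to resolve hydrophobic mismatch, and nucleate gel-like (L<sub>β</sub>) patches in an
otherwise fluid (L<sub>α</sub>) membrane. `lipidshell` quantifies these effects from
coordinate trajectories of a bilayer with an embedded (pseudo-)symmetric
protein, the setting typified by an aquaporin tetramer in a DMPC bilayer:

* **3D lipid density maps** ρ(x) — time-averaged sums of per-atom Gaussians
  weighted by scattering amplitudes, optionally averaged over the protein's
  C4 rotational symmetry, masked (protein exclusion or radial cutoff), and
  reported in σ units (zero mean, unit SD over the normalization region) for
  comparison with electron-crystallography lipid densities.
* **Leaflet-resolved 2D property maps** on an n×n lateral grid (100×100 by
  default): inter-phosphate thickness, hydrophobic thickness (carbon-2
  surfaces), local area-per-lipid from a periodic Voronoi tessellation, and
  carbon–deuterium order parameters
  S<sub>CD</sub> = ⟨(3 cos²θ − 1)/2⟩ with C–H directions reconstructed
  from the C(k−1)→C(k+1) chain axis.
* **Hexatic order** ψ₆ of the lateral chain packing, separating gel
  (hexagonal, |ψ₆| → 1) from fluid (|ψ₆| ≲ 0.4) regions.
* **Protein dynamics**: per-atom/per-residue RMSF after least-squares
  superposition, and a truncated Coulomb + Lennard-Jones decomposition of
  lipid–residue interaction energies into electrostatic and van der Waals
  parts.

Because public bilayer/protein trajectories at the required scale are rarely
deposited, the package ships a **synthetic bilayer generator**
(`lipidshell.synthetic`) that produces GRO/XTC trajectories with fully known
ground truth — phase (fluid/gel lattices), thicknesses, area-per-lipid,
imposed chain order, a rigid C4 inclusion with configurable annular
occupancy enhancement, and harmonically restrained beads — so every analysis
stage is validated end-to-end by parameter recovery.

## Worked example

Generate a fluid bilayer containing a C4-symmetric inclusion whose annular
shell is enhanced 2×, then measure the enhancement back from the density map
and map the membrane properties:

```python
import lipidshell as ls
from lipidshell import density as D

spec = ls.SyntheticBilayerSpec(
    n_lipids_per_leaflet=100, n_frames=1000, seed=5,
    inclusion=ls.InclusionSpec(radius=1.2, static=True),
    annular_enhancement=2.0, annulus_width=0.5,
)
traj, topo, truth = ls.generate_inclusion_system(spec)

grid = D.accumulate_density(
    traj, topo, "phosphate",
    D.GridSpec.covering_box(traj.box[0], 0.1),
    scattering=D.occupancy_kernel(),
)
zmid = traj.box[0][2] / 2
contrast = D.annular_contrast(
    grid, truth.inclusion_center, 1.35, 1.55,
    (zmid + 1.2, zmid + 2.3), r_bulk_max=3.6,
)
print(f"annular/bulk occupancy contrast: {contrast:.3f}")

leaflets = ls.assign_leaflets(traj, topo)
thk = ls.thickness_map(traj, topo, leaflets, "pp", 60, 60, radial_cutoff=3.6)
import numpy as np
print(f"mean P-P thickness: {np.nanmean(thk.values):.3f} nm")
```

Output:

```
annular/bulk occupancy contrast: 2.012
mean P-P thickness: 3.500 nm
```

The contrast recovers the generator's 2× enhancement (the measured shell is
shrunk 0.15 nm on each side to stay clear of kernel blur at the region
edges), and the thickness map recovers the generated 3.5 nm phosphate
separation.

The same analyses are available from the shell:

```bash
lipidshell simulate --seed 5 --n-lipids 100 --n-frames 200 \
    --inclusion-radius 1.2 --enhancement 2.0 --out system/
lipidshell thickness --coord system/system.gro --traj system/system.xtc \
    --topology system/system_topology.csv --out thickness_pp.dat
lipidshell run --config examples/demo_config.yaml   # full pipeline
```

`lipidshell run` executes generate → density (C4-averaged, σ-normalized) →
thickness/APL/S<sub>CD</sub> maps → hexatic → RMSF → energies from one YAML config,
writes every map (MRC volumes, text matrices with JSON sidecars, CSV
tables), the resolved config, a manifest, and a summary JSON that is
bit-identical across runs with the same seed.

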