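# Methods

This note documents the models and conventions implemented in `lipidshell`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices a user may want to change.

## Units and conventions

All lengths are nm, areas nm², energies kJ/mol, times ps. Boxes are
orthorhombic; triclinic inputs are rejected rather than silently mishandled.
The bilayer normal is z. Leaflets are labeled +1 (upper/extracellular) and
−1 (lower/intracellular) by the sign of each lipid's phosphate z against the
midplane (the mean phosphate z of a reference frame; assignment is cached
from frame 0 by default since lipid flip-flop is negligible on the hundreds
of-ns timescales these analyses average over).

Topology annotations come from a tabular CSV sidecar (atom name, residue,
element, role, chain/carbon index, charge, LJ σ/ε) rather than a force-field
topology — the package stays force-field-agnostic and the analysis needs
only roles and nonbonded parameters.

## 3D density maps

The density of a selection is accumulated on a regular grid as

ρ(x) = (1/F) Σ_frames Σ_atoms Σ_i A_i (π B_i)^(−3/2) exp(−|x − r_a|²/B_i),

evaluated at voxel centers (the voxel value is the field at the center; the
map origin is the center of voxel (0,0,0) and is stored in the MRC header).
Each Gaussian integrates to A_i, so voxel-sum × voxel-volume of an
unnormalized, unmasked map equals the per-frame total amplitude; this mass
conservation holds to <0.5% for spacing ≤ √B_min/3 and truncation radius
≥ 4√B_max (the defaults: spacing 0.05 nm, r_cut = 4√B_max).

Two kernels are provided:

* the **scattering table** (default): per-element amplitude equal to the
  electron count, split 60/40 over a sharp (B = 0.03 nm²) and diffuse
  (B = 0.08 nm²) Gaussian. This is a documented stand-in profile with an
  overall ~2 Å spread matching the sub-2 Å resolution context the maps are
  visually compared against; no atomic displacement factor is folded in.
  Users doing quantitative scattering work should supply their own table.
* the **occupancy kernel** (`occupancy_kernel()`): one narrow unit-amplitude
  Gaussian per element (B = 0.01 nm², spatial SD ≈ 0.07 nm). Used for
  quantifying occupancy ratios such as the annular contrast, where the broad
  kernel would blur the empty protein core into a ~0.5 nm annular shell and
  bias shell means by several percent.

Atoms are wrapped into the primary box and contribute to edge voxels through
the minimum image when the grid tiles the box.

**C4 symmetry averaging** is done in map space: the accumulated map is
resampled under the rotation group about a z-parallel axis (trilinear
interpolation) and averaged. For a fold dividing 4, equal in-plane spacings,
and the axis on a voxel center the rotation maps voxel centers onto voxel
centers and the operation is exact; otherwise interpolation error is bounded
by the grid spacing. The axis defaults to the time-averaged in-plane center
of mass of the protein atoms. Averaging in map space is equivalent to
rotating coordinates per frame for a rotation-commuting kernel (isotropic
Gaussians), and far cheaper.

**σ normalization** maps values to (ρ − mean)/SD over a normalization
region; the default region is all unmasked voxels, since it is not obvious
that masked protein voxels should enter the statistics. Masked voxels carry
NaN and are excluded from all later statistics; masked maps cannot be
written as MRC volumes without first replacing the sentinel.

**Annular contrast** is the mean voxel value in an annular shell around the
inclusion divided by the bulk mean (r beyond the shell plus a margin, capped
to stay inside the primary box), within one leaflet's z-slab. Callers should
shrink the measured shell by ~2 kernel SDs on each side; the demo and
acceptance analyses use 0.15 nm with the occupancy kernel.

## 2D membrane property maps

Grid cells are half-open intervals over the time-averaged box; samples are
wrapped into the primary box before binning. A lipid is binned by the
reference atom of the property being mapped (phosphate for thickness/APL,
carbon-k for S_CD) — per-property, not by a single lipid center.

* **Thickness**: per-frame, per-leaflet reference atoms (phosphates, or the
  minimum-image mean of the two carbon-2 atoms for the hydrophobic surface)
  are binned; per-cell z is time-averaged; empty cells are filled from the
  nearest valid cell (needed so the upper−lower subtraction is defined
  everywhere); thickness = upper − lower.
* **Area per lipid**: per frame and leaflet, a Voronoi tessellation of the
  phosphate x,y positions surrounded by their 8 periodic images exactly
  tiles the box, giving per-lipid areas whose sum equals the box area to
  1e-9 relative — the invariant that motivated choosing Voronoi over
  occupancy counting. Protein atoms' lateral positions (deduplicated) are
  included as extra seeds so lipid cells do not extend into the protein
  footprint; protein-owned grid cells are masked. Each grid cell records the
  area of the lipid owning its center, time-averaged.
* **S_CD**: at carbon k the two C–H directions are reconstructed as an
  orthonormal pair perpendicular to the minimum-image C(k−1)→C(k+1) axis.
  For any such pair, the mean of (3cos²θ−1)/2 over the two H's equals
  −½ P2(cos θ_axis) *identically* (for any orthonormal pair {e1,e2}
  perpendicular to axis a, cos²(z·e1) + cos²(z·e2) = 1 − (z·a)²), so the
  estimator realizes the classic −½ axis-to-CH relation per sample; the
  equality is additionally validated numerically against explicit
  tetrahedral-geometry sampling in the test suite. Values are stored
  signed; reporting uses |S_CD| to match the conventional positive scale.
  Cells with no samples are masked (no filling) — omission, not
  interpolation, is the display convention for sparse order-parameter maps.
* **Radial profiles** reduce any 2D map to count-weighted annular means.
* **Hexatic order**: ψ6(j) = |(1/n_j) Σ_k exp(6iθ_jk)| over neighbors within
  a cutoff under the periodic minimum image. The default cutoff of 0.8 nm is
  ~1.5× the gel chain spacing (√(2·0.24/√3) ≈ 0.53 nm at 0.24 nm²/chain),
  capturing the first neighbor shell only; at that cutoff the hexagonal
  lattice gives ψ6 = 1, and fluid/random patterns give ≲ 0.35. ψ6 is
  evaluated on the carbon-2 bead pattern by default — the chain anchor
  plane, where packing order is defined — since deeper carbons carry
  orientational disorder in both real chains and the generator.

Radial masking (default 6.5 nm around the protein center, on a 100×100
grid) matches the common practice of showing only the membrane patch around
the protein.

## Protein dynamics

**RMSF**: each frame is least-squares superposed (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) onto a reference built by
one fit-to-frame-0 pass followed by a fit-to-the-mean pass; then
rmsf_i = √⟨|r_i − ⟨r_i⟩|²⟩. Fitting can be disabled for externally
restrained systems analysed in the lab frame. Per-residue values are means
over each residue's measured atoms, and can be written into the PDB B-factor
column (in Å, a display convention for surface coloring, not a
crystallographic B).

**Energy decomposition**: plain truncated Coulomb
(f q_a q_b / r, f = 138.935458 kJ mol⁻¹ nm e⁻²) plus Lennard-Jones
4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combination, summed over
minimum-image pairs within a cutoff (default 1.0 nm, the upper end of the
usual 0.8–1.0 nm short-range window) and time-averaged, resolved per residue
of group A. This is a rerun-style contact-ranking decomposition, not a
reconstruction of the simulation Hamiltonian: no mesh electrostatics, no
switching function (an optional potential shift is deliberately omitted
until someone needs GROMACS-convention matching).

## The synthetic bilayer generator

Frames are **independent redraws** of configurational noise about fixed
lattice sites, not integrated dynamics. Every analysis above is a time
average of configurational quantities, so i.i.d. sampling yields the same
estimators with exactly known statistics — which is what makes honest
parameter-recovery tests possible. The cost is that the generator says
nothing about kinetics, correlations, or excluded volume (see limitations).

Geometry per lipid: one phosphate bead at ±h_pp (default 1.75 nm, giving the
3.5 nm P–P thickness of a fluid DMPC-like bilayer), two straight acyl chains
of 14 indexed carbon beads anchored with carbon-2 exactly at ±h_c2 (default
1.45 nm → 2.9 nm hydrophobic thickness) and descending toward the midplane
along a per-chain director. Defaults: area-per-lipid 0.60 nm² (fluid) /
0.48 nm² (gel preset), 196 lipids per leaflet (a tetramer-scale patch),
kT = 2.577 kJ/mol (310 K).

**Chain order** is imposed by sampling each director uniformly from a
spherical cap whose lower cosine bound c₀ solves c₀(1+c₀)/2 = S (the mean P2
of a uniform cap), with an optional fixed collective tilt entering
multiplicatively as P2(cos tilt) (exact for uniform tilt azimuth, by the
addition theorem). The fluid default S = 0.40 yields |S_CD| = 0.20,
mid-range for a fluid phosphatidylcholine chain; the gel preset uses
S = 0.90.

**Noise** enters as (a) lateral jitter of the lattice sites (default 0.4 nm
for the fluid square lattice — roughly half the lattice constant, enough to
destroy bond-orientational order as in a liquid — and 0.02 nm for gel) and
(b) an isotropic rigid-body displacement of each whole lipid (default
0.05 nm fluid / 0.02 nm gel; gel lipids are lattice-locked). Rigid-body
noise leaves internal chain geometry untouched, so imposed order parameters
survive exactly.

**Inclusion systems** place an exactly C4-symmetric cylinder of beads
(pattern built in one quadrant, replicated by 90° rotations) at the box
center; lipids are excluded from the cylinder radius. Protein beads are
static (restrained limit) or redrawn per frame from the harmonic-restraint
equilibrium N(0, kT/k) per coordinate — at the default
k = 1000 kJ nm⁻² mol⁻¹ and kT = 2.577 kJ/mol the per-atom RMSF is
√(3kT/k) = 0.0879 nm.

Two inclusion modes exist:

* **occupancy resampling** (annular_enhancement ≠ 1 or per-quadrant
  asymmetry): lipid lateral positions are redrawn i.i.d. each frame by
  rejection sampling from a piecewise-constant density — 0 in the core,
  enhancement × quadrant-weight in the annulus (width 0.5 nm by default),
  1 outside — so the true annular/bulk occupancy ratio is exactly the
  enhancement factor;
* **two-domain lattice** (annulus_apl set): a hexagonal patch at the annulus
  area-per-lipid (and optionally its own thicknesses/order) fills an annular
  domain, with the bulk lattice outside — a gel-like annulus in a fluid
  bulk. Lattice-boundary cells are geometrically distorted, so recovery
  tests measure in bands at least one lattice spacing clear of the seams.

### What the generator does not emulate

No excluded volume (lipids can overlap each other and, with large chain
excursions, the inclusion — which is why the demo energy stage ranks
protein–headgroup contacts rather than chain contacts), no dihedral chain
structure, no headgroup atoms beyond the phosphate bead, no water/ions, no
undulations or curvature, no temporal correlations, and no quantitative
DMPC phase thermodynamics. Passing recovery tests therefore demonstrates
that the *analysis machinery* is correct and unbiased at known ground truth;
it does not validate force fields or sampling of real trajectories.

## Numerical choices and degenerate inputs

* Kernel truncation: spherical, at 4√B_max; truncated mass < 1e-6 of total.
* Voronoi degeneracies (collinear sites, unbounded cells) raise errors
  naming the frame; coincident protein seeds are deduplicated.
* Zero-length chain axes (possible only with degenerate input coordinates)
  are skipped with a warning, not propagated as NaN.
* σ normalization refuses zero-variance regions; symmetrize requires equal
  in-plane spacings.
* All randomness flows from a single integer seed per generated system;
  identical config + seed reproduces byte-identical pipeline summaries.

## Problem sizes used in tests and acceptance

Recovery runs use 64–256 lipids per leaflet and 200–2000 frames — patches at
the scale of one inclusion plus several lipid shells, chosen so each
statistical tolerance (3·SE bounds, 5–10% recovery bands) is met with
comfortable margin by the estimators' own convergence rates. Oracle
equivalence checks run on deliberately tiny systems (≤ 20 lipids, 4×4 grids,
≤ 50 atoms) where brute-force reference implementations are feasible and
comparisons are bit-for-bit.
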