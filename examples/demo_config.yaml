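# Demo: C4 inclusion in a fluid bilayer with 2x annular occupancy enhancement
outdir: demo_out
seed: 7
synthetic:
  n_lipids_per_leaflet: 100
  apl_target: 0.60
  n_frames: 150
  annular_enhancement: 2.0
  annulus_width: 0.5
inclusion:
  radius: 1.2
density_spacing: 0.1
symmetry_fold: 4
grid_nx: 60
grid_ny: 60
radial_cutoff: 3.6
scd_carbon: 7
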