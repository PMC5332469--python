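{
 "annular_contrast": 1.9558889354,
 "density_voxel_sum": 2964499.296878641,
 "energy_electrostatic": 7.94895981,
 "energy_vdw": 2042.0198912233,
 "max_rmsf": 0.0918236637,
 "mean_abs_scd_lower": 0.1959625511,
 "mean_abs_scd_upper": 0.1978456774,
 "mean_apl": 0.660465645,
 "mean_psi6": 0.3325654637,
 "mean_rmsf": 0.0860004214,
 "mean_thickness_hydrophobic": 2.9009656664,
 "mean_thickness_pp": 3.5009656664,
 "n_atoms": 5860,
 "n_frames": 150,
 "seed": 7
}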