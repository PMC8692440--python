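# Dose-mean lineal energy of 30 MeV protons in unit-density tissue-equivalent
# gas, 360 nm spheres (reflective cube of side 179 x diameter).
benchmark: lineal_energy
material: TEG
density: 1.0
energy_mev: 30.0
diameter_nm: 360.0
lattice_side: 179
max_incidence_deg: 30.0
proton_frac_cut: 0.005
electron_cutoff_ev: 1.0
y_max: 10.0
histories: 200
seed: 1
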