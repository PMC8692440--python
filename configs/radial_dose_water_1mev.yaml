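# Radial dose around a 1 MeV proton track in liquid water: 100 nm slab with
# reflective caps, projectile cut after 0.1% energy loss, electrons to 1 eV.
benchmark: radial_dose
material: water
energy_mev: 1.0
thickness_nm: 100.0
proton_frac_cut: 0.001
electron_cutoff_ev: 1.0
histories: 500
seed: 1
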