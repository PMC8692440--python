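# First-generation secondary-electron spectrum from a thin (10 nm) water foil
# at 1e24 atoms/cm^3 (3.33e23 molecules/cm^3).
benchmark: sdcs
material:
  name: water-dense
  number_density: 3.333e23
  composition: {H2O: 1.0}
energy_mev: 1.0
thickness_nm: 10.0
histories: 20000
seed: 1
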