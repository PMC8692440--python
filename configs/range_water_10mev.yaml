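# Projected range of protons in a thick liquid-water column (1 keV threshold).
benchmark: range
material: water
energy_mev: 10.0
column_cm: 500.0
threshold_ev: 1000.0
histories: 50
seed: 1
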