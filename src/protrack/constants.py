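"""Physical constants (CODATA-2018 rounded) used throughout the package.

Energies are handled in eV, lengths in cm internally (tallies convert to nm).
"""

# Rydberg energy [eV]
RYDBERG_EV = 13.605693

# Bohr radius [cm]
BOHR_RADIUS_CM = 5.29177210903e-9

# Electron / proton rest energies [eV]
ELECTRON_MASS_EV = 510998.95
PROTON_MASS_EV = 938.27208816e6

# m_e / m_p
ME_OVER_MP = ELECTRON_MASS_EV / PROTON_MASS_EV

# Avogadro constant [1/mol]
N_AVOGADRO = 6.02214076e23

# 4 pi K / (m_e c^2) prefactor of the Bethe formula: 0.307075 MeV cm^2 / mol
# (multiply by Z/A [mol/g] to get MeV cm^2/g)
K_BETHE_MEV_CM2_PER_MOL = 0.307075

CM_PER_NM = 1.0e-7
NM_PER_CM = 1.0e7
EV_PER_MEV = 1.0e6
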