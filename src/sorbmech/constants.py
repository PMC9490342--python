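"""Physical constants and reference values used by the chemical-potential
bookkeeping and the unit-conversion tables.

All SI unless noted.  Molar quantities use kJ/mol where stated.
"""

KB = 1.380649e-23           # Boltzmann constant, J/K
NA = 6.02214076e23          # Avogadro constant, 1/mol
R_GAS = KB * NA             # gas constant, J/(mol K)
R_GAS_KJ = R_GAS / 1000.0   # kJ/(mol K)
PLANCK = 6.62607015e-34     # Planck constant, J s

M_WATER = 18.015            # molar mass of water, g/mol

# Saturation vapour pressure of water at 300 K, Pa.
P_SAT_WATER_300K = 3550.0
T_REF = 300.0               # K

# Dielectric constants used in the volume-fraction mixing rule:
# dry keratin (experimental) and liquid water.
EPS_KERATIN = 4.0
EPS_WATER = 72.0
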