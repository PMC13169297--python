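"""Physical constants and unit conventions.

Energies are kcal/mol, lengths Å, angles degrees at the API surface
(radians internally where noted), temperatures K, times ps.
"""

#: Boltzmann constant in kcal/(mol K)
KB = 0.0019872041

#: Default simulation temperature (K)
DEFAULT_TEMPERATURE = 300.0

#: Puckering amplitude floor (Å) below which theta/phi are noise-dominated
AMPLITUDE_FLOOR = 0.05

#: Ideal ring bond lengths (Å) used by the geometry builder
BOND_CC = 1.52
BOND_CO = 1.43
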