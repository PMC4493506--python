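"""Physical constants and unit conventions.

Internal units follow the GROMACS convention: length nm, time ps, mass amu
(g/mol), energy kJ/mol.  With these, force is kJ/mol/nm, velocity nm/ps, and
1 kJ/mol == 1 amu nm^2/ps^2, so accelerations need no conversion factor.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.008_314_462_1

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
F_ELEC = 138.935_458

#: kJ per kcal (thermochemical calorie, exact)
KCAL = 4.184

#: pressure conversion: 1 kJ mol^-1 nm^-3 in bar
PRESSURE_BAR = 16.605_402

#: default simulation temperature, K
T_BODY = 310.0
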