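"""Physical constants and unit conversions.

Internal length unit is the angstrom; GRO files (nm) are converted at I/O.
Energies are handled in SI and converted to GPa/MPa at the reporting surface.
"""

#: Boltzmann constant, J/K.
KB_J_PER_K = 1.380649e-23

#: Cubic angstroms per cubic metre.
A3_PER_M3 = 1e30

#: Angstroms per nanometre.
A_PER_NM = 10.0

#: Pascals per gigapascal / megapascal.
PA_PER_GPA = 1e9
PA_PER_MPA = 1e6

#: Axial repeat of a pyranose ring in an ideally extended cellulose chain, in
#: angstroms.  This sets both the ideal chain length (n_rings * repeat) and
#: the ring-ring spacing that shows up as the 1.17 A^-1 feature of the
#: ring-centroid structure factor.
CELLULOSE_RING_REPEAT_A = 5.2

#: Molar masses used for composition bookkeeping, g/mol.
M_GLUCOSE_RESIDUE = 162.14  # anhydroglucose unit
M_WATER = 18.015
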