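"""Physical constants and unit conventions.

Internal units: length in Angstrom, energy in kcal/mol, charge in elementary
charges, mass in amu, time in fs.  Velocities are therefore A/fs and angular
velocities rad/fs; kinetic energies computed from them are converted back to
kcal/mol with :data:`KCAL_MOL_FS2`.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
K_BOLTZMANN = 0.0019872041

#: Coulomb prefactor k_c such that E = k_c q_i q_j / (eps r) is in kcal/mol
#: for charges in e and r in Angstrom.
COULOMB_CONSTANT = 332.0637

#: Conversion: 1 kcal/mol expressed in amu A^2 fs^-2.
#: (4184 J/mol / N_A) / (1 amu * 1 A^2 / 1 fs^2)
KCAL_MOL_FS2 = 4.184e-4

#: Default cap applied to clashing intermolecular energies, kcal/mol.
E_CAP = 100.0

#: Default H-bond geometric gate: H...acceptor distance (A) and
#: donor-H...acceptor angle (degrees).
HBOND_RMAX = 2.5
HBOND_ANGLE_MIN = 135.0

#: Atomic masses (amu) for elements the package commonly encounters.
ELEMENT_MASSES = {
    "H": 1.008, "He": 4.0026, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Ar": 39.948, "X": 10.0,
}
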