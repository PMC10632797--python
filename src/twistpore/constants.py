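"""Physical constants in the unit system used throughout the package.

Energies are kcal/mol, lengths Å, times ps, concentrations mol/L,
temperatures K.  All conversions between these and SI happen here.
"""

#: Boltzmann constant, kcal/(mol K).
KB_KCAL = 0.0019872

#: Coulomb prefactor e^2/(4 pi eps0), kcal Å / mol.
COULOMB_KCAL_A = 332.0637

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Gas constant over Faraday constant at 1 K, volts.
RT_OVER_F_PER_K = 8.617333262e-5  # k_B/e in V/K

#: kcal to kJ.
KCAL_TO_KJ = 4.184

#: mol/L -> number density in 1/Å^3.
MOLAR_TO_PER_A3 = AVOGADRO / 1.0e27

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Default relative permittivity of water near 300 K.
DEFAULT_PERMITTIVITY = 78.4


def thermal_energy(temperature: float) -> float:
    """k_B T in kcal/mol."""
    return KB_KCAL * temperature


def bjerrum_length(temperature: float, relative_permittivity: float) -> float:
    """Bjerrum length in Å: distance at which two unit charges interact at k_B T."""
    return COULOMB_KCAL_A / (relative_permittivity * thermal_energy(temperature))
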