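"""Physical constants and unit conventions.

Unit system (AKMA-like): energies in kcal/mol, lengths in Angstrom, masses in
amu (g/mol), times in ps.  In these units 1 kcal/mol = 418.4 amu A^2/ps^2, so
forces in kcal/mol/A are multiplied by ``KCAL_PER_MOL_AKMA`` before dividing by
mass to obtain accelerations in A/ps^2.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: 1 kcal/mol expressed in amu*A^2/ps^2.
KCAL_PER_MOL_AKMA = 418.4

#: Standard-state volume of an ideal gas at 298 K used by the volume
#: correction, A^3 (1 molecule at 1 atm / 298 K; deliberately not the 1 M
#: textbook value 1660.5).
V0_STANDARD = 1649.76

#: Default simulation temperature, K.
T_DEFAULT = 298.15


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at ``temperature`` (K)."""
    return KB * temperature


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
    return 1.0 / kbt(temperature)
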