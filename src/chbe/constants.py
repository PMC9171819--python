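"""Physical constants and unit conversions.

Internal energy unit is kcal/mol for pair potentials (matching the units in
which C_ij coefficients are tabulated, kcal mol^-1 A^4) and kJ/mol for
binding free energies (matching how chelator affinities are reported).
"""

#: Molar gas constant, kJ mol^-1 K^-1.
R_KJ = 8.31446e-3

#: Boltzmann constant expressed per mole, kcal mol^-1 K^-1.
KB_KCAL = 1.9872041e-3

#: kcal -> kJ.
KCAL_TO_KJ = 4.184

#: Coulomb prefactor e^2/(4 pi eps0) in kcal mol^-1 A e^-2, AMBER convention.
COULOMB_KCAL = 332.0522173

#: Reference temperature for affinity conversion, K.
T_REF = 298.0


def kcal_to_kj(x: float) -> float:
    """Convert kcal/mol to kJ/mol."""
    return x * KCAL_TO_KJ


def kj_to_kcal(x: float) -> float:
    """Convert kJ/mol to kcal/mol."""
    return x / KCAL_TO_KJ
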