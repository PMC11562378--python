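"""Physical constants and unit conventions.

Internal units throughout the package: lengths in Angstrom (Å), times in
picoseconds (ps), energies in kcal/mol, temperatures in Kelvin.
Concentrations are molar; conversions happen only at I/O edges.
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = 0.0019872041

#: Standard-state volume per molecule at 1 M, in Å^3.
V_STANDARD_A3 = 1660.0

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: Å^3 expressed in liters.
A3_TO_LITER = 1e-27

#: ps expressed in seconds.
PS_TO_S = 1e-12

#: kcal expressed in kJ.
KCAL_TO_KJ = 4.184


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at ``temperature`` Kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
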