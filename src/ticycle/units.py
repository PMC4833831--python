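"""Physical constants and unit conventions.

Everything in this package uses nm, ps, kJ/mol, K and elementary charges.
"""

#: Molar gas constant, kJ mol^-1 K^-1 (engine convention, 4 significant digits).
R_GAS = 0.008314

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458


def rt(temperature: float) -> float:
    """RT in kJ/mol at the given temperature in K."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return R_GAS * temperature
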