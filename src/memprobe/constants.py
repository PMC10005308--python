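"""Physical constants and unit conversion factors.

Internal units are nm (length), ns (time), amu (mass), kJ/mol (energy),
K (temperature).
"""

#: Gas constant in kJ mol^-1 K^-1.
R_GAS = 0.008314462618

#: amu / nm^3 -> kg / m^3.
AMU_PER_NM3_TO_KG_PER_M3 = 1.66053906660

#: nm^2 / ns -> cm^2 / s.
NM2_PER_NS_TO_CM2_PER_S = 1.0e-5


def rt(temperature: float) -> float:
    """RT in kJ/mol at the given temperature (K)."""
    return R_GAS * temperature
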