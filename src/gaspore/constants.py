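"""Physical constants and unit conventions.

Units throughout the package: lengths in Å, energies in kcal/mol,
temperatures in K, times in ns, charges in elementary charge units.
"""

#: Gas constant, kcal/(mol·K).
R = 1.987204e-3

#: Default simulation temperature, K.
T_DEFAULT = 310.0

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_K = 332.0636


def RT(temperature: float = T_DEFAULT) -> float:
    """Thermal energy R·T in kcal/mol (≈0.6160 kcal/mol at 310 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R * temperature
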