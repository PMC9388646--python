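"""Physical constants and unit conventions.

Coordinates are stored in angstrom (Å) throughout the package; collective
variables that are defined on a nanometre scale (switched-RMSD scores,
native contacts) convert internally.  Energies are in kcal/mol, times in ps,
temperatures in kelvin.
"""

#: Boltzmann constant in kcal/mol/K.
K_B: float = 0.0019872041

#: Å per nm.
ANGSTROM_PER_NM: float = 10.0


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B * temperature
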