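"""Physical constants shared across the package.

All energies are in kcal/mol, lengths in angstrom, times in ps.
"""

#: Boltzmann constant in kcal/mol/K; fixed to this literal so that kT
#: conversions are bit-identical across modules.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Simulation temperature used throughout the reference calculations (K).
DEFAULT_TEMPERATURE = 323.25


def thermal_energy(temperature: float) -> float:
    """kT in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
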