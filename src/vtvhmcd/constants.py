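"""Physical constants in wavenumber units.

Magnetic energies are handled throughout in cm^-1, fields in Tesla and
temperatures in Kelvin, the natural units of low-temperature MCD work.
"""

#: Bohr magneton, cm^-1 per Tesla (mu_B / hc).
BOHR_MAGNETON_CM1_PER_T = 0.4668645

#: Boltzmann constant, cm^-1 per Kelvin (k_B / hc).
BOLTZMANN_CM1_PER_K = 0.6950348


def nm_to_cm1(wavelength_nm: float) -> float:
    """Convert a wavelength in nm to a transition energy in cm^-1."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 1.0e7 / wavelength_nm


def cm1_to_nm(energy_cm1: float) -> float:
    """Convert a transition energy in cm^-1 to a wavelength in nm."""
    if energy_cm1 <= 0:
        raise ValueError("energy must be positive")
    return 1.0e7 / energy_cm1
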