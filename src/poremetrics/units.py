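"""Unit conventions and physical constants.

Internal units throughout the package: lengths in nm, times in ns,
pressures in bar, forces/tensions in pN, energies in J (with kBT
convenience conversions), hydrophobicity in kcal/mol.  All conversion
factors live here so no module hard-codes its own.
"""

#: Boltzmann constant [J/K].
KB_J_PER_K = 1.380649e-23

#: 1 bar * nm^2 expressed in pN  (1e5 Pa * 1e-18 m^2 = 1e-13 N).
BAR_NM2_TO_PN = 0.1

#: 1 pN * nm expressed in J.
PN_NM_TO_J = 1e-21

#: 1 Angstrom in nm.
ANGSTROM_TO_NM = 0.1

#: Production simulation temperature [K] (37 degC).
SIMULATION_TEMPERATURE_K = 310.15

#: Standard temperature [K] used for quoting energies in kBT.
STANDARD_TEMPERATURE_K = 298.15

#: Molarity of pure water [mol/l]; used for water-count based salt molarity.
WATER_MOLARITY = 55.5


def kbt_in_joule(temperature_k: float) -> float:
    """Thermal energy kB*T in J at the given temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_J_PER_K * temperature_k


def kbt_in_pn_nm(temperature_k: float) -> float:
    """Thermal energy kB*T expressed in pN*nm."""
    return kbt_in_joule(temperature_k) / PN_NM_TO_J
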