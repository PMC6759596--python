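"""Physical constants and fixed conventions used throughout the package.

All internal quantities are SI: concentrations in mol m^-3 (1 mM == 1 mol m^-3),
potentials in V, pressures in Pa, lengths in m, fluxes in mol m^-2 s^-1.
"""

FARADAY = 96485.33212  # C mol^-1
GAS_CONSTANT = 8.31446  # J mol^-1 K^-1
TEMPERATURE = 298.15  # K, fixed unless configured
WATER_DENSITY = 1000.0  # kg m^-3, converts compartment volume to fresh weight

#: RT/F at the default temperature (V)
def thermal_voltage(T: float = TEMPERATURE) -> float:
    return GAS_CONSTANT * T / FARADAY


#: mol s^-1 kg^-1 -> nmol min^-1 g^-1  (1e9 nmol/mol * 60 s/min * 1e-3 kg/g)
MOL_PER_S_KG_TO_NMOL_PER_MIN_G = 1e9 * 60.0 * 1e-3

SPECIES = ("Na", "K", "Cl", "H")
VALENCE = {"Na": 1, "K": 1, "Cl": -1, "H": 1}
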