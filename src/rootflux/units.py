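"""Unit conversions between SI and the reporting units of root physiology."""

NMOL_PER_MOL = 1e9
SECONDS_PER_MINUTE = 60.0
GRAMS_PER_KG = 1e3
SECONDS_PER_DAY = 86400.0


def mol_s_kg_to_nmol_min_g(x: float) -> float:
    """mol s^-1 kg(FW)^-1 -> nmol min^-1 g(FW)^-1."""
    return x * NMOL_PER_MOL * SECONDS_PER_MINUTE / GRAMS_PER_KG


def nmol_min_g_to_mol_s_kg(x: float) -> float:
    return x * GRAMS_PER_KG / (NMOL_PER_MOL * SECONDS_PER_MINUTE)


def mol_m3_to_mM(x: float) -> float:
    """mol m^-3 is numerically identical to mM."""
    return x


def mol_kg_to_umol_g(x: float) -> float:
    """mol kg(FW)^-1 -> umol g(FW)^-1 (numerically identical)."""
    return x * 1e6 / GRAMS_PER_KG


def days(x: float) -> float:
    """Days -> seconds."""
    return x * SECONDS_PER_DAY
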