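"""Physical constants (CODATA 2018) and laboratory defaults."""

#: Faraday constant, C mol^-1
FARADAY = 96485.33212

#: Molar gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314462618

#: Elementary charge, C
ELEMENTARY_CHARGE = 1.602176634e-19

#: Default absolute temperature, K (standard electrophysiology convention;
#: RT/F = 25.693 mV)
T_DEFAULT = 298.15

#: Default cytosolic K+ concentration of a Xenopus oocyte, mol L^-1
K_IN_DEFAULT = 0.1

#: Default cytosolic H+ concentration (pH 7.1, measured in oocytes), mol L^-1
H_IN_DEFAULT = 10.0 ** -7.1


def thermal_voltage_mV(T_K: float = T_DEFAULT) -> float:
    """RT/F in millivolts at absolute temperature ``T_K``."""
    return GAS_CONSTANT * T_K / FARADAY * 1e3


def nernst_slope_mV(T_K: float = T_DEFAULT) -> float:
    """Decadic Nernst slope RT ln(10)/F in mV per tenfold concentration ratio."""
    import math

    return thermal_voltage_mV(T_K) * math.log(10.0)
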