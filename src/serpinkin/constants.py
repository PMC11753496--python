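"""Physical constants used across the kinetic modules."""

#: gas constant, J mol^-1 K^-1
R_GAS = 8.314

#: additive offset for degC -> K conversion (exact by convention here)
CELSIUS_OFFSET = 273.15


def c_to_k(t_c):
    return t_c + CELSIUS_OFFSET


def k_to_c(t_k):
    return t_k - CELSIUS_OFFSET
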