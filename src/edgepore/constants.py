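"""Physical constants used across the analyses."""

#: molar gas constant in kJ mol^-1 K^-1
GAS_CONSTANT_KJ_PER_MOL_K = 0.0083145

#: default analysis temperature (K)
DEFAULT_TEMPERATURE_K = 300.0
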