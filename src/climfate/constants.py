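"""Physical constants shared across the package."""

#: Ideal gas constant, J mol^-1 K^-1 (equivalently Pa m^3 mol^-1 K^-1).
R_J_MOL_K = 8.314

#: Days per model year (no leap days).
DAYS_PER_YEAR = 365
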