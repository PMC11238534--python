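"""Physical constants and shared defaults (kcal, mol, K units throughout)."""

#: Gas constant in kcal/mol/K.
R_KCAL = 0.0019872

#: Reference temperature for "298" superscript quantities, kelvin (25 degC).
T_REF = 298.15

#: Heat capacity of bulk water per molecule, kcal/mol/K (experimental value,
#: used for the water-count imbalance correction of the binding-dCp cycle).
BULK_WATER_CP = 0.018

#: Default simulation temperature grid for energy scans, kelvin.
DEFAULT_SCAN_TEMPERATURES = (283.0, 288.0, 293.0, 298.0, 303.0)
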