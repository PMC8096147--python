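"""Physical constants and unit conventions shared by all modules.

Units follow the conventions of nucleic-acid thermodynamics tables:
enthalpies in kcal/mol, entropies in cal mol^-1 K^-1, temperatures stored
in Kelvin internally and reported in degrees Celsius.
"""

#: Gas constant in cal mol^-1 K^-1 (thermochemical calorie convention).
R_CAL = 1.987

#: Reference temperature for standard Gibbs energies, K (25 degrees C).
T_REF = 298.15

#: Celsius / Kelvin offset.
ZERO_C = 273.15


def celsius_to_kelvin(t_c):
    return t_c + ZERO_C


def kelvin_to_celsius(t_k):
    return t_k - ZERO_C
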