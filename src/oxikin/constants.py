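"""Physical constants and fitting conventions used throughout oxikin.

Every regression in this package uses the abscissa x = 1000/T (K), so a
slope multiplied by R = 8.314 J mol^-1 K^-1 lands directly in kJ/mol.
All constants are collected here and echoed into analysis reports, because
the three silent ways to get these fits wrong are an abscissa rescaling,
a different R, and a different ln(kB/h) convention.
"""

from __future__ import annotations

import math

#: Gas constant, J mol^-1 K^-1 (rounded value conventional in thermal analysis).
R_J_PER_MOL_K: float = 8.314

#: Hartree -> kJ/mol conversion (CODATA-style molar value).
HARTREE_TO_KJ_PER_MOL: float = 2625.4996

#: Celsius -> Kelvin offset.
CELSIUS_OFFSET: float = 273.15

#: ln(kB/h) as conventionally tabulated for Eyring fits on rate constants in
#: reciprocal hours with the 1000/T abscissa. This is the reproduction
#: default; see LN_KB_OVER_H_SI for the SI s^-1 value.
LN_KB_OVER_H_DEFAULT: float = 21.46

#: ln(kB/h) from SI constants (kB = 1.380658e-23 J/K, h = 6.6260755e-34 J s),
#: i.e. for rate constants in s^-1.
LN_KB_OVER_H_SI: float = math.log(1.380658e-23 / 6.6260755e-34)

#: Flynn-Wall-Ozawa linearization constant (Doyle approximation).
FWO_FACTOR: float = 0.4567

#: Kissinger-Akahira-Sunose linearization constant, 1/ln(10).
KAS_FACTOR: float = 0.4343

#: Abscissa convention recorded in every fit.
ABSCISSA: str = "1000/T_K"


def conventions() -> dict:
    """Return the conventions block embedded in every report."""
    return {
        "abscissa": ABSCISSA,
        "gas_constant_J_per_mol_K": R_J_PER_MOL_K,
        "hartree_to_kJ_per_mol": HARTREE_TO_KJ_PER_MOL,
        "ln_kb_over_h_default": LN_KB_OVER_H_DEFAULT,
        "ln_kb_over_h_si": LN_KB_OVER_H_SI,
        "fwo_factor": FWO_FACTOR,
        "kas_factor": KAS_FACTOR,
        "log_base": "log10 for isoconversional fits, ln for Arrhenius/Eyring",
    }
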