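"""Physical constants and unit conversions (kcal/mol convention throughout)."""

import math

#: Gas constant in kcal/(mol K).
GAS_CONSTANT = 1.987204258e-3

#: Natural log of 10.
LN10 = math.log(10.0)

#: Standard-state temperature in kelvin.
STANDARD_TEMPERATURE = 298.15

#: Hartree -> kcal/mol.
HARTREE_TO_KCAL = 627.509474


def rt_ln10(temperature: float = STANDARD_TEMPERATURE) -> float:
    """R*T*ln(10) in kcal/mol — the free-energy-per-pH-unit conversion.

    At 298.15 K this evaluates to 1.3643 kcal/mol: a pKa shift of one pH
    unit corresponds to 1.3643 kcal/mol of isodesmic reaction free energy.
    """
    return GAS_CONSTANT * temperature * LN10
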