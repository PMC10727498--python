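"""Stimulus solution recipes used as simulator and fixture parameters.

The artificial oilseed-rape (OSR) nectar mimic is glucose + fructose
with a trace of sucrose; behavioural controls use an equimolar sucrose
solution, and electrophysiology uses a 10% dilution of the mimic.
"""

from __future__ import annotations

#: Artificial OSR nectar composition, mol/L.
OSR_RECIPE_M = {
    "glucose": 1.04,
    "fructose": 0.746,
    "sucrose": 0.007,
}

#: Sucrose molarity equimolar to the 10% OSR dilution (electrophysiology).
EQUIMOLAR_SUCROSE_10PCT_M = 0.173


def osr_total_molarity() -> float:
    """Total sugar molarity of the OSR mimic (the equimolar-sucrose match)."""
    return sum(OSR_RECIPE_M.values())


def osr_dilution_molarity(fraction: float) -> float:
    """Total molarity of a diluted OSR solution (e.g. 0.1 for 10% OSR)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return osr_total_molarity() * fraction
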