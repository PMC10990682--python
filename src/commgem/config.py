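"""Global numerical conventions.

All flux values are in mmol · gCDW⁻¹ · h⁻¹ (member-normalised fluxes) or
mmol · gCDW_community⁻¹ · h⁻¹ after scaling by mass fractions.
"""

#: Numeric tolerance for feasibility, optimality and "zero flux" classification.
TOLERANCE: float = 1e-6

#: Magnitude used for "unconstrained" flux bounds (COBRA convention).
#: Infinite bounds encountered on read are clamped to this magnitude.
DEFAULT_BOUND: float = 1000.0
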