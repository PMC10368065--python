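"""Unit conventions and physical constants.

All internal computations use millimetres and picoseconds.  Optical
coefficients are therefore carried in mm^-1 internally, while the public
command-line surface and most published values in this field are quoted in
cm^-1.  Conversion: 1 cm^-1 = 0.1 mm^-1.
"""

import math

#: Speed of light in vacuum (mm/ps).
C_MM_PS = 0.299792458

LN10 = math.log(10.0)


def speed_in_medium(n: float) -> float:
    """Speed of light in a medium of refractive index ``n`` (mm/ps)."""
    return C_MM_PS / n


def per_cm_to_per_mm(x):
    """Convert an optical coefficient from cm^-1 to mm^-1."""
    return x * 0.1


def per_mm_to_per_cm(x):
    """Convert an optical coefficient from mm^-1 to cm^-1."""
    return x * 10.0
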