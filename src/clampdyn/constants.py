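"""Physical constants and unit conversions (AKMA-like unit system).

Internal units: length Å, time ps, mass amu (= g/mol), energy kcal/mol.
Angles are degrees at every API boundary; radians internally where noted.
"""

import math

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

#: 1 kcal/mol expressed in amu Å^2 ps^-2.
#: 1 amu Å^2 ps^-2 = 1e-3 kg/mol * 1e-20 m^2 / 1e-24 s^2 = 10 J/mol exactly,
#: hence 4184 J/mol / 10 = 418.4.
KCAL_TO_AKMA = 418.4

#: Conversion factor degrees -> radians.
DEG = math.pi / 180.0

#: (180/pi)^2 — converts a force constant per deg^2 to per rad^2.
PER_DEG2_TO_PER_RAD2 = (180.0 / math.pi) ** 2
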