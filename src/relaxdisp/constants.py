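"""Physical constants used by the relaxation-rate expressions.

Gyromagnetic ratios are CODATA values in rad s^-1 T^-1. gamma_N is negative
(15N precesses opposite to 1H); every prefactor squares the coupling so only
the magnitude enters a rate, but the signed value is stored.
"""

import math

GAMMA_H = 2.6752218708e8  # 1H, rad s^-1 T^-1
GAMMA_N = -2.7116e7       # 15N, rad s^-1 T^-1

#: |gamma_N| / gamma_H — converts a 1H Larmor frequency to the 15N one.
GAMMA_RATIO_NH = abs(GAMMA_N) / GAMMA_H

MU0 = 4.0 * math.pi * 1e-7     # vacuum permeability, T^2 m^3 J^-1
HBAR = 1.054571817e-34         # reduced Planck constant, J s

ANGSTROM = 1e-10               # m
TWO_PI = 2.0 * math.pi
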