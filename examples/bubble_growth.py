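"""Maximum bubble radius across the treatment pressure range.

Evaluates the analytic Kelvin-Voigt growth model at the elastic moduli of
the two thrombus components. Red blood cell regions (G = 4 kPa) grow
~100-um bubbles; fibrin (G = 14 MPa) arrests growth entirely (the net
tension xi is negative, so R_MAX stays at the 2.5-nm nucleus).
"""

import numpy as np

from thrombosim import max_radius, xi

print(f"{'p- (MPa)':>9} {'R in RBC (um)':>14} {'R in fibrin (um)':>17}")
for p_mpa in np.arange(28.0, 41.0, 2.0):
    r_rbc = max_radius(p_mpa * 1e6, 4e3) * 1e6
    r_fib = max_radius(p_mpa * 1e6, 14e6) * 1e6
    print(f"{p_mpa:>9.0f} {r_rbc:>14.1f} {r_fib:>17.4f}")
print(f"\nnet tension in fibrin at 40 MPa: xi = {xi(40e6, 14e6):.0f} (< 0, no growth)")
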