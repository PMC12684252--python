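"""Plate-reader computations: doubling time, reporter signal, turn-on ratio.

A clean exponential growth curve read every 5 minutes is inverted for
the doubling time using the standard early-exponential window (first ten
readings from OD600 >= 0.015 after blank subtraction); reporter
normalization and fluorogenic turn-on ratios are simple guarded ratios.
"""

import numpy as np

import strobetrack as st

t = np.arange(60) * 5.0  # minutes
curve = st.GrowthCurve(t, 0.04 + 0.01 * 2 ** (t / 30.0), blank=0.04)
td = st.doubling_time(curve)
print(f"doubling time: {td:.3f} min (constructed with 30 min)")

f_per_od = st.normalized_reporter(fluorescence=1500.0, od=0.5)
print(f"reporter signal: 1500 AU at OD 0.5 -> {f_per_od:.0f} AU/OD")

for name, f_plus, f_minus in (("dye with ~3x turn-on", 300.0, 100.0),
                              ("dye with ~2x turn-on", 200.0, 100.0)):
    print(f"{name}: ratio = {st.turn_on_ratio(f_plus, f_minus):.1f}")
# The turn-on ratio is the fluorogenicity measure for click dyes: signal
# after reaction with the clickable amino acid over unreacted signal.
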