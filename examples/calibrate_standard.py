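"""Calibrate measured scattering vectors against a reference standard.

Simulated standard peaks with a 2% scale error and a small offset are
regressed against the bundled cholesteryl palmitate reference positions; the
fitted (slope, intercept) then corrects a sample measurement.  The corrected
values should equal the literature positions.
"""

import numpy as np

from saxskit import llc

std = llc.load_standard("cholesteryl palmitate")
print("literature q (nm^-1):", np.round(std.literature_q, 4))

# what a slightly miscalibrated camera would measure
measured = 1.02 * std.literature_q + 0.005
cal = llc.prepare_standard(measured, std)
print(f"calibration: slope = {cal.slope:.4f}, intercept = {cal.intercept:.4f} nm^-1")

corrected = llc.calibrate(measured, cal)
print("corrected q  (nm^-1):", np.round(corrected, 4))
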