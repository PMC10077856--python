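"""Assign a lyotropic mesophase and lattice parameter from peak positions.

The five peak positions of a body-centred bicontinuous cubic phase with
a = 2.17 nm are converted to lattice-plane distances; the ratio pattern
identifies the phase, Miller indices and space group, and the lattice
parameter is recovered from each reflection.
"""

import numpy as np

from saxskit import llc

# observed reflections 211, 220, 310, 321, 611 of a cubic cell, a = 2.17 nm
n = np.array([6.0, 8.0, 10.0, 14.0, 38.0])
q_measured = (2 * np.pi / 2.17) * np.sqrt(n)

d = np.sort(llc.d_from_q(q_measured))[::-1]
result = llc.assign_phase(d, tolerance=0.02)
a = llc.lattice_parameter(result)

print(f"phase: {result.phase} ({result.space_group}, {result.centering})")
print("indices:", ", ".join(str(m) for m in result.indices))
print("d ratios:", np.round(result.d_ratios, 4))
print(f"lattice parameter a = {a:.4f} nm (spread {result.a_spread:.2e} nm)")
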