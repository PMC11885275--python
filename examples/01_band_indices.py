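"""Band-power hemodynamic indices from a calibrated speckle trace.

Generates a 10-s fast speckle trace whose power is split over the five
relHI frequency bands at a baseline microcirculatory profile, then runs the
band-power decomposition and normalization stages and prints the recovered
indices next to the generating fractions.
"""

import numpy as np

from dlsflow import (BandFractionSpec, band_power_decomposition,
                     compute_relhis, simulate_speckle_trace)

target = (0.880, 0.054, 0.033, 0.020, 0.013)
trace = simulate_speckle_trace(BandFractionSpec(target), duration=10.0, seed=1)
rel = compute_relhis(band_power_decomposition(trace))
recovered = rel.median()

print("band   target   recovered")
for i, (t, r) in enumerate(zip(target, recovered), start=1):
    print(f"relHI{i}  {t:.3f}    {r:.4f}")
print("\nrelHI1 is the smallest-vessel fraction; recovering the generating")
print("fractions within ~0.02 shows the decomposition is spectrally calibrated.")
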