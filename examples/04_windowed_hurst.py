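"""Windowed Hurst-exponent analysis with AC/DC decomposition.

Generates a 10-min flow signal at a persistent flowmotion exponent, splits
it into pulsatile (AC) and non-pulsatile (DC) components at 0.5 Hz, and
estimates the Hurst exponent in 180-s windows with 90-s steps.
"""

import numpy as np

from dlsflow import FlowSignalSpec, simulate_pulsatile_flow, windowed_hurst

flow = simulate_pulsatile_flow(FlowSignalSpec(duration=600.0,
                                              hurst_target=1.0, seed=4))
for comp in ("full", "ac", "dc"):
    hs = windowed_hurst(flow, comp)          # 180-s window, 90-s step
    print(f"{comp:4s}: {hs.window_starts.size} windows, "
          f"median H = {hs.median():.3f}")
print("\n0.5 means uncorrelated flow; values near 1 indicate self-similar,")
print("persistent flowmotion. The DC (slow) component is the smoothest and")
print("scores highest; the AC pulse train is quasi-periodic and scores low.")
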